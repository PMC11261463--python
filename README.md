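# cpmtools

Connectome-based predictive modeling (CPM) of behavioral severity from
functional-connectivity (FC) matrices, with the follow-up analyses that
typically surround it in clinical neuroimaging: hub-node identification,
hub-seeded group comparison between patient subtypes, covariate-adjusted
correlation of the discriminating connection with clinical scores, and
RBF-SVM subtype classification.

The package is aimed at researchers analyzing resting-state fMRI cohorts
parcellated into a whole-brain atlas (the default design assumes a
246-region parcellation and a three-group cohort: melancholic MDD,
non-melancholic MDD, healthy controls, with anhedonia measured on the
TEPS scale). Because such clinical datasets are rarely shareable, the
package ships a seeded synthetic-cohort generator that reproduces the
statistical structure the analyses assume — planted behavior-linked
edges concentrated on hub nodes, a planted subtype-difference edge, and
realistic score distributions — so every stage is testable end to end
against known ground truth.

## The model

For subjects with FC matrices `M⁽ˢ⁾` (Pearson correlations between
regional time series) and a behavioral score `y⁽ˢ⁾`, CPM proceeds per
leave-one-out fold:

1. **Edge selection.** Each edge's values across the training subjects
   are correlated with `y`; the two-tailed p comes from
   `t = r·√((n−2)/(1−r²))` with `n−2` df. The positive network is
   `{edges : r > 0, p < 0.0001}` (negative tail analogous).
2. **Network strength.** Each subject is summarized by
   `S⁽ˢ⁾ = Σ_{(i,j)∈mask} M⁽ˢ⁾ᵢⱼ`, the sum of FC values over the
   selected edges.
3. **Prediction.** Univariate least squares `y = β₀ + β₁·S` is fitted
   on the training subjects; the held-out subject is predicted from its
   own strength under the training mask.

The model is summarized by the Pearson correlation `r_obs` between
observed and cross-validated predicted scores and the mean squared
error, with significance from permuting `y` across subjects and
re-running everything: `p = (1 + #{r_null ≥ r_obs}) / (1 + N_perm)`.

Nodes with ≥ 5 incident edges in the across-fold consensus network are
hubs; hub-seeded FC is compared between subtypes with pooled-variance
t-tests (Bonferroni-corrected), the top edge is correlated with
clinical scores controlling for age, education, illness duration and
head motion (partial correlation), and finally used as the feature of a
grid-searched RBF-SVM (LIBSVM-style workflow: per-fold scaling to
[−1, 1], stratified five-fold CV, `c`/`g` over powers of two).

## Worked example

```python
from cpmtools import (CohortSpec, CPMConfig, generate_cohort, run_cpm,
                      permutation_test, seed_fc_compare, grid_search_cv)

spec = CohortSpec(edge_behavior_r=0.6, subtype_diff_d=1.5, seed=7)
cohort = generate_cohort(spec)          # 31 + 28 + 32 subjects, 246 nodes

cfg = CPMConfig(p_threshold=1e-4, n_permutations=200, seed=7)
result = permutation_test(cohort, cfg, result=run_cpm(cohort, cfg))
print(f"r_obs = {result.r_obs:.4f}, MSE = {result.mse:.4f}, "
      f"p_perm = {result.p_perm:.4f}")
print("consensus edges:", result.consensus_mask.n_selected,
      "hubs:", result.hubs())

comps = seed_fc_compare(cohort, seeds=result.hubs())
top = comps[0]
print(f"top edge ({top.seed}, {top.target}): t = {top.t:.3f}, "
      f"p_bonf = {top.p_bonf:.4f} (m = {top.family_size})")

patients = cohort.patients()
cls = grid_search_cv(patients.edge_values(top.seed, top.target),
                     patients.group_labels(), k=5, seed=7,
                     subject_ids=patients.ids())
print(cls.as_percentages())
```

prints

```
r_obs = 0.9653, MSE = 1.9668, p_perm = 0.0050
consensus edges: 21 hubs: [89, 109]
top edge (109, 174): t = -4.588, p_bonf = 0.0122 (m = 489)
{'sensitivity_pct': 74.19, 'specificity_pct': 71.43, 'accuracy_pct': 72.88}
```

Reading: the cross-validated network strength predicts the anhedonia
score nearly perfectly on this synthetic cohort (`r_obs = 0.97`, and no
permutation reached it, so `p` sits at its floor `1/201`); 21 of the 26
planted edges survive into the consensus network; both planted hub
nodes (89 = right inferior-temporal analog, 109 = right parahippocampal
analog) are recovered. The hub-seeded group comparison top-ranks edge
(109, 174) — exactly the planted subtype-difference connection to the
left cingulate analog — with melancholic patients lower (t < 0), and
that single FC value separates the subtypes at 72.9% CV accuracy.

The same workflow is available from the shell:

```sh
cpm simulate --out cohort --seed 7
cpm run --cohort cohort --out out --n-perm 200 --seed 7
cpm groupdiff --cohort cohort --seeds 89,109 --out out/gd
cpm classify --cohort cohort --edges 109,174 --out out/cls --seed 7
cpm all --out out_all --seed 7          # everything, with manifest.json
```

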