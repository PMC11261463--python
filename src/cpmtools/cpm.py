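"""Connectome-based predictive modeling (CPM).

The procedure, per cross-validation fold:

1. correlate every FC edge with the behavioral score across the
   training subjects (Pearson r, two-tailed p from the t transform
   ``t = r * sqrt((n-2) / (1-r^2))`` with n-2 df);
2. select the positive tail (r > 0, p < threshold) and/or the negative
   tail (r < 0, p < threshold);
3. collapse each training subject's selected edges into a single
   network-strength score (sum of the raw FC values over the mask);
4. fit univariate least squares ``behavior ~ strength`` on the training
   subjects and predict the held-out subject from its own strength
   under the training mask.

Observed-vs-predicted Pearson r and MSE summarize the model over all
held-out predictions; significance comes from permuting the behavior
vector across subjects (FC fixed) and re-running the whole procedure,
with the add-one p estimator ``(1 + #{r_null >= r_obs}) / (1 + N)``.

Leave-one-out CV is the default; folds whose selection is empty fall
back to an intercept-only model (training-mean prediction) and are
flagged. Hub nodes are those with at least ``hub_threshold`` incident
edges in the across-fold consensus mask.

The per-fold selection statistics are computed with leave-one-out
updates of the full-sample cross-products, so a single LOOCV pass is
O(subjects x edges) and the permutation loop reuses all behavior-
independent terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .atlas import Atlas
from .connectome import FCMatrix, edge_pairs, n_edges, vectorize_edges

__all__ = [
    "CPMConfig", "EdgeMask", "CPMResult", "DegreeRecord",
    "edge_behavior_correlation", "select_edges", "network_strength",
    "run_cpm", "run_cpm_edges", "permutation_test", "permutation_pvalue",
    "consensus_and_degree", "summarize_mask_by_atlas",
]

_TINY = 1e-300


@dataclass(frozen=True)
class CPMConfig:
    """Tunable parameters of the CPM stage."""

    p_threshold: float = 1e-4
    tail: str = "positive"  # positive | negative | both
    cv: str = "loocv"       # loocv | kfold
    k: int = 10             # folds when cv == "kfold"
    n_permutations: int = 5000
    behavior: str = "teps_abstract_consummatory"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.tail not in ("positive", "negative", "both"):
            raise ValueError(f"unknown tail {self.tail!r}")
        if self.cv not in ("loocv", "kfold"):
            raise ValueError(f"unknown cv scheme {self.cv!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


class EdgeMask:
    """Binary symmetric edge set over ``n_nodes``, stored as a flat
    boolean vector in upper-triangle edge order."""

    def __init__(self, flat: np.ndarray, n_nodes: int, tail: str = "positive"):
        flat = np.asarray(flat, dtype=bool)
        if flat.shape != (n_edges(n_nodes),):
            raise ValueError(
                f"mask length {flat.size} != {n_edges(n_nodes)} edges for "
                f"{n_nodes} nodes")
        self.flat = flat
        self.n_nodes = n_nodes
        self.tail = tail

    @classmethod
    def from_matrix(cls, m: np.ndarray, tail: str = "positive") -> "EdgeMask":
        m = np.asarray(m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("edge mask matrix must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("edge mask matrix must be symmetric")
        if np.any(np.diag(m)):
            raise ValueError("edge mask diagonal must be zero")
        iu, ju = edge_pairs(m.shape[0])
        return cls(m[iu, ju] != 0, m.shape[0], tail)

    def to_matrix(self) -> np.ndarray:
        m = np.zeros((self.n_nodes, self.n_nodes), dtype=int)
        iu, ju = edge_pairs(self.n_nodes)
        m[iu, ju] = self.flat
        m[ju, iu] = self.flat
        return m

    def edge_list(self) -> list[tuple[int, int]]:
        iu, ju = edge_pairs(self.n_nodes)
        sel = np.flatnonzero(self.flat)
        return [(int(iu[k]), int(ju[k])) for k in sel]

    def degrees(self) -> np.ndarray:
        return self.to_matrix().sum(axis=1)

    @property
    def n_selected(self) -> int:
        return int(self.flat.sum())

    def __and__(self, other: "EdgeMask") -> "EdgeMask":
        if other.n_nodes != self.n_nodes:
            raise ValueError("masks cover different node counts")
        return EdgeMask(self.flat & other.flat, self.n_nodes, self.tail)

    def issubset(self, other: "EdgeMask") -> bool:
        return bool(np.all(~self.flat | other.flat))

    def __eq__(self, other) -> bool:
        return (isinstance(other, EdgeMask) and self.n_nodes == other.n_nodes
                and np.array_equal(self.flat, other.flat))


@dataclass(frozen=True)
class DegreeRecord:
    node: int
    degree: int
    is_hub: bool


@dataclass
class CPMResult:
    """Cross-validated CPM output for one behavior score."""

    predictions: pd.Series          # indexed by subject id
    observed: pd.Series
    r_obs: float
    mse: float
    fold_masks: list[EdgeMask]
    consensus_mask: EdgeMask
    degrees: list[DegreeRecord]
    empty_mask_folds: list[int]
    config: CPMConfig
    p_perm: float | None = None
    null_distribution: np.ndarray | None = None
    n_null_failures: int = 0

    def hubs(self) -> list[int]:
        return [d.node for d in self.degrees if d.is_hub]


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p of Pearson r via the t transform with n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, _TINY))
    return 2.0 * special.stdtr(df, -np.abs(t))


def edge_behavior_correlation(edge_values: np.ndarray, behavior: np.ndarray
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge Pearson r (and two-tailed p) with a behavioral score.

    ``edge_values`` is subjects-by-edges. Constant edges get r = 0,
    p = 1; a constant behavior vector is an error (selection undefined).
    """
    X = np.asarray(edge_values, dtype=float)
    y = np.asarray(behavior, dtype=float)
    if X.ndim != 2:
        raise ValueError("edge_values must be subjects x edges")
    n = X.shape[0]
    if y.shape != (n,):
        raise ValueError("behavior length does not match subject count")
    if n < 4:
        raise ValueError(f"need at least 4 subjects, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("behavior score is constant; edge selection undefined")
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    sy = np.sqrt((yc * yc).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    constant = sx == 0
    r[constant] = 0.0
    r = np.clip(r, -1.0, 1.0)
    p = _corr_pvalues(r, n)
    p[constant] = 1.0
    return r, p


def select_edges(r: np.ndarray, p: np.ndarray, p_threshold: float,
                 n_nodes: int | None = None
                 ) -> tuple[np.ndarray, np.ndarray] | tuple[EdgeMask, EdgeMask]:
    """Positive-tail and negative-tail edge selections at ``p_threshold``.

    Returns flat boolean vectors, or :class:`EdgeMask` objects when
    ``n_nodes`` is given.
    """
    r = np.asarray(r)
    p = np.asarray(p)
    pos = (r > 0) & (p < p_threshold)
    neg = (r < 0) & (p < p_threshold)
    if n_nodes is None:
        return pos, neg
    return EdgeMask(pos, n_nodes, "positive"), EdgeMask(neg, n_nodes, "negative")


def network_strength(fc, mask) -> float:
    """Sum of FC values over the masked edges (each unordered pair once)."""
    if isinstance(mask, EdgeMask):
        flat_mask = mask.flat
    else:
        flat_mask = np.asarray(mask, dtype=bool)
    if isinstance(fc, FCMatrix):
        vec = vectorize_edges(fc)
    else:
        vec = np.asarray(fc, dtype=float)
        if vec.ndim == 2:
            vec = vectorize_edges(vec)
    if vec.shape != flat_mask.shape:
        raise ValueError(
            f"FC edge vector ({vec.shape}) and mask ({flat_mask.shape}) disagree")
    return float(vec[flat_mask].sum())


def _signed_strengths(X: np.ndarray, pos: np.ndarray, neg: np.ndarray,
                      tail: str) -> np.ndarray:
    if tail == "positive":
        return X[:, pos].sum(axis=1)
    if tail == "negative":
        return X[:, neg].sum(axis=1)
    return X[:, pos].sum(axis=1) - X[:, neg].sum(axis=1)


class _LoocvWorkspace:
    """Behavior-independent cross-products cached across permutations."""

    def __init__(self, X: np.ndarray):
        self.X = X
        n = X.shape[0]
        self.n = n
        sx = X.sum(axis=0)
        sxx = (X * X).sum(axis=0)
        m = n - 1
        self.sx_tr = sx[None, :] - X            # (n, E): training sums
        vx = (sxx[None, :] - X * X) - self.sx_tr ** 2 / m
        self.vx_tr = np.maximum(vx, 0.0)
        self.m = m

    def fold_correlations(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Training-set per-edge r and p for every leave-one-out fold."""
        X, n, m = self.X, self.n, self.m
        sy = y.sum() - y
        syy = (y * y).sum() - y * y
        vy = np.maximum(syy - sy * sy / m, 0.0)
        sxy = (X.T @ y)[None, :] - X * y[:, None]
        cov = sxy - self.sx_tr * sy[:, None] / m
        denom = np.sqrt(self.vx_tr * vy[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(denom > 0, cov / np.maximum(denom, _TINY), 0.0)
        r = np.clip(r, -1.0, 1.0)
        p = _corr_pvalues(r, m)
        p[self.vx_tr == 0] = 1.0
        return r, p


def _loocv_predict(ws: _LoocvWorkspace, y: np.ndarray, config: CPMConfig,
                   keep_masks: bool
                   ) -> tuple[np.ndarray, list[np.ndarray], list[int]]:
    """One full LOOCV pass; returns predictions, per-fold positive-tail
    masks (or selected-tail masks), and indices of empty-mask folds."""
    X, n = ws.X, ws.n
    r_all, p_all = ws.fold_correlations(y)
    preds = np.empty(n)
    masks: list[np.ndarray] = []
    empty: list[int] = []
    thr = config.p_threshold
    for i in range(n):
        pos = (r_all[i] > 0) & (p_all[i] < thr)
        neg = (r_all[i] < 0) & (p_all[i] < thr)
        if keep_masks:
            masks.append(pos if config.tail != "negative" else neg)
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        s = _signed_strengths(X, pos, neg, config.tail)
        s_tr, y_tr = s[tr], y[tr]
        var_s = s_tr.var()
        if var_s == 0:  # empty (or degenerate) selection: intercept only
            preds[i] = y_tr.mean()
            if (config.tail == "positive" and not pos.any()) or \
               (config.tail == "negative" and not neg.any()) or \
               (config.tail == "both" and not (pos.any() or neg.any())):
                empty.append(i)
            continue
        slope = np.cov(s_tr, y_tr, ddof=0)[0, 1] / var_s
        intercept = y_tr.mean() - slope * s_tr.mean()
        preds[i] = intercept + slope * s[i]
    return preds, masks, empty


def _kfold_predict(X: np.ndarray, y: np.ndarray, config: CPMConfig,
                   fold_of: np.ndarray
                   ) -> tuple[np.ndarray, list[np.ndarray], list[int]]:
    n = X.shape[0]
    preds = np.empty(n)
    masks, empty = [], []
    for f in range(fold_of.max() + 1):
        te = fold_of == f
        tr = ~te
        r, p = edge_behavior_correlation(X[tr], y[tr])
        pos, neg = select_edges(r, p, config.p_threshold)
        masks.append(pos if config.tail != "negative" else neg)
        s = _signed_strengths(X, pos, neg, config.tail)
        s_tr, y_tr = s[tr], y[tr]
        var_s = s_tr.var()
        if var_s == 0:
            preds[te] = y_tr.mean()
            empty.append(f)
            continue
        slope = np.cov(s_tr, y_tr, ddof=0)[0, 1] / var_s
        intercept = y_tr.mean() - slope * s_tr.mean()
        preds[te] = intercept + slope * s[te]
    return preds, masks, empty


def _pearson_or_zero(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, with 0 for degenerate (constant) inputs."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def run_cpm_edges(X: np.ndarray, y: np.ndarray, config: CPMConfig | None = None,
                  n_nodes: int | None = None,
                  subject_ids: list[str] | None = None,
                  hub_threshold: int = 5) -> CPMResult:
    """CPM on a raw subjects-by-edges matrix and behavior vector.

    ``n_nodes`` enables mask/degree reporting in matrix form; when
    omitted it is inferred if the edge count is triangular, otherwise
    masks are kept flat over a synthetic 1-node-per-edge layout.
    """
    config = config or CPMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, E = X.shape
    if n < 6:
        raise ValueError(f"CPM needs at least 6 subjects, got {n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("behavior vector contains non-finite values")
    if n_nodes is None:
        # invert E = k(k-1)/2 when possible
        k = int((1 + np.sqrt(1 + 8 * E)) / 2)
        n_nodes = k if n_edges(k) == E else None
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(n)]

    order = np.argsort(np.asarray(subject_ids))  # order-invariant folds
    Xo, yo = X[order], y[order]
    if config.cv == "loocv":
        ws = _LoocvWorkspace(Xo)
        preds_o, masks, empty = _loocv_predict(ws, yo, config, keep_masks=True)
    else:
        k = min(config.k, n)
        rng = np.random.default_rng(config.seed)
        fold_of = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
        rng.shuffle(fold_of)
        preds_o, masks, empty = _kfold_predict(Xo, yo, config, fold_of)

    preds = np.empty(n)
    preds[order] = preds_o
    r_obs = _pearson_or_zero(preds, y)
    mse = float(np.mean((preds - y) ** 2))

    if n_nodes is not None:
        tail = config.tail if config.tail != "both" else "positive"
        fold_masks = [EdgeMask(m, n_nodes, tail) for m in masks]
        consensus, degrees = consensus_and_degree(fold_masks, hub_threshold)
    else:
        fold_masks = []
        flat = np.logical_and.reduce(masks) if masks else np.zeros(E, dtype=bool)
        consensus = _FlatMask(flat)
        degrees = []

    ids = list(np.asarray(subject_ids))
    return CPMResult(
        predictions=pd.Series(preds, index=ids),
        observed=pd.Series(y, index=ids),
        r_obs=r_obs, mse=mse,
        fold_masks=fold_masks, consensus_mask=consensus, degrees=degrees,
        empty_mask_folds=empty, config=config)


class _FlatMask:
    """Flat consensus mask for edge matrices without node geometry."""

    def __init__(self, flat: np.ndarray):
        self.flat = np.asarray(flat, dtype=bool)
        self.n_nodes = None
        self.tail = "positive"

    @property
    def n_selected(self) -> int:
        return int(self.flat.sum())


def run_cpm(cohort, config: CPMConfig | None = None,
            hub_threshold: int = 5) -> CPMResult:
    """CPM over a cohort's patient subjects (melancholic + non-melancholic)."""
    config = config or CPMConfig()
    patients = cohort.patients() if hasattr(cohort, "patients") else cohort
    if len(patients.subjects) < 6:
        raise ValueError(f"CPM needs at least 6 patients, got {len(patients.subjects)}")
    X = patients.edge_matrix()
    y = patients.behavior_vector(config.behavior)
    return run_cpm_edges(X, y, config, n_nodes=patients.n_nodes,
                         subject_ids=patients.ids(), hub_threshold=hub_threshold)


def permutation_pvalue(r_obs: float, null_r: np.ndarray) -> float:
    """Add-one permutation p: (1 + #{null >= observed}) / (1 + N)."""
    null_r = np.asarray(null_r, dtype=float)
    return float((1 + np.sum(null_r >= r_obs)) / (1 + null_r.size))


def permutation_test(data, config: CPMConfig | None = None,
                     result: CPMResult | None = None,
                     behavior: np.ndarray | None = None) -> CPMResult:
    """Permutation significance of a CPM model.

    ``data`` is a cohort or a subjects-by-edges matrix (then ``behavior``
    is required). Each iteration shuffles the behavior vector across
    subjects with FC fixed, re-runs the full cross-validated procedure,
    and records the null observed-vs-predicted r. Iteration ``i`` draws
    its permutation from ``default_rng([seed, i])``, so the null
    distribution is reproducible in any execution order. Iterations
    whose predictions are degenerate contribute r_null = 0 and are
    counted in ``n_null_failures``.
    """
    config = config or CPMConfig()
    if behavior is None:
        patients = data.patients() if hasattr(data, "patients") else data
        X = patients.edge_matrix()
        y = patients.behavior_vector(config.behavior)
        ids = patients.ids()
        n_nodes = patients.n_nodes
    else:
        X = np.asarray(data, dtype=float)
        y = np.asarray(behavior, dtype=float)
        ids = None
        n_nodes = None
    if result is None:
        result = run_cpm_edges(X, y, config, n_nodes=n_nodes, subject_ids=ids)

    n = X.shape[0]
    null_r = np.empty(config.n_permutations)
    failures = 0
    if config.cv == "loocv":
        order = np.argsort(np.asarray(ids)) if ids is not None else np.arange(n)
        ws = _LoocvWorkspace(X[order])
        y_sorted = y[order]
        for it in range(config.n_permutations):
            rng = np.random.default_rng([config.seed, it])
            yp = y_sorted[rng.permutation(n)]
            preds, _, _ = _loocv_predict(ws, yp, config, keep_masks=False)
            r = _pearson_or_zero(preds, yp)
            if np.ptp(preds) == 0:
                failures += 1
            null_r[it] = r
    else:
        for it in range(config.n_permutations):
            rng = np.random.default_rng([config.seed, it])
            yp = y[rng.permutation(n)]
            res_p = run_cpm_edges(X, yp, config, n_nodes=n_nodes, subject_ids=ids)
            null_r[it] = res_p.r_obs
            if np.ptp(res_p.predictions.to_numpy()) == 0:
                failures += 1

    p = permutation_pvalue(result.r_obs, null_r)
    return replace_result(result, p_perm=p, null_distribution=null_r,
                          n_null_failures=failures)


def replace_result(result: CPMResult, **kw) -> CPMResult:
    d = {f.name: getattr(result, f.name) for f in result.__dataclass_fields__.values()}
    d.update(kw)
    return CPMResult(**d)


def consensus_and_degree(fold_masks: list[EdgeMask], hub_threshold: int = 5
                         ) -> tuple[EdgeMask, list[DegreeRecord]]:
    """Across-fold intersection mask and its node degrees.

    Records are sorted by degree descending, ties by node index
    ascending; ``is_hub`` marks degree >= ``hub_threshold``.
    """
    if not fold_masks:
        raise ValueError("need at least one fold mask")
    n_nodes = fold_masks[0].n_nodes
    flat = np.logical_and.reduce([m.flat for m in fold_masks])
    consensus = EdgeMask(flat, n_nodes, fold_masks[0].tail)
    deg = consensus.degrees()
    records = [DegreeRecord(int(i), int(d), bool(d >= hub_threshold))
               for i, d in enumerate(deg)]
    records.sort(key=lambda rec: (-rec.degree, rec.node))
    return consensus, records


def summarize_mask_by_atlas(mask: EdgeMask, atlas: Atlas, level: str = "lobe"
                            ) -> pd.DataFrame:
    """Region-by-region edge counts of a mask at the lobe or gyrus level.

    Returns a symmetric DataFrame whose (a, b) cell counts mask edges
    with one endpoint in region a and the other in b; summing the upper
    triangle (diagonal included) recovers the mask's edge count.
    """
    if atlas.n_nodes != mask.n_nodes:
        raise ValueError(
            f"atlas covers {atlas.n_nodes} nodes but mask has {mask.n_nodes}")
    labels = atlas.labels(level)
    cats = list(dict.fromkeys(labels))  # first-appearance order
    pos = {c: k for k, c in enumerate(cats)}
    counts = np.zeros((len(cats), len(cats)), dtype=int)
    for i, j in mask.edge_list():
        a, b = pos[labels[i]], pos[labels[j]]
        counts[a, b] += 1
        if a != b:
            counts[b, a] += 1
    return pd.DataFrame(counts, index=cats, columns=cats)
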