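"""Group-level statistics around the predictive network.

Covers the follow-up analyses of the CPM stage: seed-based FC
comparison between patient subtypes (pooled-variance two-sample t with
Bonferroni correction), covariate-adjusted partial correlation between
an FC edge and clinical scores, and the demographic-table tests
(one-way ANOVA and pooled t from summary statistics, chi-square test of
independence). Summary-statistic forms exist so that published
mean/SD/n tables can be checked without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary", "SeedFCComparison", "PartialCorrResult",
    "seed_fc_compare", "partial_correlation", "anova_oneway_from_summary",
    "chi_square_independence", "t_test_from_summary", "bonferroni",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD and n of one variable in one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")


@dataclass(frozen=True)
class SeedFCComparison:
    seed: int
    target: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    df: int
    p_raw: float
    p_bonf: float
    family_size: int


@dataclass(frozen=True)
class PartialCorrResult:
    x_name: str
    y_name: str
    covariates: tuple[str, ...]
    n: int
    r_partial: float
    df: int
    p_raw: float
    p_bonf: float


def bonferroni(p_raw: float, m: int) -> float:
    """Family-wise corrected p: min(1, m * p_raw)."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if not 0 <= p_raw <= 1:
        raise ValueError("p_raw must lie in [0, 1]")
    return min(1.0, m * p_raw)


def t_test_from_summary(a: GroupSummary, b: GroupSummary,
                        welch: bool = False) -> tuple[float, float, float]:
    """Independent-samples t-test from group summaries.

    Pooled-variance (Student) by default, with ``df = n_a + n_b - 2``;
    set ``welch=True`` for the unequal-variance form.
    """
    if a.sd == 0 and b.sd == 0 and a.mean == b.mean:
        raise ValueError("degenerate test: both groups constant and equal")
    res = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                   equal_var=not welch)
    df = a.n + b.n - 2 if not welch else res.df
    return float(res.statistic), float(df), float(res.pvalue)


def anova_oneway_from_summary(groups: list[GroupSummary]
                              ) -> tuple[float, int, int, float]:
    """One-way ANOVA (F, df_between, df_within, p) from group summaries.

    ``F = MSB / MSW`` with the between-group sum of squares taken over
    n-weighted group means around the grand mean and the within-group
    sum of squares as ``sum (n_i - 1) s_i^2``.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    N = ns.sum()
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds ** 2).sum())
    df_b = len(groups) - 1
    df_w = int(N) - len(groups)
    if ssw == 0:
        raise ValueError("within-group variance is zero; F undefined")
    F = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return float(F), df_b, df_w, p


def chi_square_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction; expected counts come from the margins and
    must all be positive.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin; expected counts undefined")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        covariates: np.ndarray | None = None,
                        x_name: str = "x", y_name: str = "y",
                        covariate_names: tuple[str, ...] = (),
                        family_size: int = 1) -> PartialCorrResult:
    """Covariate-adjusted correlation between ``x`` and ``y``.

    Both variables are residualized on the covariates (plus intercept)
    by least squares; the partial r is the Pearson correlation of the
    residuals, with significance from the t transform on
    ``df = n - 2 - k`` for ``k`` covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    k = Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    coef_x, _, _, _ = np.linalg.lstsq(design, x, rcond=None)
    coef_y, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ coef_x
    ry = y - design @ coef_y
    if np.allclose(rx, 0, atol=1e-12) or np.allclose(ry, 0, atol=1e-12):
        raise ValueError("variable constant after residualization")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r * r))
        p = float(2 * sps.t.sf(abs(t), df))
    return PartialCorrResult(x_name, y_name, tuple(covariate_names), n,
                             r, df, p, bonferroni(p, family_size))


def seed_fc_compare(cohort, seeds, groups=("melancholic", "non_melancholic"),
                    family_size: int | None = None,
                    welch: bool = False) -> list[SeedFCComparison]:
    """Seed-to-whole-brain FC comparison between two groups.

    For every seed node and every other node, the per-subject FC value
    is compared between the groups with a pooled-variance two-sample
    t-test; Bonferroni correction uses ``family_size`` (default: the
    number of tests actually performed). Rows are sorted by raw p
    ascending (ties by seed, then target).
    """
    ga, gb = groups
    cohort_a = cohort.select([ga])
    cohort_b = cohort.select([gb])
    na, nb = len(cohort_a.subjects), len(cohort_b.subjects)
    if na < 2 or nb < 2:
        raise ValueError(f"both groups need >= 2 subjects (got {na}, {nb})")
    n_nodes = cohort.n_nodes
    seeds = [int(s) for s in seeds]
    for s in seeds:
        if not 0 <= s < n_nodes:
            raise ValueError(f"seed node {s} outside atlas (0..{n_nodes - 1})")

    fc_a = np.stack([s.fc_matrix().values for s in cohort_a.subjects])
    fc_b = np.stack([s.fc_matrix().values for s in cohort_b.subjects])

    rows: list[tuple[int, int, float, float, float, float]] = []
    tested = set()
    for seed in seeds:
        for target in range(n_nodes):
            if target == seed or (min(seed, target), max(seed, target)) in tested:
                continue
            tested.add((min(seed, target), max(seed, target)))
            rows.append((seed, target))
    a_vals = np.stack([fc_a[:, s, t] for s, t in rows], axis=1)  # (na, m)
    b_vals = np.stack([fc_b[:, s, t] for s, t in rows], axis=1)
    res = sps.ttest_ind(a_vals, b_vals, axis=0, equal_var=not welch)
    m = family_size if family_size is not None else len(rows)
    df = na + nb - 2
    out = []
    for idx, (seed, target) in enumerate(rows):
        p_raw = float(res.pvalue[idx])
        out.append(SeedFCComparison(
            seed=seed, target=target,
            mean_a=float(a_vals[:, idx].mean()), sd_a=float(a_vals[:, idx].std(ddof=1)),
            mean_b=float(b_vals[:, idx].mean()), sd_b=float(b_vals[:, idx].std(ddof=1)),
            t=float(res.statistic[idx]),
            df=int(df if not welch else res.df[idx]),
            p_raw=p_raw, p_bonf=bonferroni(p_raw, m), family_size=m))
    out.sort(key=lambda rec: (rec.p_raw, rec.seed, rec.target))
    return out
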