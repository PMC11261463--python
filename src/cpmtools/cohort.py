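"""Seeded synthetic cohorts with planted connectome-behavior structure.

The generator emulates the statistical design of a three-group
resting-state study: melancholic MDD (n=31), non-melancholic MDD (n=28)
and healthy controls (n=32), each subject carrying a 246-node FC matrix,
TEPS/HAMD behavioral scores and nuisance covariates. A configurable set
of "planted" edges (default 26, concentrated on two hub nodes) is made
to correlate with one behavioral score across patients, and one edge
carries a standardized mean difference between the two patient
subtypes. Everything downstream — edge selection, cross-validated
prediction, seed-based group comparison, classification — can then be
validated against known ground truth.

FC is generated directly at the edge level::

    edge = base + beta * z(behavior) + noise,   clipped to (-1, 1)

with ``beta = noise_sd * r / sqrt(1 - r^2)`` so that the edge-behavior
correlation is ``r`` in expectation. An optional time-series mode draws
node signals from the nearest-PSD completion of the target correlation
matrix, so that Pearson FC approximately realizes the planted values.
Subject FC matrices are not forced positive definite in edge mode; the
analyses consume edge values only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import Atlas, synthetic_atlas
from .connectome import (
    FCMatrix, devectorize, fc_from_timeseries, n_edges, pair_to_flat,
    vectorize_edges,
)

__all__ = [
    "CohortSpec", "Subject", "Cohort", "CohortSpecError",
    "generate_cohort", "write_cohort", "read_cohort",
    "default_planted_edges", "PATIENT_GROUPS", "GROUPS",
    "BEHAVIOR_STATS", "COVARIATE_STATS", "SEX_MALE_COUNTS",
]

GROUPS = ("melancholic", "non_melancholic", "control")
PATIENT_GROUPS = ("melancholic", "non_melancholic")

# Per-group (mean, SD) of each behavioral score, matching the study's
# demographic table; order: melancholic, non_melancholic, control.
BEHAVIOR_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "hamd": {"melancholic": (21.77, 3.79), "non_melancholic": (21.00, 3.14),
             "control": (0.94, 0.95)},
    "teps_anticipatory": {"melancholic": (26.30, 7.83),
                          "non_melancholic": (33.71, 5.91),
                          "control": (35.13, 6.11)},
    "teps_abstract_anticipatory": {"melancholic": (13.17, 4.71),
                                   "non_melancholic": (17.04, 3.85),
                                   "control": (19.94, 2.70)},
    "teps_contextual_anticipatory": {"melancholic": (13.13, 3.90),
                                     "non_melancholic": (16.68, 3.64),
                                     "control": (15.19, 4.31)},
    "teps_consummatory": {"melancholic": (32.00, 7.34),
                          "non_melancholic": (35.75, 7.12),
                          "control": (42.53, 6.63)},
    "teps_abstract_consummatory": {"melancholic": (20.20, 5.12),
                                   "non_melancholic": (22.39, 5.28),
                                   "control": (26.78, 4.23)},
    "teps_contextual_consummatory": {"melancholic": (11.80, 3.18),
                                     "non_melancholic": (13.36, 3.27),
                                     "control": (15.75, 3.65)},
    "teps_total": {"melancholic": (58.30, 13.95),
                   "non_melancholic": (69.46, 11.16),
                   "control": (77.66, 11.60)},
}

COVARIATE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"melancholic": (28.65, 5.30), "non_melancholic": (32.04, 8.18),
            "control": (29.59, 5.00)},
    "education": {"melancholic": (15.16, 3.195),
                  "non_melancholic": (12.54, 3.00), "control": (14.59, 2.82)},
    "illness_duration": {"melancholic": (6.75, 4.26),
                         "non_melancholic": (5.96, 4.64),
                         "control": (0.0, 0.0)},
    "fd": {"melancholic": (0.05, 0.03), "non_melancholic": (0.04, 0.02),
           "control": (0.05, 0.02)},
}

SEX_MALE_COUNTS = {"melancholic": 10, "non_melancholic": 10, "control": 15}

# valid ranges for truncated-Gaussian score generation (scale bounds)
_RANGES: dict[str, tuple[float, float]] = {
    "hamd": (0.0, 52.0),
    "teps_anticipatory": (10.0, 60.0),
    "teps_abstract_anticipatory": (5.0, 30.0),
    "teps_contextual_anticipatory": (5.0, 30.0),
    "teps_consummatory": (8.0, 48.0),
    "teps_abstract_consummatory": (4.0, 34.0),
    "teps_contextual_consummatory": (4.0, 26.0),
    "teps_total": (18.0, 108.0),
    "age": (18.0, 65.0),
    "education": (0.0, 25.0),
    "illness_duration": (0.0, 360.0),
    "fd": (0.005, 1.0),
}

BEHAVIOR_NAMES = tuple(BEHAVIOR_STATS)
COVARIATE_NAMES = ("age", "sex", "education", "illness_duration", "fd")


class CohortSpecError(ValueError):
    """Invalid cohort specification; the message names the offending field."""


def default_planted_edges(atlas: Atlas, n_edges_total: int = 26
                          ) -> tuple[list[tuple[int, int]], tuple[int, int],
                                     tuple[int, int]]:
    """Default planted-edge layout mirroring the study's positive network.

    Returns ``(edges, (hub_a, hub_b), subtype_edge)``: 26 unordered node
    pairs with 9 incident to a right inferior-temporal hub and 7 to a
    right parahippocampal hub (both above the degree-5 hub threshold),
    the remainder scattered over non-hub nodes. The subtype-difference
    edge joins the parahippocampal hub to a left cingulate node.
    """
    itg_r = atlas.find("ITG", "R")
    phg_r = atlas.find("PhG", "R")
    cg_l = atlas.find("CG", "L")
    if not (len(itg_r) and len(phg_r) and len(cg_l)):
        raise CohortSpecError("planted_positive_edges: atlas lacks ITG_R/PhG_R/CG_L nodes")
    hub_a, hub_b = int(itg_r[0]), int(phg_r[0])
    cg = int(cg_l[0])
    n = atlas.n_nodes
    used = {hub_a, hub_b, cg}

    def take(k: int, exclude: set[int]) -> list[int]:
        out = []
        for cand in range(n):
            if cand not in exclude and cand not in used:
                out.append(cand)
                used.add(cand)
                if len(out) == k:
                    break
        return out

    deg_a = min(9, n_edges_total)
    deg_b = min(7, max(0, n_edges_total - deg_a))
    edges = [(hub_a, p) for p in take(deg_a, {hub_a})]
    partners_b = [cg] + take(deg_b - 1, {hub_b}) if deg_b else []
    edges += [(hub_b, p) for p in partners_b]
    rest = n_edges_total - len(edges)
    fillers = take(2 * rest, set())
    edges += [(fillers[2 * k], fillers[2 * k + 1]) for k in range(rest)]
    edges = [(min(i, j), max(i, j)) for i, j in edges]
    return edges, (hub_a, hub_b), (min(hub_b, cg), max(hub_b, cg))


@dataclass
class CohortSpec:
    """Parameters of the synthetic study design (defaults = study conditions)."""

    n_nodes: int = 246
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"melancholic": 31, "non_melancholic": 28,
                                 "control": 32})
    behavior_stats: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in BEHAVIOR_STATS.items()})
    covariate_stats: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in COVARIATE_STATS.items()})
    sex_male_counts: dict[str, int] = field(
        default_factory=lambda: dict(SEX_MALE_COUNTS))
    planted_positive_edges: list[tuple[int, int]] | None = None  # None -> default layout
    behavior_target: str = "teps_abstract_consummatory"
    edge_behavior_r: float = 0.5
    subtype_diff_edge: tuple[int, int] | None = None  # None -> hub-b <-> CG_L analog
    subtype_diff_d: float = 1.0
    base_fc: float = 0.1
    planted_base_fc: float = 0.3
    noise_sd: float = 0.2
    time_series_mode: bool = False
    n_timepoints: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise CohortSpecError("n_nodes: must be >= 2")
        for g, sz in self.group_sizes.items():
            if g not in GROUPS:
                raise CohortSpecError(f"group_sizes: unknown group {g!r}")
            if sz < 2:
                raise CohortSpecError(f"group_sizes: group {g!r} must have >= 2 subjects")
        if not 0 <= abs(self.edge_behavior_r) < 1:
            raise CohortSpecError("edge_behavior_r: |r| must be < 1")
        if self.noise_sd <= 0:
            raise CohortSpecError("noise_sd: must be > 0")
        if self.behavior_target not in self.behavior_stats:
            raise CohortSpecError(f"behavior_target: unknown score {self.behavior_target!r}")
        for score, per_group in self.behavior_stats.items():
            for g, (_, sd) in per_group.items():
                if sd <= 0:
                    raise CohortSpecError(f"behavior_stats: SD for {score}/{g} must be > 0")
        edges = self.planted_positive_edges
        if edges is not None:
            seen = set()
            for i, j in edges:
                if i == j:
                    raise CohortSpecError("planted_positive_edges: self-loop "
                                          f"({i}, {j}) not allowed")
                key = (min(i, j), max(i, j))
                if key in seen:
                    raise CohortSpecError(f"planted_positive_edges: duplicate edge {key}")
                seen.add(key)
                if max(i, j) >= self.n_nodes or min(i, j) < 0:
                    raise CohortSpecError(f"planted_positive_edges: edge {key} out of "
                                          f"range for n_nodes={self.n_nodes}")
        if self.subtype_diff_edge is not None:
            i, j = self.subtype_diff_edge
            if i == j or max(i, j) >= self.n_nodes or min(i, j) < 0:
                raise CohortSpecError("subtype_diff_edge: invalid node pair")
        if self.time_series_mode and self.n_timepoints < 3:
            raise CohortSpecError("n_timepoints: must be >= 3")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["planted_positive_edges"] = (
            None if self.planted_positive_edges is None
            else [list(e) for e in self.planted_positive_edges])
        d["subtype_diff_edge"] = (
            None if self.subtype_diff_edge is None else list(self.subtype_diff_edge))
        d["behavior_stats"] = {s: {g: list(ms) for g, ms in pg.items()}
                               for s, pg in d["behavior_stats"].items()}
        d["covariate_stats"] = {s: {g: list(ms) for g, ms in pg.items()}
                                for s, pg in d["covariate_stats"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("planted_positive_edges") is not None:
            d["planted_positive_edges"] = [tuple(e) for e in d["planted_positive_edges"]]
        if d.get("subtype_diff_edge") is not None:
            d["subtype_diff_edge"] = tuple(d["subtype_diff_edge"])
        for key in ("behavior_stats", "covariate_stats"):
            if key in d:
                d[key] = {s: {g: tuple(ms) for g, ms in pg.items()}
                          for s, pg in d[key].items()}
        return cls(**d)


@dataclass
class Subject:
    """One participant: group label, scores, covariates, and FC data."""

    id: str
    group: str
    behavior: dict[str, float]
    covariates: dict[str, float]
    fc: FCMatrix | None = None
    time_series: np.ndarray | None = None

    def fc_matrix(self) -> FCMatrix:
        """FC, computing it from the time series when necessary."""
        if self.fc is not None:
            return self.fc
        if self.time_series is None:
            raise ValueError(f"subject {self.id}: neither fc nor time_series present")
        return fc_from_timeseries(self.time_series)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Subject):
            return NotImplemented
        ts_eq = ((self.time_series is None) == (other.time_series is None)) and (
            self.time_series is None
            or np.array_equal(self.time_series, other.time_series))
        return (self.id == other.id and self.group == other.group
                and self.behavior == other.behavior
                and self.covariates == other.covariates
                and self.fc == other.fc and ts_eq)


class Cohort:
    """Subjects plus the atlas they are parcellated with."""

    def __init__(self, subjects: list[Subject], atlas: Atlas,
                 spec: CohortSpec | None = None):
        self.subjects = list(subjects)
        self.atlas = atlas
        self.spec = spec

    def __len__(self) -> int:
        return len(self.subjects)

    def __eq__(self, other) -> bool:
        return (isinstance(other, Cohort) and self.subjects == other.subjects
                and self.atlas == other.atlas)

    @property
    def n_nodes(self) -> int:
        return self.atlas.n_nodes

    def select(self, groups) -> "Cohort":
        groups = set(groups)
        return Cohort([s for s in self.subjects if s.group in groups],
                      self.atlas, self.spec)

    def patients(self) -> "Cohort":
        return self.select(PATIENT_GROUPS)

    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    def group_labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def behavior_vector(self, name: str) -> np.ndarray:
        try:
            return np.array([s.behavior[name] for s in self.subjects], dtype=float)
        except KeyError as exc:
            raise KeyError(f"behavioral score {name!r} missing for some subject") from exc

    def covariate_matrix(self, names) -> np.ndarray:
        return np.column_stack([
            np.array([s.covariates[c] for s in self.subjects], dtype=float)
            for c in names])

    def edge_matrix(self) -> np.ndarray:
        """Subjects-by-edges matrix of vectorized FC values."""
        return np.vstack([vectorize_edges(s.fc_matrix()) for s in self.subjects])

    def edge_values(self, i: int, j: int) -> np.ndarray:
        """Per-subject FC value of the unordered edge {i, j}."""
        return np.array([s.fc_matrix().values[i, j] for s in self.subjects])


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    """Gaussian draws redrawn into [lo, hi] (clipped after 100 rounds)."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, lo, hi)


def _nearest_corr(c: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Nearest (eigenvalue-clipped) PSD matrix, rescaled to unit diagonal."""
    w, v = np.linalg.eigh(c)
    c2 = (v * np.maximum(w, eps)) @ v.T
    d = np.sqrt(np.diag(c2))
    c2 = c2 / np.outer(d, d)
    np.fill_diagonal(c2, 1.0)
    return c2


def generate_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Generate a seeded synthetic cohort per ``spec`` (default = study design)."""
    spec = spec if spec is not None else CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    atlas = synthetic_atlas(spec.n_nodes)

    if spec.planted_positive_edges is None:
        planted, _, default_subtype = default_planted_edges(atlas)
    else:
        planted = [(min(i, j), max(i, j)) for i, j in spec.planted_positive_edges]
        default_subtype = None
    subtype_edge = spec.subtype_diff_edge
    if subtype_edge is None:
        subtype_edge = default_subtype  # may stay None with custom planted edges
    # materialize the resolved design on the spec copy carried by the cohort
    spec = dataclasses.replace(spec, planted_positive_edges=planted,
                               subtype_diff_edge=subtype_edge)

    groups_per_subject: list[str] = []
    for g in GROUPS:
        groups_per_subject += [g] * spec.group_sizes.get(g, 0)
    n_sub = len(groups_per_subject)
    ids = [f"sub-{k:03d}" for k in range(n_sub)]
    group_arr = np.array(groups_per_subject)

    behavior: dict[str, np.ndarray] = {}
    for score, per_group in spec.behavior_stats.items():
        lo, hi = _RANGES.get(score, (-np.inf, np.inf))
        vals = np.empty(n_sub)
        for g in GROUPS:
            m = group_arr == g
            if not m.any():
                continue
            mean, sd = per_group[g]
            vals[m] = _truncated_normal(rng, mean, sd, lo, hi, int(m.sum()))
        behavior[score] = vals

    covariates: dict[str, np.ndarray] = {}
    for cov, per_group in spec.covariate_stats.items():
        lo, hi = _RANGES.get(cov, (-np.inf, np.inf))
        vals = np.empty(n_sub)
        for g in GROUPS:
            m = group_arr == g
            if not m.any():
                continue
            mean, sd = per_group[g]
            vals[m] = _truncated_normal(rng, mean, sd, lo, hi, int(m.sum()))
        covariates[cov] = vals
    sex = np.zeros(n_sub)
    for g in GROUPS:
        m = np.flatnonzero(group_arr == g)
        if not m.size:
            continue
        p_male = spec.sex_male_counts.get(g, 0) / m.size
        sex[m] = (rng.random(m.size) < p_male).astype(float)
    covariates["sex"] = sex

    # behavior z-scored over patients: planted correlations are a patient-level
    # property (controls inherit the same mapping)
    y = behavior[spec.behavior_target]
    pat = np.isin(group_arr, PATIENT_GROUPS)
    ref = y[pat] if pat.any() else y
    z = (y - ref.mean()) / ref.std(ddof=0)

    E = n_edges(spec.n_nodes)
    X = spec.base_fc + spec.noise_sd * rng.standard_normal((n_sub, E))
    r = spec.edge_behavior_r
    beta = spec.noise_sd * r / np.sqrt(1.0 - r * r)
    planted_flat = np.array(
        [pair_to_flat(i, j, spec.n_nodes) for i, j in planted], dtype=int)
    if planted_flat.size:
        X[:, planted_flat] += (spec.planted_base_fc - spec.base_fc
                               + beta * z[:, None])
    if subtype_edge is not None and spec.subtype_diff_d != 0:
        k = pair_to_flat(*subtype_edge, spec.n_nodes)
        # d is expressed in units of the edge's residual noise SD
        delta = spec.subtype_diff_d * spec.noise_sd
        X[group_arr == "melancholic", k] -= delta / 2
        X[group_arr == "non_melancholic", k] += delta / 2
    X = np.clip(X, -0.999, 0.999)

    subjects = []
    for k, (sid, g) in enumerate(zip(ids, groups_per_subject)):
        beh = {s: float(behavior[s][k]) for s in spec.behavior_stats}
        cov = {c: float(covariates[c][k]) for c in COVARIATE_NAMES
               if c in covariates}
        fc = devectorize(X[k], spec.n_nodes)
        if spec.time_series_mode:
            target = _nearest_corr(fc.values)
            L = np.linalg.cholesky(target + 1e-10 * np.eye(spec.n_nodes))
            ts = L @ rng.standard_normal((spec.n_nodes, spec.n_timepoints))
            subjects.append(Subject(sid, g, beh, cov, fc=None, time_series=ts))
        else:
            subjects.append(Subject(sid, g, beh, cov, fc=fc))
    return Cohort(subjects, atlas, spec)


# ---------------------------------------------------------------------------
# cohort directory I/O: subjects.tsv + atlas.tsv + fc_<id>.tsv / ts_<id>.tsv
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, directory: str | Path) -> list[Path]:
    """Write a cohort as plain TSV files; returns the files written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    rows = []
    for s in cohort.subjects:
        row = {"id": s.id, "group": s.group}
        row.update({k: s.behavior[k] for k in sorted(s.behavior)})
        row.update({k: s.covariates[k] for k in sorted(s.covariates)})
        rows.append(row)
    subjects_path = directory / "subjects.tsv"
    pd.DataFrame(rows).to_csv(subjects_path, sep="\t", index=False,
                              float_format="%.17g")
    written.append(subjects_path)
    atlas_path = directory / "atlas.tsv"
    cohort.atlas.to_tsv(atlas_path)
    written.append(atlas_path)
    for s in cohort.subjects:
        if s.time_series is not None:
            p = directory / f"ts_{s.id}.tsv"
            np.savetxt(p, s.time_series, delimiter="\t", fmt="%.17g")
        else:
            p = directory / f"fc_{s.id}.tsv"
            np.savetxt(p, s.fc_matrix().values, delimiter="\t", fmt="%.17g")
        written.append(p)
    if cohort.spec is not None:
        p = directory / "spec.yaml"
        cohort.spec.to_yaml(p)
        written.append(p)
    return written


def read_cohort(directory: str | Path) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    subjects_path = directory / "subjects.tsv"
    if not subjects_path.exists():
        raise FileNotFoundError(f"{subjects_path}: no subjects table")
    df = pd.read_csv(subjects_path, sep="\t", float_precision="round_trip")
    for col in ("id", "group"):
        if col not in df.columns:
            raise ValueError(f"{subjects_path}: missing column {col!r}")
    missing_cov = [c for c in COVARIATE_NAMES if c not in df.columns]
    if missing_cov:
        raise ValueError(f"{subjects_path}: missing covariate column(s) {missing_cov}")
    atlas = Atlas.from_tsv(directory / "atlas.tsv")
    behavior_cols = [c for c in df.columns
                     if c not in ("id", "group") and c not in COVARIATE_NAMES]
    subjects = []
    for _, row in df.iterrows():
        sid = str(row["id"])
        beh = {c: float(row[c]) for c in behavior_cols}
        cov = {c: float(row[c]) for c in COVARIATE_NAMES}
        fc_path = directory / f"fc_{sid}.tsv"
        ts_path = directory / f"ts_{sid}.tsv"
        fc = ts = None
        if fc_path.exists():
            vals = np.loadtxt(fc_path, delimiter="\t", ndmin=2)
            try:
                fc = FCMatrix(vals)
            except ValueError as exc:
                raise ValueError(f"{fc_path}: {exc}") from exc
        elif ts_path.exists():
            ts = np.loadtxt(ts_path, delimiter="\t", ndmin=2)
        else:
            raise FileNotFoundError(
                f"subject {sid}: neither fc_{sid}.tsv nor ts_{sid}.tsv in {directory}")
        subjects.append(Subject(sid, str(row["group"]), beh, cov,
                                fc=fc, time_series=ts))
    spec = None
    spec_path = directory / "spec.yaml"
    if spec_path.exists():
        spec = CohortSpec.from_yaml(spec_path)
    return Cohort(subjects, atlas, spec)
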