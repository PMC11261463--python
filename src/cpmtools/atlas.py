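"""Synthetic 246-node brain parcellation table.

Emulates a whole-brain atlas with 210 cortical and 36 subcortical
subregions, 7 lobes, 24 gyri, and a 7-network functional division, so
that atlas-level summaries (lobe-by-lobe / gyrus-by-gyrus edge counts)
can be exercised without any imaging data. The node table is synthetic:
names and block sizes follow the conventional gyrus abbreviations, but
no anatomical coordinates or image registration are involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AtlasNode", "Atlas", "synthetic_atlas", "LOBES", "GYRI", "NETWORKS"]

LOBES = (
    "Frontal", "Temporal", "Parietal", "Insular", "Limbic", "Occipital",
    "Subcortical",
)

# gyrus -> (lobe, number of subregions); cortical blocks alternate L/R
GYRI: dict[str, tuple[str, int]] = {
    "SFG": ("Frontal", 14), "MFG": ("Frontal", 14), "IFG": ("Frontal", 12),
    "OrG": ("Frontal", 12), "PrG": ("Frontal", 12), "PCL": ("Frontal", 4),
    "STG": ("Temporal", 12), "MTG": ("Temporal", 8), "ITG": ("Temporal", 14),
    "FuG": ("Temporal", 6), "PhG": ("Temporal", 12), "pSTS": ("Temporal", 4),
    "SPL": ("Parietal", 10), "IPL": ("Parietal", 12), "Pcun": ("Parietal", 8),
    "PoG": ("Parietal", 8),
    "INS": ("Insular", 12),
    "CG": ("Limbic", 14),
    "MVOcC": ("Occipital", 10), "LOcC": ("Occipital", 12),
    "Amyg": ("Subcortical", 4), "Hipp": ("Subcortical", 4),
    "BG": ("Subcortical", 12), "Tha": ("Subcortical", 16),
}

NETWORKS = (
    "Visual", "Somatomotor", "DorsalAttention", "VentralAttention",
    "Limbic", "Frontoparietal", "Default",
)

_COLUMNS = ["node_index", "name", "hemisphere", "lobe", "gyrus", "network"]


@dataclass(frozen=True)
class AtlasNode:
    index: int
    name: str
    hemisphere: str
    lobe: str
    gyrus: str
    network: str


class Atlas:
    """Node table with closed lobe/gyrus/network vocabularies.

    Node indices are 0-based, unique, and contiguous.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"atlas table missing column(s) {missing}")
        df = df[_COLUMNS].sort_values("node_index").reset_index(drop=True)
        idx = df["node_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(df))):
            raise ValueError("node indices must be unique and contiguous from 0")
        for col, vocab in (("lobe", LOBES), ("network", NETWORKS)):
            bad = set(df[col]) - set(vocab)
            if bad:
                raise ValueError(f"unknown {col} label(s) {sorted(bad)}")
        bad = set(df["gyrus"]) - set(GYRI)
        if bad:
            raise ValueError(f"unknown gyrus label(s) {sorted(bad)}")
        self.df = df

    @property
    def n_nodes(self) -> int:
        return len(self.df)

    def node(self, index: int) -> AtlasNode:
        row = self.df.iloc[index]
        return AtlasNode(int(row.node_index), row["name"], row.hemisphere,
                         row.lobe, row.gyrus, row.network)

    def labels(self, level: str) -> np.ndarray:
        """Per-node labels for ``level`` in {'lobe', 'gyrus', 'network'}."""
        if level not in ("lobe", "gyrus", "network"):
            raise ValueError(f"unknown atlas level {level!r}")
        return self.df[level].to_numpy()

    def find(self, gyrus: str, hemisphere: str | None = None) -> np.ndarray:
        """Node indices of a gyrus, optionally restricted to one hemisphere."""
        m = self.df["gyrus"] == gyrus
        if hemisphere is not None:
            m &= self.df["hemisphere"] == hemisphere
        return self.df.loc[m, "node_index"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Atlas":
        try:
            df = pd.read_csv(path, sep="\t")
        except Exception as exc:  # pragma: no cover - message passthrough
            raise ValueError(f"could not parse atlas table {path}: {exc}") from exc
        return cls(df)

    def __eq__(self, other) -> bool:
        return isinstance(other, Atlas) and self.df.equals(other.df)


def synthetic_atlas(n_nodes: int = 246) -> Atlas:
    """Deterministic synthetic parcellation of ``n_nodes`` regions.

    For the default 246 nodes every gyrus receives its conventional
    subregion count; for smaller test parcellations the gyrus blocks are
    truncated proportionally (each gyrus keeps at least one L/R pair
    while nodes remain). Hemispheres alternate L, R within each block;
    functional-network labels cycle through the 7-network vocabulary.
    """
    if n_nodes < 2 * len(GYRI):
        raise ValueError(f"n_nodes must be >= {2 * len(GYRI)} to cover every gyrus")
    sizes = {g: c for g, (_, c) in GYRI.items()}
    if n_nodes != 246:
        scale = n_nodes / 246
        sizes = {g: max(2, 2 * round(c * scale / 2)) for g, c in sizes.items()}
        # trim/pad the largest blocks to hit n_nodes exactly
        order = sorted(sizes, key=lambda g: -sizes[g])
        k = 0
        while sum(sizes.values()) > n_nodes:
            g = order[k % len(order)]
            if sizes[g] > 2:
                sizes[g] -= 1
            k += 1
        k = 0
        while sum(sizes.values()) < n_nodes:
            sizes[order[k % len(order)]] += 1
            k += 1
    rows = []
    idx = 0
    for gyrus, (lobe, _) in GYRI.items():
        for sub in range(sizes[gyrus]):
            hemi = "L" if sub % 2 == 0 else "R"
            rows.append({
                "node_index": idx,
                "name": f"{gyrus}_{hemi}_{sub // 2 + 1}",
                "hemisphere": hemi,
                "lobe": lobe,
                "gyrus": gyrus,
                "network": NETWORKS[idx % len(NETWORKS)],
            })
            idx += 1
    return Atlas(pd.DataFrame(rows))
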