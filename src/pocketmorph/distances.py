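"""Continuous morphometric distances in the 3-ratio space.

Similarity between pockets is the unweighted Euclidean distance between
their (rEV21, rEV32, rEV31) vectors.  rEV31 is algebraically the product of
the other two ratios but is kept in the vector so that overall anisotropy is
represented continuously; no reweighting is applied.

Block summaries mirror an 8x8 layout of (archetype x group) cells: diagonal
blocks are mean distances over unordered distinct pairs within a cell,
off-diagonal blocks are means over all cross pairs.  Group-level summaries
(within group 1, within group 2, between groups) report mean, SD and the 5th
percentile (linear-interpolation quantile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

RATIO_COLUMNS = ["rEV21", "rEV32", "rEV31"]


@dataclass
class DistanceSummary:
    """Block-mean distance matrix plus per-group distance distributions."""

    block_means: pd.DataFrame  # (archetype, group) x (archetype, group)
    block_counts: pd.DataFrame
    group_stats: pd.DataFrame  # rows: within/between group pairs; cols: mean, sd, q05, n_pairs

    def to_csv(self, path) -> None:
        self.block_means.to_csv(path)


def ratio_distance(a, b) -> float:
    """Unweighted Euclidean distance between two ratio vectors.

    Accepts length-3 sequences or objects with rEV21/rEV32/rEV31 attributes.
    """
    va = _as_vector(a)
    vb = _as_vector(b)
    return float(np.linalg.norm(va - vb))


def _as_vector(x) -> np.ndarray:
    if hasattr(x, "rEV21"):
        return np.array([x.rEV21, x.rEV32, x.rEV31], dtype=float)
    if isinstance(x, (pd.Series, dict)):
        return np.array([x["rEV21"], x["rEV32"], x["rEV31"]], dtype=float)
    return np.asarray(x, dtype=float)


def pairwise_distances(points: pd.DataFrame) -> np.ndarray:
    """Full symmetric pairwise distance matrix over the ratio columns."""
    vecs = points[RATIO_COLUMNS].to_numpy(dtype=float)
    return squareform(pdist(vecs, metric="euclidean"))


def distance_summary(
    points: pd.DataFrame,
    group_col: str = "group",
    archetype_col: str = "archetype",
) -> DistanceSummary:
    """Intra-/inter-cell mean distances over (archetype, group) cells.

    ``points`` needs the three ratio columns plus group and archetype labels.
    Cells with fewer than one distinct pair have undefined (NaN) diagonal
    entries.  Self-pairs are always excluded.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    dmat = pairwise_distances(points)
    groups = list(pd.unique(points[group_col]))
    archetypes = list(pd.unique(points[archetype_col]))
    cells = [(a, g) for a in archetypes for g in groups]
    idx = {
        cell: np.flatnonzero(
            (points[archetype_col] == cell[0]).to_numpy()
            & (points[group_col] == cell[1]).to_numpy()
        )
        for cell in cells
    }

    labels = pd.MultiIndex.from_tuples(cells, names=["archetype", "group"])
    means = pd.DataFrame(np.nan, index=labels, columns=labels)
    counts = pd.DataFrame(0, index=labels, columns=labels)
    for i, ci in enumerate(cells):
        for j, cj in enumerate(cells):
            ii, jj = idx[ci], idx[cj]
            if i == j:
                if len(ii) < 2:
                    continue
                sub = dmat[np.ix_(ii, ii)]
                vals = sub[np.triu_indices(len(ii), k=1)]
            else:
                if len(ii) == 0 or len(jj) == 0:
                    continue
                vals = dmat[np.ix_(ii, jj)].ravel()
            means.iloc[i, j] = vals.mean()
            counts.iloc[i, j] = vals.size

    group_stats = _group_stats(points, dmat, group_col)
    return DistanceSummary(block_means=means, block_counts=counts, group_stats=group_stats)


def _group_stats(points: pd.DataFrame, dmat: np.ndarray, group_col: str) -> pd.DataFrame:
    groups = list(pd.unique(points[group_col]))
    rows = {}
    gidx = {g: np.flatnonzero((points[group_col] == g).to_numpy()) for g in groups}
    for gi in range(len(groups)):
        for gj in range(gi, len(groups)):
            a, b = groups[gi], groups[gj]
            ii, jj = gidx[a], gidx[b]
            if gi == gj:
                if len(ii) < 2:
                    continue
                vals = dmat[np.ix_(ii, ii)][np.triu_indices(len(ii), k=1)]
                name = f"{a}-{a}"
            else:
                vals = dmat[np.ix_(ii, jj)].ravel()
                name = f"{a}-{b}"
            if vals.size == 0:
                continue
            rows[name] = {
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if vals.size > 1 else np.nan,
                "q05": np.quantile(vals, 0.05),
                "n_pairs": vals.size,
            }
    return pd.DataFrame(rows).T
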