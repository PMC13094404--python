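"""Median-anchored shape archetypes and their bootstrap stability.

Pockets are partitioned in the (rEV21, rEV32) plane using the global medians
of the two ratios computed on the combined reference set.  With thresholds
(m21, m32), the decision tree assigns:

    rEV21 >= m21 and rEV32 >= m32  ->  sphere-like
    rEV21 <  m21 and rEV32 >= m32  ->  rod-like
    rEV21 >= m21 and rEV32 <  m32  ->  disk-like
    rEV21 <  m21 and rEV32 <  m32  ->  strongly anisotropic

"High" is >= the median (ties classify upward); this tie-break is covered by
a dedicated test.  The derived ratio rEV31 plays no role in assignment.

Partition stability under sampling variability is quantified by a stratified
bootstrap: each replicate resamples the two groups with replacement at their
original sizes, refits the medians on the pooled resample, and compares the
labels of the resampled pockets under the replicate's thresholds with their
labels under the original thresholds (adjusted Rand index and fraction
reclassified).  This pairing isolates the effect of threshold variability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

SPHERE = "sphere"
ROD = "rod"
DISK = "disk"
STRONGLY_ANISOTROPIC = "strongly_anisotropic"

ARCHETYPES = (SPHERE, ROD, DISK, STRONGLY_ANISOTROPIC)

#: Human-readable names used in reports.
ARCHETYPE_LABELS = {
    SPHERE: "sphere-like",
    ROD: "rod-like",
    DISK: "disk-like",
    STRONGLY_ANISOTROPIC: "strongly anisotropic",
}


@dataclass(frozen=True)
class DecisionThresholds:
    """The two global medians anchoring the archetype partition."""

    m21: float
    m32: float
    reference_n: int

    def __post_init__(self):
        if not (0 < self.m21 < 1 and 0 < self.m32 < 1):
            raise ValueError(f"thresholds must lie in (0, 1), got ({self.m21}, {self.m32})")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DecisionThresholds":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ArchetypeAssignment:
    pocket_id: str
    archetype: str
    rEV21: float
    rEV32: float
    boundary_margin: float


@dataclass(frozen=True)
class StabilityReport:
    """Aggregate bootstrap stability metrics for the archetype partition."""

    n_replicates: int
    ari_median: float
    ari_q025: float
    ari_q975: float
    frac_ari_ge_090: float
    frac_ari_ge_080: float
    median_reclassified_fraction: float
    threshold_sd_m21: float
    threshold_sd_m32: float
    seed: int
    #: per-replicate diagnostics (ari, reclassified_fraction, m21, m32);
    #: populated when keep_replicates=True
    replicates: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        out = asdict(self)
        out.pop("replicates")
        return out


def fit_thresholds(descriptors: pd.DataFrame) -> DecisionThresholds:
    """Global medians of rEV21 and rEV32 over the pooled descriptor table.

    Even-count medians are the midpoint of the two central order statistics
    (the numpy default).
    """
    if len(descriptors) < 2:
        raise ValueError("need at least 2 pockets to fit thresholds")
    m21 = float(np.median(descriptors["rEV21"].to_numpy()))
    m32 = float(np.median(descriptors["rEV32"].to_numpy()))
    return DecisionThresholds(m21=m21, m32=m32, reference_n=len(descriptors))


def classify_arrays(
    rev21: np.ndarray, rev32: np.ndarray, thresholds: DecisionThresholds
) -> np.ndarray:
    """Vectorized archetype labels for arrays of ratio pairs."""
    rev21 = np.asarray(rev21, dtype=float)
    rev32 = np.asarray(rev32, dtype=float)
    hi21 = rev21 >= thresholds.m21
    hi32 = rev32 >= thresholds.m32
    out = np.empty(rev21.shape, dtype=object)
    out[hi21 & hi32] = SPHERE
    out[~hi21 & hi32] = ROD
    out[hi21 & ~hi32] = DISK
    out[~hi21 & ~hi32] = STRONGLY_ANISOTROPIC
    return out.astype(str)


def classify(
    descriptors: "pd.Series | pd.DataFrame | object", thresholds: DecisionThresholds
) -> ArchetypeAssignment | list[ArchetypeAssignment]:
    """Assign one pocket (or every row of a table) to an archetype.

    Accepts a ShapeDescriptors record, a Series/mapping with ``rEV21`` and
    ``rEV32``, or a DataFrame (returns a list).
    """
    if isinstance(descriptors, pd.DataFrame):
        return [classify(row, thresholds) for _, row in descriptors.iterrows()]
    d = descriptors
    r21 = float(d["rEV21"] if isinstance(d, (pd.Series, dict)) else d.rEV21)
    r32 = float(d["rEV32"] if isinstance(d, (pd.Series, dict)) else d.rEV32)
    if isinstance(d, (pd.Series, dict)):
        pid = str(d.get("pocket_id", ""))
    else:
        pid = d.pocket_id
    label = classify_arrays(np.array([r21]), np.array([r32]), thresholds)[0]
    margin = min(abs(r21 - thresholds.m21), abs(r32 - thresholds.m32))
    return ArchetypeAssignment(
        pocket_id=pid, archetype=label, rEV21=r21, rEV32=r32, boundary_margin=margin
    )


def assign_table(descriptors: pd.DataFrame, thresholds: DecisionThresholds) -> pd.DataFrame:
    """Descriptor table augmented with ``archetype`` and ``boundary_margin``."""
    out = descriptors.copy()
    out["archetype"] = classify_arrays(
        descriptors["rEV21"].to_numpy(), descriptors["rEV32"].to_numpy(), thresholds
    )
    out["boundary_margin"] = np.minimum(
        np.abs(descriptors["rEV21"].to_numpy() - thresholds.m21),
        np.abs(descriptors["rEV32"].to_numpy() - thresholds.m32),
    )
    return out


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Hubert-Arabie adjusted Rand index between two labelings.

    1.0 for identical partitions (up to label permutation); expectation ~0
    for independent random labelings.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError(f"length mismatch: {labels_a.shape} vs {labels_b.shape}")
    if labels_a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(labels_a, labels_b))


def bootstrap_stability(
    descriptors: pd.DataFrame,
    group_col: str = "group",
    n_replicates: int = 1000,
    seed: int = 0,
    thresholds: DecisionThresholds | None = None,
    keep_replicates: bool = False,
) -> StabilityReport:
    """Stratified bootstrap of the median-based partition.

    Each replicate resamples every group with replacement at its original
    size, refits the thresholds on the pooled resample, and classifies the
    resampled pockets under both the replicate's and the reference
    thresholds.  Fully reproducible for a given ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    groups = descriptors[group_col].unique()
    strata = [descriptors[descriptors[group_col] == g] for g in groups]
    if any(len(s) == 0 for s in strata):
        raise ValueError("every stratum must be non-empty")
    reference = thresholds or fit_thresholds(descriptors)

    rng = np.random.default_rng(seed)
    r21 = [s["rEV21"].to_numpy() for s in strata]
    r32 = [s["rEV32"].to_numpy() for s in strata]

    aris = np.empty(n_replicates)
    reclassified = np.empty(n_replicates)
    m21s = np.empty(n_replicates)
    m32s = np.empty(n_replicates)
    for b in range(n_replicates):
        idx = [rng.integers(0, len(a), size=len(a)) for a in r21]
        boot21 = np.concatenate([a[i] for a, i in zip(r21, idx)])
        boot32 = np.concatenate([a[i] for a, i in zip(r32, idx)])
        bt = DecisionThresholds(
            m21=float(np.median(boot21)),
            m32=float(np.median(boot32)),
            reference_n=boot21.size,
        )
        ref_labels = classify_arrays(boot21, boot32, reference)
        boot_labels = classify_arrays(boot21, boot32, bt)
        aris[b] = adjusted_rand_score(ref_labels, boot_labels)
        reclassified[b] = np.mean(ref_labels != boot_labels)
        m21s[b], m32s[b] = bt.m21, bt.m32

    return StabilityReport(
        n_replicates=n_replicates,
        ari_median=float(np.median(aris)),
        ari_q025=float(np.quantile(aris, 0.025)),
        ari_q975=float(np.quantile(aris, 0.975)),
        frac_ari_ge_090=float(np.mean(aris >= 0.90)),
        frac_ari_ge_080=float(np.mean(aris >= 0.80)),
        median_reclassified_fraction=float(np.median(reclassified)),
        threshold_sd_m21=float(np.std(m21s, ddof=1)) if n_replicates > 1 else 0.0,
        threshold_sd_m32=float(np.std(m32s, ddof=1)) if n_replicates > 1 else 0.0,
        seed=seed,
        replicates=(
            pd.DataFrame(
                {"ari": aris, "reclassified_fraction": reclassified, "m21": m21s, "m32": m32s}
            )
            if keep_replicates
            else None
        ),
    )


def archetype_frequencies(
    assignments: pd.DataFrame, group_col: str = "group"
) -> pd.DataFrame:
    """Counts and percentages per (group, archetype), plus a pooled column.

    Percentages are relative to each group's size; the ``global`` column is
    relative to the total.  Groups absent from an archetype get zero rows.
    """
    counts = (
        assignments.groupby([group_col, "archetype"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(ARCHETYPES), fill_value=0)
        .T
    )
    counts["global"] = counts.sum(axis=1)
    pct = counts / counts.sum(axis=0) * 100.0
    out = pd.concat({"count": counts, "percent": pct}, axis=1)
    out.index.name = "archetype"
    return out
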