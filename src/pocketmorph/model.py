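"""Model/Results interface over the pocket-morphometrics pipeline.

`PocketShapeModel` takes a descriptor table (one row per pocket, with the
three eigenvalue ratios, the size descriptors and a two-level group label)
and `fit()` runs the full analysis: median thresholds, archetype
assignment, archetype frequencies, the two-cohort statistical battery,
bootstrap partition stability, and ratio-space distance summaries.  The
returned `PocketShapeResults` carries every intermediate product and can
render a text `summary()`.

    >>> model = PocketShapeModel.from_dataframe(table, group_col="group")
    >>> res = model.fit(n_boot=1000, seed=17)
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import archetypes as arch
from . import distances as dist
from . import stats as pstats
from .descriptors import ShapeDescriptors


class PocketShapeModel:
    """Morphometric archetype model for a two-group pocket cohort.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per pocket with at least ``rEV21`` and ``rEV32`` (``rEV31``
        is recomputed as the product if missing) and the group column.
    group_col : str
        Name of the two-level group label column (e.g. RNA vs protein).
    """

    def __init__(self, data: pd.DataFrame, group_col: str = "group"):
        if group_col not in data.columns:
            raise ValueError(f"missing group column {group_col!r}")
        data = data.copy()
        if "rEV31" not in data.columns:
            data["rEV31"] = data["rEV21"] * data["rEV32"]
        for col in ("rEV21", "rEV32"):
            vals = data[col].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError(f"{col} outside [0, 1]")
        self.data = data
        self.group_col = group_col

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, group_col: str = "group") -> "PocketShapeModel":
        return cls(data, group_col=group_col)

    @classmethod
    def from_descriptors(
        cls, records: list[ShapeDescriptors], groups: list[str], group_col: str = "group"
    ) -> "PocketShapeModel":
        if len(records) != len(groups):
            raise ValueError("records and groups must have equal length")
        df = pd.DataFrame([r.as_dict() for r in records])
        df[group_col] = groups
        return cls(df, group_col=group_col)

    def fit(
        self,
        n_boot: int = 1000,
        seed: int = 0,
        compute_distances: bool = True,
    ) -> "PocketShapeResults":
        """Fit thresholds and run the full comparison and stability analysis.

        ``n_boot=0`` skips the bootstrap (useful for quick looks); distances
        are O(n^2) and can be disabled for very large cohorts.
        """
        thresholds = arch.fit_thresholds(self.data)
        assignments = arch.assign_table(self.data, thresholds)
        frequencies = arch.archetype_frequencies(assignments, group_col=self.group_col)
        comparison = pstats.compare_groups(
            assignments, group_col=self.group_col, archetype_col="archetype"
        )
        stability = None
        if n_boot > 0:
            stability = arch.bootstrap_stability(
                self.data,
                group_col=self.group_col,
                n_replicates=n_boot,
                seed=seed,
                thresholds=thresholds,
            )
        distance_summary = None
        if compute_distances:
            distance_summary = dist.distance_summary(
                assignments, group_col=self.group_col, archetype_col="archetype"
            )
        return PocketShapeResults(
            model=self,
            thresholds=thresholds,
            assignments=assignments,
            frequencies=frequencies,
            comparison=comparison,
            stability=stability,
            distance_summary=distance_summary,
        )


@dataclass
class PocketShapeResults:
    """Fitted archetype partition plus the full comparison battery."""

    model: PocketShapeModel
    thresholds: arch.DecisionThresholds
    assignments: pd.DataFrame
    frequencies: pd.DataFrame
    comparison: pstats.ComparisonReport
    stability: arch.StabilityReport | None = None
    distance_summary: dist.DistanceSummary | None = None

    def summary(self) -> str:
        lines = []
        w = 72
        lines.append("=" * w)
        lines.append("Pocket shape archetype analysis".center(w))
        lines.append("=" * w)
        n = len(self.assignments)
        g1, g2 = self.comparison.group_names
        lines.append(f"Pockets: {n}  ({g1} vs {g2})")
        lines.append(
            f"Decision thresholds (global medians): m21 = {self.thresholds.m21:.3f}, "
            f"m32 = {self.thresholds.m32:.3f}"
        )
        lines.append("-" * w)
        lines.append("Archetype frequencies (count / % of group):")
        freq = self.frequencies
        for archetype in freq.index:
            label = arch.ARCHETYPE_LABELS.get(archetype, archetype)
            parts = []
            for col in freq["count"].columns:
                c = int(freq.loc[archetype, ("count", col)])
                p = freq.loc[archetype, ("percent", col)]
                parts.append(f"{col}: {c} ({p:.1f}%)")
            lines.append(f"  {label:<22s} " + "  ".join(parts))
        if self.comparison.frequency_chi2 is not None:
            c2 = self.comparison.frequency_chi2
            lines.append(
                f"Frequency chi-square: chi2 = {c2.statistic:.3f}, df = {c2.df}, "
                f"p = {c2.p:.3g}"
            )
        lines.append("-" * w)
        lines.append("Descriptor comparison (Welch t, Holm within family, Cohen's d):")
        t = self.comparison.descriptor_table
        header = f"  {'descriptor':<10s} {'t':>8s} {'p(Holm)':>10s} {'d':>8s} {'median':>8s}"
        lines.append(header)
        for name, row in t.iterrows():
            lines.append(
                f"  {name:<10s} {row['t']:>8.3f} {row['p_holm']:>10.3g} "
                f"{row['cohen_d']:>8.3f} {row['pooled_median']:>8.3f}"
            )
        if self.stability is not None:
            s = self.stability
            lines.append("-" * w)
            lines.append(
                f"Bootstrap stability ({s.n_replicates} replicates, seed {s.seed}): "
                f"median ARI = {s.ari_median:.3f} "
                f"[{s.ari_q025:.3f}, {s.ari_q975:.3f}]"
            )
            lines.append(
                f"  ARI >= 0.90 in {100 * s.frac_ari_ge_090:.1f}% of replicates; "
                f">= 0.80 in {100 * s.frac_ari_ge_080:.1f}%; "
                f"median reclassified fraction = {100 * s.median_reclassified_fraction:.1f}%"
            )
        lines.append("=" * w)
        return "\n".join(lines)
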