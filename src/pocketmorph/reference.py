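"""Published benchmark summaries used as fixture inputs.

These are the printed summary statistics of a curated benchmark of 300 RNA
and 300 protein ligand-binding pockets: per-descriptor group means, sample
SDs and sizes, the pooled medians, and the per-group archetype counts.
They serve as *inputs* for the summary-statistics modes of the statistical
battery (effect sizes and frequency tests can be recomputed directly from
them); the underlying per-pocket dataset is not distributed here, so
per-pocket quantities cannot be derived from this module.
"""

from __future__ import annotations

import pandas as pd

from .stats import GroupSummary

#: Per-descriptor cohort summaries: (RNA mean, RNA SD, protein mean,
#: protein SD, pooled median), n = 300 per group.
COHORT_SUMMARIES = {
    "rEV21": (0.572, 0.171, 0.600, 0.165, 0.592),
    "rEV32": (0.547, 0.184, 0.600, 0.182, 0.575),
    "rEV31": (0.309, 0.128, 0.360, 0.144, 0.328),
    "n_atoms": (244.713, 91.756, 176.353, 57.169, 200.500),
    "Rg": (9.248, 1.304, 8.759, 1.062, 9.019),
}

GROUP_N = 300

#: Published standardized effect sizes (Cohen's d, RNA - protein) for the
#: descriptors above, at the printed 3-decimal precision.
PUBLISHED_COHEN_D = {
    "rEV21": -0.165,
    "rEV32": -0.289,
    "rEV31": -0.372,
    "n_atoms": 0.894,
    "Rg": 0.412,
}

#: Pooled-cohort decision thresholds (global medians of rEV21 and rEV32).
REFERENCE_THRESHOLDS = (0.592, 0.575)

#: Archetype counts per group in the benchmark (n = 300 each).
ARCHETYPE_COUNTS = pd.DataFrame(
    {
        "RNA": {"sphere": 49, "disk": 91, "strongly_anisotropic": 75, "rod": 85},
        "protein": {"sphere": 86, "disk": 74, "strongly_anisotropic": 60, "rod": 80},
    }
)


def summary_pair(descriptor: str) -> tuple[GroupSummary, GroupSummary]:
    """(RNA, protein) GroupSummary pair for one descriptor."""
    m1, s1, m2, s2, _ = COHORT_SUMMARIES[descriptor]
    return (
        GroupSummary(n=GROUP_N, mean=m1, sd=s1, descriptor_name=descriptor),
        GroupSummary(n=GROUP_N, mean=m2, sd=s2, descriptor_name=descriptor),
    )
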