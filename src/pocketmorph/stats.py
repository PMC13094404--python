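"""Statistical battery for comparing two pocket cohorts.

Implements the comparison design used throughout the package: Welch's t
tests (unequal variances) with Holm adjustment applied separately to the
shape-ratio family {rEV21, rEV32, rEV31} and the size family {n_atoms, Rg};
Cohen's d with a pooled-SD denominator and a fixed group1 - group2 direction
convention; per-archetype one-factor MANOVA on (rEV21, rEV32) using Pillai's
trace (rEV31 is excluded as algebraically dependent) with BH/FDR-corrected
univariate follow-ups; and a Pearson chi-square test of independence on
archetype frequencies.

Each test accepts either raw value vectors or published summary statistics
(mean, SD with n-1 denominator, n), so printed cohort tables can be consumed
directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedEffectError

SHAPE_FAMILY = ["rEV21", "rEV32", "rEV31"]
SIZE_FAMILY = ["n_atoms", "Rg"]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptive statistics of one descriptor."""

    n: int
    mean: float
    sd: float  # sample SD, n-1 denominator
    median: float = float("nan")
    descriptor_name: str = ""

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_values(cls, values: Sequence[float], descriptor_name: str = "") -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError("need at least 2 observations")
        return cls(
            n=int(v.size),
            mean=float(v.mean()),
            sd=float(v.std(ddof=1)),
            median=float(np.median(v)),
            descriptor_name=descriptor_name,
        )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float = float("nan")
    adjust_method: str = "none"
    family: str = ""


@dataclass(frozen=True)
class EffectSize:
    cohen_d: float
    direction: str = "group1 - group2"


@dataclass(frozen=True)
class ManovaResult:
    pillai_trace: float
    approx_F: float
    df1: float
    df2: float
    p: float
    box_m: float = float("nan")
    box_m_p: float = float("nan")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    expected: np.ndarray


def _as_summary(x, name: str = "") -> GroupSummary:
    if isinstance(x, GroupSummary):
        return x
    return GroupSummary.from_values(x, descriptor_name=name)


def welch_t(summary1, summary2) -> TestResult:
    """Welch's two-sided t test from summaries or raw vectors.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite df.
    """
    s1 = _as_summary(summary1)
    s2 = _as_summary(summary2)
    if s1.sd == 0 and s2.sd == 0:
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind_from_stats(
        s1.mean, s1.sd, s1.n, s2.mean, s2.sd, s2.n, equal_var=False
    )
    # Welch-Satterthwaite degrees of freedom
    v1, v2 = s1.sd**2 / s1.n, s2.sd**2 / s2.n
    df = (v1 + v2) ** 2 / (v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1))
    return TestResult(statistic=float(res.statistic), df=float(df), p_raw=float(res.pvalue))


def cohen_d(summary1, summary2) -> EffectSize:
    """Cohen's d with the pooled-SD denominator.

    s_pooled = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)); at equal n this
    reduces to sqrt((s1^2 + s2^2)/2).  The sign follows group1 - group2.
    """
    s1 = _as_summary(summary1)
    s2 = _as_summary(summary2)
    pooled_var = ((s1.n - 1) * s1.sd**2 + (s2.n - 1) * s2.sd**2) / (s1.n + s2.n - 2)
    if pooled_var == 0:
        if s1.mean == s2.mean:
            return EffectSize(cohen_d=0.0)
        raise UndefinedEffectError("zero pooled SD with unequal means")
    return EffectSize(cohen_d=float((s1.mean - s2.mean) / np.sqrt(pooled_var)))


def holm_adjust(p_values: Sequence[float], family: str = "") -> np.ndarray:
    """Step-down Holm familywise-error adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _sscp(values: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Between-group (H) and within-group (E) SSCP matrices."""
    grand = values.mean(axis=0)
    H = np.zeros((values.shape[1], values.shape[1]))
    E = np.zeros_like(H)
    for g in np.unique(groups):
        sub = values[groups == g]
        diff_mean = (sub.mean(axis=0) - grand)[:, None]
        H += len(sub) * diff_mean @ diff_mean.T
        centered = sub - sub.mean(axis=0)
        E += centered.T @ centered
    return H, E


def _box_m(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Box's M test of covariance homogeneity (chi-square approximation)."""
    uniq = np.unique(groups)
    p = values.shape[1]
    k = len(uniq)
    ns = np.array([np.sum(groups == g) for g in uniq])
    covs = [np.cov(values[groups == g], rowvar=False) for g in uniq]
    pooled = sum((n - 1) * c for n, c in zip(ns, covs)) / (ns.sum() - k)
    sign, logdet_pooled = np.linalg.slogdet(pooled)
    if sign <= 0:
        return float("nan"), float("nan")
    m = (ns.sum() - k) * logdet_pooled
    for n, c in zip(ns, covs):
        s, ld = np.linalg.slogdet(c)
        if s <= 0:
            return float("nan"), float("nan")
        m -= (n - 1) * ld
    c1 = (2 * p**2 + 3 * p - 1) / (6 * (p + 1) * (k - 1)) * (
        np.sum(1 / (ns - 1)) - 1 / (ns.sum() - k)
    )
    chi2 = m * (1 - c1)
    df = (k - 1) * p * (p + 1) / 2
    return float(chi2), float(sps.chi2.sf(chi2, df))


def manova_two_group(values: np.ndarray, groups: Sequence) -> ManovaResult:
    """One-factor two-level MANOVA with Pillai's trace.

    ``values`` is an (n, p) response matrix (typically the two independent
    ratios rEV21 and rEV32); ``groups`` a length-n label vector with exactly
    two levels, each with at least 3 observations.  Pillai's trace is
    V = tr(H (H + E)^-1) with the standard F approximation; a Box's M
    covariance-homogeneity diagnostic is reported alongside (no gating).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(uniq)}")
    if min(np.sum(groups == g) for g in uniq) < 3:
        raise ValueError("each group needs at least 3 observations")
    n, p = values.shape
    H, E = _sscp(values, groups)
    T = H + E
    cond = np.linalg.cond(T)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular H+E matrix (condition number {cond:.3g}); responses may be collinear"
        )
    V = float(np.trace(H @ np.linalg.inv(T)))

    df_h = 1  # two groups
    df_e = n - 2
    s = min(p, df_h)
    m_par = (abs(p - df_h) - 1) / 2
    n_par = (df_e - p - 1) / 2
    df1 = s * (2 * m_par + s + 1)
    df2 = s * (2 * n_par + s + 1)
    F = (df2 / df1) * (V / (s - V))
    pval = float(sps.f.sf(F, df1, df2))
    box_m, box_p = _box_m(values, groups)
    return ManovaResult(
        pillai_trace=V, approx_F=float(F), df1=float(df1), df2=float(df2), p=pval,
        box_m=box_m, box_m_p=box_p,
    )


def chi_square_independence(counts) -> ChiSquareResult:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(counts, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    res = sps.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p=float(res.pvalue),
        expected=np.asarray(res.expected_freq),
    )


@dataclass
class ComparisonReport:
    """Structured output of the full two-cohort comparison battery."""

    group_names: tuple[str, str]
    descriptor_table: pd.DataFrame  # per descriptor: summaries, t, p, holm p, d, pooled median
    archetype_manova: pd.DataFrame | None = None
    archetype_size_tests: pd.DataFrame | None = None
    archetype_shape_followups: pd.DataFrame | None = None
    frequency_table: pd.DataFrame | None = None
    frequency_chi2: ChiSquareResult | None = None

    def to_json_dict(self) -> dict:
        out = {
            "groups": list(self.group_names),
            "descriptors": self.descriptor_table.reset_index().to_dict(orient="records"),
        }
        if self.archetype_manova is not None:
            out["archetype_manova"] = self.archetype_manova.reset_index().to_dict(orient="records")
        if self.archetype_size_tests is not None:
            out["archetype_size_tests"] = (
                self.archetype_size_tests.reset_index().to_dict(orient="records")
            )
        if self.archetype_shape_followups is not None:
            out["archetype_shape_followups"] = (
                self.archetype_shape_followups.reset_index().to_dict(orient="records")
            )
        if self.frequency_chi2 is not None:
            out["frequency_chi2"] = {
                "statistic": self.frequency_chi2.statistic,
                "df": self.frequency_chi2.df,
                "p": self.frequency_chi2.p,
            }
        return out


def compare_groups(
    descriptors: pd.DataFrame,
    group_col: str = "group",
    group_order: tuple[str, str] | None = None,
    archetype_col: str | None = "archetype",
) -> ComparisonReport:
    """Run the full comparison battery on a two-group descriptor table.

    The effect-size direction is group1 - group2 in ``group_order`` (by
    default ("RNA", "protein") when those labels are present, otherwise
    sorted order).  Holm families: shape ratios and size descriptors,
    adjusted separately.  If an archetype column is present, adds
    per-archetype MANOVA on (rEV21, rEV32) with BH follow-ups, per-archetype
    size-descriptor Welch tests (Holm within each archetype), and the
    archetype-frequency chi-square.
    """
    groups = list(pd.unique(descriptors[group_col]))
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if group_order is None:
        if set(groups) == {"RNA", "protein"}:
            group_order = ("RNA", "protein")
        else:
            group_order = tuple(sorted(groups))
    g1, g2 = group_order
    d1 = descriptors[descriptors[group_col] == g1]
    d2 = descriptors[descriptors[group_col] == g2]

    present = [c for c in SHAPE_FAMILY + SIZE_FAMILY if c in descriptors.columns]
    rows = {}
    for col in present:
        s1 = GroupSummary.from_values(d1[col], col)
        s2 = GroupSummary.from_values(d2[col], col)
        t = welch_t(s1, s2)
        d = cohen_d(s1, s2)
        rows[col] = {
            f"{g1}_n": s1.n, f"{g1}_mean": s1.mean, f"{g1}_sd": s1.sd,
            f"{g2}_n": s2.n, f"{g2}_mean": s2.mean, f"{g2}_sd": s2.sd,
            "t": t.statistic, "df": t.df, "p_raw": t.p_raw,
            "cohen_d": d.cohen_d,
            "pooled_median": float(np.median(descriptors[col])),
        }
    table = pd.DataFrame(rows).T
    table["p_holm"] = np.nan
    table["family"] = ""
    for family, cols in (("shape", SHAPE_FAMILY), ("size", SIZE_FAMILY)):
        cols = [c for c in cols if c in table.index]
        if cols:
            table.loc[cols, "p_holm"] = holm_adjust(table.loc[cols, "p_raw"].to_numpy())
            table.loc[cols, "family"] = family
    table.index.name = "descriptor"

    report = ComparisonReport(group_names=(g1, g2), descriptor_table=table)

    if archetype_col and archetype_col in descriptors.columns:
        _add_archetype_sections(report, descriptors, group_col, (g1, g2), archetype_col)
    return report


def _add_archetype_sections(report, descriptors, group_col, order, archetype_col):
    from .archetypes import ARCHETYPES, archetype_frequencies

    g1, g2 = order
    manova_rows, size_rows, shape_rows = {}, [], []
    for arch in [a for a in ARCHETYPES if a in set(descriptors[archetype_col])]:
        sub = descriptors[descriptors[archetype_col] == arch]
        n1 = (sub[group_col] == g1).sum()
        n2 = (sub[group_col] == g2).sum()
        if min(n1, n2) >= 3:
            mres = manova_two_group(
                sub[["rEV21", "rEV32"]].to_numpy(), sub[group_col].to_numpy()
            )
            manova_rows[arch] = {
                "pillai": mres.pillai_trace, "F": mres.approx_F,
                "df1": mres.df1, "df2": mres.df2, "p": mres.p,
                "n_" + g1: n1, "n_" + g2: n2,
            }
        if min(n1, n2) >= 2:
            a1 = sub[sub[group_col] == g1]
            a2 = sub[sub[group_col] == g2]
            # univariate shape follow-ups, BH-corrected per archetype
            fam_p, fam = [], []
            for col in SHAPE_FAMILY:
                if col not in sub.columns:
                    continue
                t = welch_t(a1[col], a2[col])
                d = cohen_d(a1[col], a2[col])
                fam.append({"archetype": arch, "descriptor": col,
                            "t": t.statistic, "df": t.df, "p_raw": t.p_raw,
                            "cohen_d": d.cohen_d})
                fam_p.append(t.p_raw)
            if fam:
                adj = bh_adjust(fam_p)
                for row, pa in zip(fam, adj):
                    row["p_bh"] = pa
                shape_rows.extend(fam)
            # size descriptors, Holm within the archetype's size family
            sz_p, sz = [], []
            for col in SIZE_FAMILY:
                if col not in sub.columns:
                    continue
                t = welch_t(a1[col], a2[col])
                d = cohen_d(a1[col], a2[col])
                sz.append({"archetype": arch, "descriptor": col,
                           "t": t.statistic, "df": t.df, "p_raw": t.p_raw,
                           "cohen_d": d.cohen_d})
                sz_p.append(t.p_raw)
            if sz:
                adj = holm_adjust(sz_p)
                for row, pa in zip(sz, adj):
                    row["p_holm"] = pa
                size_rows.extend(sz)

    if manova_rows:
        report.archetype_manova = pd.DataFrame(manova_rows).T.rename_axis("archetype")
    if size_rows:
        report.archetype_size_tests = pd.DataFrame(size_rows).set_index(
            ["archetype", "descriptor"]
        )
    if shape_rows:
        report.archetype_shape_followups = pd.DataFrame(shape_rows).set_index(
            ["archetype", "descriptor"]
        )

    freq = archetype_frequencies(descriptors, group_col=group_col)
    report.frequency_table = freq
    counts = freq["count"][[g1, g2]].to_numpy()
    nonzero = counts.sum(axis=1) > 0
    report.frequency_chi2 = chi_square_independence(counts[nonzero])
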