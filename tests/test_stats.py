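"""Welch tests, effect sizes, multiplicity corrections, MANOVA, chi-square."""

import numpy as np
import pandas as pd
import pytest

from pocketmorph import (
    GroupSummary,
    bh_adjust,
    chi_square_independence,
    cohen_d,
    compare_groups,
    holm_adjust,
    manova_two_group,
    welch_t,
)
from pocketmorph.reference import (
    ARCHETYPE_COUNTS,
    COHORT_SUMMARIES,
    PUBLISHED_COHEN_D,
    summary_pair,
)


# --- Welch t ----------------------------------------------------------------

def test_welch_equal_means_null():
    s1 = GroupSummary(n=30, mean=5.0, sd=1.0)
    s2 = GroupSummary(n=50, mean=5.0, sd=3.0)
    res = welch_t(s1, s2)
    assert res.statistic == 0.0
    assert res.p_raw == pytest.approx(1.0)


def test_welch_benchmark_atom_count():
    """Hand evaluation of the Welch formulas on the benchmark summaries."""
    s_rna, s_prot = summary_pair("n_atoms")
    res = welch_t(s_rna, s_prot)
    se = np.sqrt(91.756**2 / 300 + 57.169**2 / 300)
    assert res.statistic == pytest.approx((244.713 - 176.353) / se, rel=1e-12)
    assert res.statistic == pytest.approx(10.95, abs=0.01)
    assert 490 < res.df < 510  # Welch-Satterthwaite, hand value 500.7
    assert res.p_raw < 1e-20


def test_welch_antisymmetric():
    s1 = GroupSummary(n=20, mean=3.0, sd=1.0)
    s2 = GroupSummary(n=25, mean=4.0, sd=2.0)
    r12 = welch_t(s1, s2)
    r21 = welch_t(s2, s1)
    assert r12.statistic == pytest.approx(-r21.statistic)
    assert r12.p_raw == pytest.approx(r21.p_raw)


def test_welch_reduces_to_pooled_t_at_equal_variance(rng):
    from scipy import stats as sps

    x = rng.normal(size=30)
    y = rng.normal(size=30)
    ours = welch_t(x, y)
    pooled = sps.ttest_ind(x, y, equal_var=True)
    # equal n: the Welch statistic equals the pooled statistic identically
    assert ours.statistic == pytest.approx(pooled.statistic, abs=1e-9)


def test_welch_raw_vector_mode_matches_scipy(rng):
    from scipy import stats as sps

    x = rng.normal(size=25)
    y = rng.normal(loc=0.5, scale=2.0, size=40)
    ours = welch_t(x, y)
    ref = sps.ttest_ind(x, y, equal_var=False)
    assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
    assert ours.p_raw == pytest.approx(ref.pvalue, rel=1e-12)


# --- Cohen's d --------------------------------------------------------------

def test_cohen_d_reproduces_published_values():
    """Pooled-SD Cohen's d on printed summaries matches the printed column."""
    d_atoms = cohen_d(*summary_pair("n_atoms")).cohen_d
    assert round(d_atoms, 3) == 0.894
    for name in ("rEV21", "rEV32", "rEV31", "Rg"):
        d = cohen_d(*summary_pair(name)).cohen_d
        assert d == pytest.approx(PUBLISHED_COHEN_D[name], abs=0.003)


def test_cohen_d_sign_and_zero():
    lo = GroupSummary(n=10, mean=1.0, sd=1.0)
    hi = GroupSummary(n=10, mean=2.0, sd=1.0)
    assert cohen_d(lo, hi).cohen_d < 0
    assert cohen_d(hi, lo).cohen_d > 0
    assert cohen_d(lo, lo).cohen_d == 0.0


def test_cohen_d_equal_n_reduces_to_rms_sd():
    s1 = GroupSummary(n=50, mean=3.0, sd=2.0)
    s2 = GroupSummary(n=50, mean=1.0, sd=1.0)
    assert cohen_d(s1, s2).cohen_d == pytest.approx(2.0 / np.sqrt((4 + 1) / 2))


# --- multiplicity corrections -----------------------------------------------

def test_holm_hand_example():
    np.testing.assert_allclose(holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])


def test_holm_edge_cases():
    np.testing.assert_allclose(holm_adjust([0.2]), [0.2])
    np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        holm_adjust([0.5, 1.5])


def test_bh_hand_example():
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(bh_adjust([0.07]), [0.07])


def test_adjustments_dominance_and_monotone(rng):
    for _ in range(20):
        p = rng.uniform(size=rng.integers(2, 12))
        holm = holm_adjust(p)
        bh = bh_adjust(p)
        assert np.all(holm >= p - 1e-15) and np.all(holm <= 1)
        assert np.all(bh >= p - 1e-15) and np.all(bh <= 1)
        assert np.all(holm >= bh - 1e-12)  # step-down FWER >= step-up FDR
        order = np.argsort(p)
        assert np.all(np.diff(holm[order]) >= -1e-15)
        assert np.all(np.diff(bh[order]) >= -1e-15)


# --- MANOVA -----------------------------------------------------------------

def test_manova_hand_sscp_oracle():
    """6-row dataset with H and E computed by explicit loops in the test."""
    values = np.array(
        [[0.6, 0.5], [0.7, 0.6], [0.65, 0.55], [0.4, 0.3], [0.5, 0.45], [0.45, 0.35]]
    )
    groups = np.array(["a", "a", "a", "b", "b", "b"])
    grand = values.mean(axis=0)
    H = np.zeros((2, 2))
    E = np.zeros((2, 2))
    for g in ("a", "b"):
        sub = values[groups == g]
        d = (sub.mean(axis=0) - grand).reshape(2, 1)
        H += len(sub) * (d @ d.T)
        for row in sub:
            e = (row - sub.mean(axis=0)).reshape(2, 1)
            E += e @ e.T
    expected_v = np.trace(H @ np.linalg.inv(H + E))
    res = manova_two_group(values, groups)
    assert res.pillai_trace == pytest.approx(expected_v, abs=1e-12)
    assert 0 <= res.pillai_trace <= 1


def test_manova_matches_statsmodels(rng):
    from statsmodels.multivariate.manova import MANOVA

    x = rng.normal(size=(60, 2))
    x[30:] += [0.4, -0.2]
    groups = np.array(["g1"] * 30 + ["g2"] * 30)
    res = manova_two_group(x, groups)
    df = pd.DataFrame({"y1": x[:, 0], "y2": x[:, 1], "g": groups})
    sm = MANOVA.from_formula("y1 + y2 ~ g", data=df).mv_test()
    table = sm.results["g"]["stat"]
    assert res.pillai_trace == pytest.approx(table.loc["Pillai's trace", "Value"], abs=1e-9)
    assert res.approx_F == pytest.approx(table.loc["Pillai's trace", "F Value"], rel=1e-6)
    assert res.p == pytest.approx(table.loc["Pillai's trace", "Pr > F"], abs=1e-9)


def test_manova_null_and_power():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(100, 2))
    groups = np.array(["a"] * 50 + ["b"] * 50)
    null = manova_two_group(x, groups)
    assert null.pillai_trace < 0.1

    shifted = x.copy()
    shifted[50:, 0] += 5.0  # 5 SD shift in one response
    power = manova_two_group(shifted, groups)
    assert power.p < 1e-6


def test_manova_input_validation():
    x = np.random.default_rng(0).normal(size=(10, 2))
    with pytest.raises(ValueError):
        manova_two_group(x, ["a"] * 10)
    with pytest.raises(ValueError):
        manova_two_group(x, ["a"] * 8 + ["b"] * 2)


# --- chi-square ---------------------------------------------------------------

def test_chi_square_benchmark_counts():
    res = chi_square_independence(ARCHETYPE_COUNTS.to_numpy())
    # hand Pearson computation on the 4x2 table
    table = ARCHETYPE_COUNTS.to_numpy(dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    hand = ((table - expected) ** 2 / expected).sum()
    assert res.statistic == pytest.approx(hand, abs=1e-12)
    assert res.statistic == pytest.approx(13.7104, abs=1e-3)
    assert res.df == 3
    assert res.p < 0.01


def test_chi_square_proportional_table_is_null():
    res = chi_square_independence([[10, 20], [30, 60], [5, 10]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_chi_square_matches_loop_oracle(rng):
    table = rng.integers(1, 60, size=(4, 2)).astype(float)
    res = chi_square_independence(table)
    stat = 0.0
    for i in range(4):
        for j in range(2):
            e = table[i].sum() * table[:, j].sum() / table.sum()
            stat += (table[i, j] - e) ** 2 / e
    assert res.statistic == pytest.approx(stat, abs=1e-12)
    np.testing.assert_allclose(res.expected.sum(axis=1), table.sum(axis=1))


def test_chi_square_permutation_invariance(rng):
    table = rng.integers(1, 60, size=(4, 3)).astype(float)
    res = chi_square_independence(table)
    perm = table[[2, 0, 3, 1]][:, [1, 2, 0]]
    assert chi_square_independence(perm).statistic == pytest.approx(res.statistic)


def test_chi_square_zero_margin_error():
    with pytest.raises(ValueError):
        chi_square_independence([[0, 0], [5, 3]])


# --- compare_groups -----------------------------------------------------------

def _identical_groups_table():
    rng = np.random.default_rng(42)
    base = pd.DataFrame(
        {
            "rEV21": rng.uniform(0.2, 0.9, 30),
            "rEV32": rng.uniform(0.2, 0.9, 30),
            "n_atoms": rng.integers(50, 300, 30).astype(float),
            "Rg": rng.uniform(7, 11, 30),
        }
    )
    base["rEV31"] = base["rEV21"] * base["rEV32"]
    a = base.copy()
    a["group"] = "RNA"
    b = base.copy()
    b["group"] = "protein"
    both = pd.concat([a, b], ignore_index=True)
    both["archetype"] = np.tile(["sphere", "rod", "disk"], 20)
    return both


def test_compare_identical_groups_is_null():
    report = compare_groups(_identical_groups_table())
    t = report.descriptor_table
    np.testing.assert_allclose(t["cohen_d"], 0.0, atol=1e-12)
    np.testing.assert_allclose(t["p_raw"], 1.0)
    assert report.frequency_chi2.statistic == pytest.approx(0.0, abs=1e-12)


def test_compare_groups_direction_is_rna_minus_protein(cohort):
    from pocketmorph import assign_table, fit_thresholds

    table = assign_table(cohort, fit_thresholds(cohort))
    report = compare_groups(table)
    assert report.group_names == ("RNA", "protein")
    # synthetic cohort: RNA pockets have more atoms, so d(n_atoms) > 0
    assert report.descriptor_table.loc["n_atoms", "cohen_d"] > 0


def test_compare_groups_recovers_generator_effects(cohort):
    """On a cohort generated with the benchmark group means/SDs, recovered
    effect sizes fall within the sampling-error envelope of the targets."""
    from pocketmorph import assign_table, fit_thresholds

    table = assign_table(cohort, fit_thresholds(cohort))
    report = compare_groups(table)
    d = report.descriptor_table["cohen_d"]
    assert d["n_atoms"] == pytest.approx(PUBLISHED_COHEN_D["n_atoms"], abs=0.15)
    assert d["Rg"] == pytest.approx(PUBLISHED_COHEN_D["Rg"], abs=0.15)


def test_compare_groups_archetype_sections(cohort):
    from pocketmorph import assign_table, fit_thresholds

    table = assign_table(cohort, fit_thresholds(cohort))
    report = compare_groups(table)
    assert report.archetype_manova is not None
    assert set(report.archetype_manova.columns) >= {"pillai", "F", "p"}
    assert report.archetype_size_tests is not None
    assert report.archetype_shape_followups is not None
    fu = report.archetype_shape_followups
    assert np.all(fu["p_bh"] >= fu["p_raw"] - 1e-15)


def test_compare_groups_requires_two_groups(cohort):
    with pytest.raises(ValueError):
        compare_groups(cohort[cohort["group"] == "RNA"])


def test_welch_null_calibration_small():
    """Empirical type-I error of the Welch test at alpha=0.05 (quick check;
    the full 10,000-replicate calibration runs in the acceptance suite)."""
    from scipy import stats as sps

    rng = np.random.default_rng(314)
    x = rng.normal(size=(2000, 30))
    y = rng.normal(size=(2000, 30))
    p = sps.ttest_ind(x, y, axis=1, equal_var=False).pvalue
    rate = np.mean(p < 0.05)
    assert 0.035 < rate < 0.065
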