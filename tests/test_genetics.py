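"""SNP statistics: MAF, HWE, dominance grouping, t-tests, Mann-Whitney,
Bonferroni, chi-square, risk counts and power."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import metscore as m
from metscore.genetics import GenotypeMatrix, hwe_report


# --- MAF and HWE -------------------------------------------------------------


@pytest.mark.parametrize(
    "dosages, expected",
    [([0, 0, 0], 0.0), ([1, 1, 1], 0.5), ([0, 0, 1, 2], 0.375)],
)
def test_maf_direct_counts(dosages, expected):
    assert m.maf(dosages) == expected


def test_maf_ignores_missing_and_errors_when_all_missing():
    assert m.maf([np.nan, 1.0, 1.0]) == 0.5
    with pytest.raises(m.InsufficientDataError):
        m.maf([np.nan, np.nan])


def test_hwe_exact_proportions_give_zero_chi2():
    res = m.hwe_test(25, 50, 25)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)
    assert res.maf == 0.5


def test_hwe_hand_computed_example():
    res = m.hwe_test(10, 10, 10)
    assert res.chi2 == pytest.approx(10.0 / 3.0, abs=1e-9)
    assert res.p == pytest.approx(0.06789, abs=1e-4)


def test_hwe_extreme_heterozygote_excess():
    res = m.hwe_test(0, 100, 0)
    assert res.chi2 == pytest.approx(100.0)
    assert res.p < 1e-20


def test_hwe_monomorphic_is_undefined():
    with pytest.raises(m.DegenerateDataError):
        m.hwe_test(100, 0, 0)


def test_hwe_pvalues_uniform_under_null():
    rng = np.random.default_rng(21)
    pvals = []
    for _ in range(1000):
        d = rng.binomial(2, 0.3, 500)
        pvals.append(m.hwe_test(*(np.bincount(d, minlength=3))).p)
    # chi-square approximation: near-uniform at this sample size
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# --- grouping ---------------------------------------------------------------


def test_group_dominant_basic_split():
    ref, car = m.group_dominant([0, 1, 2, 0])
    assert ref.tolist() == [0, 3] and car.tolist() == [1, 2]


def test_group_dominant_excludes_missing():
    ref, car = m.group_dominant([0, np.nan, 2])
    assert ref.tolist() == [0] and car.tolist() == [2]


def test_group_dominant_table4_split_sizes():
    # 156 GG vs 50 carriers in a 206-cohort
    d = np.concatenate([np.zeros(156), np.ones(44), np.full(6, 2.0)])
    ref, car = m.group_dominant(d)
    assert ref.size == 156 and car.size == 50


# --- t-tests ----------------------------------------------------------------


@pytest.mark.parametrize(
    "summ, diff, p, ci",
    [
        # published candidate-SNP rows: (n, mean, SD) per genotype group
        ((156, 0.192, 1.380, 50, -0.600, 1.362), 0.792, 4.9e-4, (0.351, 1.233)),
        ((63, 0.350, 1.374, 143, -0.154, 1.409), 0.504, 0.018, (0.087, 0.921)),
        ((58, 0.342, 1.606, 148, -0.134, 1.313), 0.476, 0.029, (0.048, 0.904)),
        ((192, -0.080, 1.375, 13, 1.119, 1.601), -1.199, 0.003, (-1.984, -0.414)),
    ],
)
def test_t_test_summary_reproduces_reference_rows(summ, diff, p, ci):
    res = m.t_test_summary(*summ)
    assert res.mean_diff == pytest.approx(diff, abs=1e-9)
    assert res.p == pytest.approx(p, rel=0.05)
    assert res.ci_low == pytest.approx(ci[0], abs=5e-4)
    assert res.ci_high == pytest.approx(ci[1], abs=5e-4)
    assert res.df == summ[0] + summ[3] - 2


def test_t_test_identical_groups():
    res = m.t_test_summary(30, 1.0, 0.5, 20, 1.0, 0.5)
    assert res.t == 0.0 and res.p == pytest.approx(1.0)
    assert res.ci_low == pytest.approx(-res.ci_high)


def test_t_test_zero_pooled_variance():
    with pytest.raises(m.DegenerateDataError):
        m.t_test_summary(10, 1.0, 0.0, 10, 1.0, 0.0)
    with pytest.raises(m.DegenerateDataError):
        m.t_test_raw(np.ones(5), np.ones(5))


@settings(deadline=None, max_examples=100)
@given(
    st.lists(st.floats(-50, 50), min_size=2, max_size=20),
    st.lists(st.floats(-50, 50), min_size=2, max_size=20),
)
def test_t_test_raw_equals_summary_of_own_summaries(v1, v2):
    x, y = np.array(v1), np.array(v2)
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        return
    raw = m.t_test_raw(x, y)
    summ = m.t_test_summary(
        x.size, x.mean(), x.std(ddof=1), y.size, y.mean(), y.std(ddof=1)
    )
    assert raw.t == pytest.approx(summ.t, abs=1e-12)
    assert raw.p == pytest.approx(summ.p, abs=1e-12)
    assert raw.ci_low == pytest.approx(summ.ci_low, abs=1e-12)


def test_t_test_raw_constructed_shift():
    rng = np.random.default_rng(30)
    x = rng.standard_normal(100)
    res = m.t_test_raw(x, x + 1.0)
    assert res.mean_diff == pytest.approx(-1.0, abs=1e-12)


# --- Mann-Whitney ------------------------------------------------------------


def _exact_mw_p(x, y):
    """Exhaustive two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    us = np.array([u_of(c) for c in itertools.combinations(range(len(pooled)), n1)])
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


def test_mann_whitney_identical_multisets():
    _, p = m.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p > 0.9


def test_mann_whitney_separated_groups_exact_enumeration():
    u, p = m.mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert p == pytest.approx(0.1, abs=1e-12)


@pytest.mark.parametrize("n1, n2", [(3, 3), (4, 5), (6, 4), (8, 8)])
def test_mann_whitney_matches_exhaustive_oracle(n1, n2):
    rng = np.random.default_rng(n1 * 10 + n2)
    x = rng.standard_normal(n1)
    y = rng.standard_normal(n2) + 0.8
    _, p = m.mann_whitney(x, y)
    assert p == pytest.approx(_exact_mw_p(x, y), abs=1e-9)


def test_mann_whitney_empty_group_errors():
    with pytest.raises(m.InsufficientDataError):
        m.mann_whitney([], [1.0])


# --- Bonferroni --------------------------------------------------------------


def test_bonferroni_published_example_and_caps():
    assert round(m.bonferroni(0.00049, 37), 3) == 0.018
    assert m.bonferroni(0.5, 37) == 1.0
    assert m.bonferroni(0.123, 1) == 0.123


@settings(deadline=None, max_examples=100)
@given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 100))
def test_bonferroni_monotone_and_dominates_raw(p1, p2, mm):
    lo, hi = sorted([p1, p2])
    assert m.bonferroni(lo, mm) <= m.bonferroni(hi, mm)
    assert m.bonferroni(p1, mm) >= p1
    assert m.bonferroni(p1, mm) <= m.bonferroni(p1, mm + 1)


# --- dispatching and chi-square ----------------------------------------------


def test_per_trait_association_dispatch():
    rng = np.random.default_rng(31)
    a, b = rng.standard_normal(80), rng.standard_normal(80) + 0.3
    test, _, _ = m.per_trait_association(a, b)
    assert test == "t"
    heavy = np.exp(rng.standard_normal(80) * 2)
    test, _, _ = m.per_trait_association(heavy, heavy * 1.2)
    assert test == "mann_whitney"


def test_chi2_independent_balanced_table():
    labels = np.repeat([0, 1], 100)
    status = np.tile(np.repeat([0, 1], 50), 2)
    chi2, p = m.chi2_association(labels, status)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi2_matches_direct_formula():
    labels = np.repeat([0, 1], 40)
    status = np.concatenate([np.repeat([0, 1], [30, 10]), np.repeat([0, 1], [10, 30])])
    chi2, p = m.chi2_association(labels, status)
    obs = np.array([[30, 10], [10, 30]], dtype=float)
    rows, cols = obs.sum(1, keepdims=True), obs.sum(0, keepdims=True)
    exp = rows @ cols / obs.sum()
    assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(), abs=1e-9)
    assert p < 1e-4


def test_chi2_zero_margin_errors():
    with pytest.raises(m.DegenerateDataError):
        m.chi2_association(np.repeat([0, 1], 5), np.zeros(10))


def test_chi2_type_one_error_rate():
    rng = np.random.default_rng(32)
    hits = 0
    reps = 600
    for _ in range(reps):
        labels = rng.integers(0, 2, 200)
        status = rng.integers(0, 2, 200)
        try:
            _, p = m.chi2_association(labels, status)
        except m.DegenerateDataError:
            continue
        hits += p < 0.05
    assert hits / reps == pytest.approx(0.05, abs=0.02)


# --- risk counts -------------------------------------------------------------


def _panel(dosage_dict):
    ids = [f"S{i}" for i in range(len(next(iter(dosage_dict.values()))))]
    dos = pd.DataFrame(dosage_dict, index=pd.Index(ids, name="id"), dtype=float)
    snps = pd.DataFrame({"gene": ""}, index=pd.Index(dos.columns, name="snp_id"))
    return GenotypeMatrix(dosages=dos, snps=snps)


def test_risk_count_all_zero_dosages_carrier_orientation():
    gm = _panel({"s1": [0, 0], "s2": [0, 0]})
    counts = m.risk_genotype_count(gm, {"s1": True, "s2": True})
    assert counts.tolist() == [0.0, 0.0]


def test_risk_count_protective_orientation_and_missing():
    gm = _panel({"s1": [0, 1, np.nan], "s2": [2, 0, 1]})
    counts = m.risk_genotype_count(gm, {"s1": False, "s2": True})
    # s1: non-carrier is the risk state; s2: carrier is
    assert counts.iloc[0] == 2.0 and counts.iloc[1] == 0.0
    assert math.isnan(counts.iloc[2])


def test_risk_count_unknown_snp_errors():
    gm = _panel({"s1": [0, 1]})
    with pytest.raises(m.ParameterError):
        m.risk_genotype_count(gm, {"nope": True})


def test_risk_count_handles_absent_top_stratum():
    """A small cohort may contain nobody with all four risk genotypes."""
    rng = np.random.default_rng(33)
    gm = _panel({f"s{i}": rng.binomial(2, 0.1, 206) for i in range(4)})
    counts = m.risk_genotype_count(gm, {f"s{i}": True for i in range(4)})
    assert counts.max() <= 4
    # no error even if the top category is empty
    assert (counts == 4).sum() >= 0


# --- power -------------------------------------------------------------------


@pytest.mark.parametrize(
    "n1, n2, expected",
    [(156, 50, 0.642), (58, 148, 0.612), (192, 13, 1.132)],
)
def test_min_detectable_diff_reference_values(n1, n2, expected):
    spec = m.PowerSpec(n1=n1, n2=n2, sigma=1.41)
    assert round(m.min_detectable_diff(spec), 3) == expected


def test_min_detectable_diff_linear_in_sigma():
    a = m.min_detectable_diff(m.PowerSpec(n1=50, n2=50, sigma=1.0))
    b = m.min_detectable_diff(m.PowerSpec(n1=50, n2=50, sigma=2.0))
    assert b == pytest.approx(2 * a, abs=1e-12)


def test_min_detectable_diff_inverse_consistency():
    spec = m.PowerSpec(n1=156, n2=50, sigma=1.41)
    delta = m.min_detectable_diff(spec)
    assert m.power_for_diff(delta, spec) == pytest.approx(0.80, abs=1e-6)


def test_exact_power_variant_close_to_normal_approximation():
    spec = m.PowerSpec(n1=156, n2=50, sigma=1.41)
    approx = m.min_detectable_diff(spec)
    exact = m.min_detectable_diff(spec, exact=True)
    assert exact == pytest.approx(approx, rel=0.02)
    assert exact > approx  # t tails are heavier than normal


def test_power_spec_validation():
    with pytest.raises(m.ParameterError):
        m.PowerSpec(n1=1, n2=50, sigma=1.0)
    with pytest.raises(m.ParameterError):
        m.PowerSpec(n1=10, n2=10, sigma=-1.0)


# --- association type-I error ------------------------------------------------


def test_dominant_t_test_type_one_error():
    """Null cohorts: the dominance t-test rejects ~5% of the time."""
    rng = np.random.default_rng(34)
    hits, total = 0, 0
    for _ in range(600):
        score = rng.standard_normal(206)
        d = rng.binomial(2, 0.2, 206)
        ref, car = m.group_dominant(d)
        if ref.size < 2 or car.size < 2:
            continue
        hits += m.t_test_raw(score[ref], score[car]).p < 0.05
        total += 1
    assert hits / total == pytest.approx(0.05, abs=0.02)


def test_hwe_report_flags_monomorphic():
    gm = _panel({"poly": [0, 1, 2, 1], "mono": [0, 0, 0, 0]})
    rep = hwe_report(gm)
    assert np.isfinite(rep.loc["poly", "hwe_p"])
    assert np.isnan(rep.loc["mono", "hwe_p"])
    assert "monomorphic" in rep.loc["mono", "note"]
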