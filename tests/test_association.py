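"""Hardy-Weinberg tests, crude and adjusted odds ratios, and model scans."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snp_epistat import (
    Counts2x2,
    GenotypeCounts,
    SubjectRecord,
    association_scan,
    crude_or,
    fit_logistic,
    hwe_chi_square,
    stratified_scan,
)
from snp_epistat.association import ConvergenceError, SeparationError, Z975


# ---------------------------------------------------------------------------
# Hardy-Weinberg


@pytest.mark.parametrize(
    "counts, chi2, p",
    [
        ((285, 236, 58), 0.78, 0.38),
        ((538, 502, 105), 0.62, 0.43),
    ],
)
def test_hwe_reproduces_study_statistics(counts, chi2, p):
    res = hwe_chi_square(GenotypeCounts(*counts))
    assert round(res.chi2, 2) == chi2
    assert round(res.p, 2) == p
    assert res.df == 1
    assert math.isclose(sum(res.expected_counts), sum(counts))


def test_hwe_exact_proportions_give_zero():
    res = hwe_chi_square(GenotypeCounts(25, 50, 25))
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_hwe_monomorphic_errors():
    with pytest.raises(ValueError, match="monomorphic"):
        hwe_chi_square(GenotypeCounts(100, 0, 0))


def _hwe_oracle(ncc, nca, naa):
    """Brute-force: build expected counts explicitly and sum Pearson terms."""
    n = ncc + nca + naa
    q = (nca + 2 * naa) / (2 * n)
    exp = [n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2]
    return sum((o - e) ** 2 / e for o, e in zip((ncc, nca, naa), exp))


@given(
    st.tuples(
        st.integers(min_value=0, max_value=4000),
        st.integers(min_value=1, max_value=4000),
        st.integers(min_value=0, max_value=2000),
    )
)
@settings(max_examples=200, derandomize=True)
def test_hwe_matches_bruteforce_oracle(counts):
    res = hwe_chi_square(GenotypeCounts(*counts))
    assert res.chi2 == pytest.approx(_hwe_oracle(*counts), rel=1e-12)


# ---------------------------------------------------------------------------
# crude odds ratios


def test_crude_or_allele_contrast_whole_cohort():
    res = crude_or(Counts2x2(a=352, b=806, c=712, d=1578))
    assert round(res.or_hat, 2) == 0.97
    assert round(res.ci_low, 2) == 0.83
    assert round(res.ci_high, 2) == 1.13
    assert round(res.p, 2) == 0.68


def test_crude_or_balanced_table_is_unity():
    res = crude_or(Counts2x2(10, 10, 10, 10))
    assert res.or_hat == pytest.approx(1.0)
    assert res.ci_low * res.ci_high == pytest.approx(1.0)  # symmetric on log scale


def test_crude_or_sp_dominant_carriers():
    # cross-product oracle: (22*538)/(46*607)
    res = crude_or(Counts2x2(a=22, b=46, c=607, d=538))
    assert res.or_hat == pytest.approx((22 * 538) / (46 * 607), rel=1e-12)
    assert round(res.or_hat, 3) == 0.424


def test_crude_or_zero_cell_uses_haldane():
    res = crude_or(Counts2x2(0, 10, 10, 10))
    assert res.method == "woolf_haldane"
    assert res.or_hat == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))


def test_crude_or_empty_margin_errors():
    with pytest.raises(ValueError, match="margin"):
        crude_or(Counts2x2(0, 0, 5, 5))


@given(st.tuples(*[st.integers(min_value=1, max_value=500)] * 4))
@settings(max_examples=200, derandomize=True)
def test_label_swap_reciprocity(cells):
    a, b, c, d = cells
    fwd = crude_or(Counts2x2(a, b, c, d))
    rev = crude_or(Counts2x2(c, d, a, b))  # cases and controls exchanged
    assert fwd.or_hat * rev.or_hat == pytest.approx(1.0, rel=1e-10)
    assert fwd.p == pytest.approx(rev.p, rel=1e-10)


@given(st.tuples(*[st.integers(min_value=1, max_value=200)] * 4))
@settings(max_examples=100, derandomize=True)
def test_large_additive_smoothing_drives_or_to_one(cells):
    # flooding every cell with a common constant washes out the association;
    # for finite unbalanced tables the approach need not be monotone in k
    ors = [
        crude_or(Counts2x2(*(v + k for v in cells))).or_hat for k in (10**3, 10**5, 10**7)
    ]
    assert abs(math.log(ors[1])) <= abs(math.log(ors[0])) + 1e-12
    assert abs(math.log(ors[2])) <= abs(math.log(ors[1])) + 1e-12
    assert ors[-1] == pytest.approx(1.0, abs=1e-4)


# ---------------------------------------------------------------------------
# logistic regression


def test_intercept_only_logistic_matches_closed_form():
    y = np.array([1.0] * 579 + [0.0] * 1145)
    fit = fit_logistic(y, pd.DataFrame(index=range(len(y))))
    assert fit.params["const"] == pytest.approx(math.log(579 / 1145), rel=1e-8)


def test_single_binary_predictor_matches_crude_or():
    t = Counts2x2(a=60, b=40, c=45, d=55)
    y = np.array([1.0] * 100 + [0.0] * 100)
    x = np.array([1.0] * 60 + [0.0] * 40 + [1.0] * 45 + [0.0] * 55)
    fit = fit_logistic(y, pd.DataFrame({"x": x}))
    res = crude_or(t)
    assert math.exp(fit.params["x"]) == pytest.approx(res.or_hat, rel=1e-6)
    # Wald endpoints agree with Woolf endpoints
    lo = math.exp(fit.params["x"] - Z975 * fit.bse["x"])
    hi = math.exp(fit.params["x"] + Z975 * fit.bse["x"])
    assert lo == pytest.approx(res.ci_low, rel=1e-4)
    assert hi == pytest.approx(res.ci_high, rel=1e-4)


def test_logistic_wald_ci_covers_truth_across_replicates():
    rng = np.random.default_rng(42)
    beta = 0.405
    n = 2000
    hits = 0
    reps = 200
    for _ in range(reps):
        x = rng.binomial(1, 0.4, n).astype(float)
        p = 1 / (1 + np.exp(-(-0.5 + beta * x)))
        y = (rng.random(n) < p).astype(float)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        lo = fit.params["x"] - Z975 * fit.bse["x"]
        hi = fit.params["x"] + Z975 * fit.bse["x"]
        hits += lo <= beta <= hi
    assert hits / reps >= 0.93


def test_logistic_detects_separation():
    y = np.array([0.0] * 20 + [1.0] * 20)
    x = np.array([0.0] * 20 + [1.0] * 20)
    with pytest.raises(SeparationError):
        fit_logistic(y, pd.DataFrame({"x": x}))


def test_logistic_rejects_rank_deficient_design():
    y = np.array([0.0, 1.0] * 20)
    x = np.arange(40, dtype=float)
    with pytest.raises(ValueError, match="rank"):
        fit_logistic(y, pd.DataFrame({"x": x, "x2": 2 * x}))


def test_log_additive_recovers_multiplicative_allele_effect():
    """Per-allele log-OR on data simulated under exact multiplicative effects."""
    rng = np.random.default_rng(7)
    beta = math.log(1.3)
    biases = []
    for _ in range(20):
        g = rng.choice(3, size=20_000, p=[0.4761, 0.4278, 0.0961]).astype(float)
        p = 1 / (1 + np.exp(-(-1.5 + beta * g)))
        y = (rng.random(20_000) < p).astype(float)
        fit = fit_logistic(y, pd.DataFrame({"g": g}))
        biases.append(fit.params["g"] - beta)
    assert abs(float(np.mean(biases))) < 0.02 * beta  # < 2% relative bias


# ---------------------------------------------------------------------------
# scans


def test_association_scan_study_allelic_row(study_cohort):
    scan = association_scan(study_cohort, models=("allelic",), covariates=())
    assert round(scan[0].or_hat, 2) == 0.97
    assert scan[0].method == "woolf_crude"


def test_association_scan_null_cohort_unadjusted():
    # two status groups with identical genotype composition: every OR is 1
    recs = []
    for status in ("case", "control"):
        for geno, n in ((0, 50), (1, 40), (2, 10)):
            for i in range(n):
                recs.append(
                    SubjectRecord(f"{status}{geno}_{i}", status, genotype=geno)
                )
    scan = association_scan(recs, covariates=())
    for res in scan:
        assert res.or_hat == pytest.approx(1.0, abs=1e-8)


def test_association_scan_flags_inestimable_models():
    recs = [
        SubjectRecord(f"a{i}", "case", genotype=0 if i % 2 else 1) for i in range(40)
    ] + [SubjectRecord(f"b{i}", "control", genotype=0 if i % 2 else 1) for i in range(40)]
    scan = association_scan(recs, covariates=())
    rec = next(r for r in scan if r.model == "recessive")
    assert not rec.estimable  # no AA homozygotes anywhere
    assert any(r.estimable for r in scan)


def test_scan_adjusted_on_simulated_cohort(default_sim):
    _, cohort, truth = default_sim
    scan = association_scan(cohort)
    by_model = {r.model: r for r in scan}
    assert set(by_model) >= {"allelic", "dominant", "recessive", "log_additive"}
    for res in scan:
        if res.estimable:
            assert res.ci_low <= res.or_hat <= res.ci_high
            assert 0 < res.p <= 1
            if res.method == "logistic_wald":
                assert res.adjusted_for == ("age", "is_male", "hla")
                assert res.lrt_p is not None


def test_stratified_scan_excludes_stratifier_and_warns_when_constant(default_sim):
    _, cohort, _ = default_sim
    strat = stratified_scan(cohort)
    assert set(strat) == {"positive", "negative"}
    for res in strat["positive"]:
        assert "hla" not in res.adjusted_for
    only_neg = [r for r in cohort if r.hla_carrier is False]
    with pytest.warns(UserWarning, match="constant"):
        single = stratified_scan(only_neg)
    assert list(single) == ["negative"]
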