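"""Synthetic cohort generator: determinism, calibration, recovery machinery."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from snp_epistat import (
    Counts2x2,
    SimConfig,
    classify_joint_exposure,
    crude_or,
    genotype_counts,
    hwe_chi_square,
    recovery_experiment,
    simulate_cohort,
)
from snp_epistat.simulate import expected_joint_cells, population_prevalence


def test_same_seed_reproduces_cohort_exactly(default_sim):
    cfg, cohort, truth = default_sim
    again, truth2 = simulate_cohort(cfg)
    assert again == cohort
    assert truth == truth2


def test_target_counts_and_invariants(default_sim):
    _, cohort, _ = default_sim
    assert sum(r.is_case for r in cohort) == 579
    assert sum(not r.is_case for r in cohort) == 1145
    for r in cohort:
        if r.is_case:
            assert r.aoo is not None and r.aoo <= r.age
            assert abs((r.age - r.aoo) - r.duration) <= 1.0
            assert 0 <= r.edss <= 10 and (2 * r.edss) == int(2 * r.edss)
            assert 0 < r.msss < 10
            assert r.ms_course in ("RR", "SP")
        else:
            assert r.aoo is None and r.msss is None and r.ms_course is None
        assert r.hla_carrier == (r.hla_copies >= 1)


def test_null_model_produces_null_association():
    cfg = SimConfig(
        n_cases=700, n_controls=1300,
        beta_geno=0.0, beta_hla=0.0, beta_interaction=0.0,
    )
    rng = np.random.default_rng(99)
    n_sig = 0
    n_near_null = 0
    n_reps = 100
    for s in rng.integers(0, 2**31 - 1, n_reps):
        cohort, _ = simulate_cohort(dataclasses.replace(cfg, seed=int(s)))
        gc = genotype_counts(cohort, where=lambda r: r.is_case)
        gk = genotype_counts(cohort, where=lambda r: not r.is_case)
        res = crude_or(
            Counts2x2(gc.n_ca + 2 * gc.n_aa, 2 * gc.n_cc + gc.n_ca,
                      gk.n_ca + 2 * gk.n_aa, 2 * gk.n_cc + gk.n_ca)
        )
        n_near_null += abs(res.or_hat - 1.0) < 0.15
        n_sig += res.p < 0.05
    assert n_near_null >= 0.90 * n_reps  # ±0.15 is ~2 sigma at this sample size
    assert n_sig <= 0.10 * n_reps


def test_default_generator_builds_in_antagonism(default_sim):
    cfg, cohort, truth = default_sim
    assert truth["sf_crude"] == pytest.approx(0.62, abs=0.01)
    table = classify_joint_exposure(cohort)
    # sampled cells close to the closed-form expectations (binomial 4-sigma)
    for (prefix, n_group) in (("case", table.n_cases), ("control", table.n_controls)):
        observed = {
            ("case", k): v for k, v in
            zip(["00", "10", "01", "11"], [table.c00, table.c10, table.c01, table.c11])
        } if prefix == "case" else {
            ("control", k): v for k, v in
            zip(["00", "10", "01", "11"], [table.k00, table.k10, table.k01, table.k11])
        }
        for key, obs in observed.items():
            p = truth["cells"][f"{key[0]}_{key[1]}"]
            sd = math.sqrt(n_group * p * (1 - p))
            assert abs(obs - n_group * p) < 4 * sd + 1


def test_controls_in_hardy_weinberg_across_seeds():
    cfg = SimConfig(n_cases=200, n_controls=1000)
    rng = np.random.default_rng(5)
    pvals = []
    for s in rng.integers(0, 2**31 - 1, 100):
        cohort, _ = simulate_cohort(dataclasses.replace(cfg, seed=int(s)))
        g = genotype_counts(cohort, where=lambda r: not r.is_case)
        pvals.append(hwe_chi_square(g).p)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.005


def test_unreachable_targets_raise():
    cfg = SimConfig(beta0=math.log(0.0005 / 0.9995), population_cap_factor=10)
    with pytest.raises(ValueError, match="unreachable"):
        simulate_cohort(cfg)


def test_prevalence_closed_form_matches_population():
    cfg = SimConfig(seed=17)
    prev = population_prevalence(cfg)
    rng = np.random.default_rng(17)
    # direct forward simulation of the disease model
    n = 400_000
    p, t = cfg.maf, cfg.tag_allele_freq
    g = rng.choice(3, size=n, p=[(1 - p) ** 2, 2 * p * (1 - p), p * p])
    h = (rng.choice(3, size=n, p=[(1 - t) ** 2, 2 * t * (1 - t), t * t]) >= 1).astype(int)
    logit = cfg.beta0 + cfg.beta_geno * g + cfg.beta_hla * h + cfg.beta_interaction * (g >= 1) * h
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    assert y.mean() == pytest.approx(prev, abs=4 * math.sqrt(prev * (1 - prev) / n))


def test_recovery_single_replicate_shape():
    cfg = SimConfig(n_cases=200, n_controls=400, seed=3)
    res = recovery_experiment(cfg, n_reps=1, estimator="sf")
    assert len(res.table) == 1
    assert res.coverage in (0.0, 1.0)
    assert res.n_failed == 0


def test_recovery_rejects_unknown_estimator():
    with pytest.raises(ValueError, match="estimator"):
        recovery_experiment(SimConfig(), 1, estimator="magic")


def test_aoo_recessive_shift_recovered():
    """A +3y AA-homozygote onset shift is recovered by recessive regression."""
    from snp_epistat import phenotype_regression

    cfg = SimConfig(
        n_cases=2000, n_controls=500,
        aoo_beta_geno=3.0, aoo_coding="recessive", seed=0,
    )
    rng = np.random.default_rng(31)
    hits = 0
    reps = 100
    for s in rng.integers(0, 2**31 - 1, reps):
        cohort, _ = simulate_cohort(dataclasses.replace(cfg, seed=int(s)))
        fit = phenotype_regression(cohort, "aoo", model="recessive", covariates=())
        hits += 1.5 <= fit.slope <= 4.5
    assert hits / reps >= 0.90
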