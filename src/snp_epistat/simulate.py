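"""Synthetic case-control cohorts with the structure the analysis assumes.

Subjects are drawn from a virtual population: SNP genotype from
Hardy-Weinberg proportions at the minor-allele frequency, HLA tag-allele
copies from Hardy-Weinberg at the frequency implied by the carrier
probability, and disease status from a logistic model

    logit P(D) = beta0 + beta_geno * g + beta_hla * h + beta_interaction * (g >= 1) * h

where g is minor-allele dosage and h the HLA carrier flag. Cases and controls
are then subsampled to the target counts (retrospective sampling), so
covariate-adjusted estimators are exercised under the sampling scheme real
case-control studies use. Age and sex are generated with case/control offsets
(controls older, cases more often female) to exercise confounder adjustment;
they do not themselves enter the disease model. Case-only phenotypes (course,
age of onset, duration, EDSS, MSSS) are generated last.

Default parameters emulate the study margins this package targets: 579/1145
cases/controls, MAF 0.31, 20% HLA carriers in the population, carrier odds
ratio 3.77, per-allele genotype odds ratio 1.07, antagonistic interaction
(synergy factor) 0.62, and a 1% baseline disease odds among double-negatives
so the target case count is reachable from a capped population draw.

All randomness flows from one integer seed through a single generator with
fixed draw order (genotype -> carrier -> covariate latents -> status ->
phenotypes), so cohorts are byte-stable across runs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .association import Counts2x2, crude_or, fit_logistic
from .cohort import SubjectRecord, cohort_to_frame
from .epistasis import classify_joint_exposure, synergy_from_table

__all__ = ["SimConfig", "simulate_cohort", "recovery_experiment", "RecoveryResult",
           "expected_joint_cells", "population_prevalence"]


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic cohort. All rates are population
    (control-like) frequencies; betas are log odds ratios."""

    n_cases: int = 579
    n_controls: int = 1145
    maf: float = 0.31
    carrier_freq: float = 0.20
    beta0: float = math.log(0.01 / 0.99)
    beta_geno: float = math.log(1.07)
    beta_hla: float = math.log(3.77)
    beta_interaction: float = math.log(0.62)
    # covariate generators (group offsets; not part of the disease model)
    control_age_mean: float = 51.86
    control_age_sd: float = 21.09
    duration_mean: float = 11.91
    duration_sd: float = 7.13
    case_female_frac: float = 403 / 579
    control_female_frac: float = 717 / 1145
    # case-only phenotype generators
    aoo_mean: float = 29.68
    aoo_sd: float = 9.78
    aoo_beta_geno: float = 0.0  # phenotype shift per encoded genotype unit, years
    aoo_coding: str = "log_additive"  # log_additive | dominant | recessive
    msss_mean: float = 4.41
    msss_sd: float = 2.09
    msss_beta_geno: float = 0.0
    msss_coding: str = "log_additive"
    edss_mean: float = 3.56
    edss_sd: float = 1.56
    sp_logit0: float = -1.65
    sp_beta_carrier: float = math.log(0.41)
    population_cap_factor: int = 100
    seed: int = 20220721

    def __post_init__(self) -> None:
        for name in ("maf", "carrier_freq"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("target counts must be positive")

    @property
    def tag_allele_freq(self) -> float:
        """HLA tag allele frequency t with 1 - (1-t)^2 = carrier_freq."""
        return 1.0 - math.sqrt(1.0 - self.carrier_freq)


def _cell_grid(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(g, h, P(g)P(h), P(D|g,h)) over the six genotype x carrier cells."""
    p = cfg.maf
    pg = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    ph = np.array([1 - cfg.carrier_freq, cfg.carrier_freq])
    g = np.repeat([0, 1, 2], 2)
    h = np.tile([0, 1], 3)
    prob = pg[g] * ph[h]
    logit = cfg.beta0 + cfg.beta_geno * g + cfg.beta_hla * h + cfg.beta_interaction * (g >= 1) * h
    return g, h, prob, expit(logit)


def population_prevalence(cfg: SimConfig) -> float:
    """Closed-form disease prevalence implied by the generating model."""
    _, _, prob, risk = _cell_grid(cfg)
    return float(np.sum(prob * risk))


def expected_joint_cells(cfg: SimConfig) -> dict:
    """Closed-form joint-exposure cell probabilities and crude truth values.

    Returns case/control probabilities over the four (A carrier, HLA carrier)
    cells plus the crude carrier-level component ORs and synergy factor the
    8-cell estimator converges to, and the crude dominant OR for the SNP.
    """
    g, h, prob, risk = _cell_grid(cfg)
    prev = float(np.sum(prob * risk))
    case_p = prob * risk / prev
    ctrl_p = prob * (1 - risk) / (1 - prev)
    cells = {}
    for name, source in (("case", case_p), ("control", ctrl_p)):
        for a_flag in (0, 1):
            for h_flag in (0, 1):
                mask = ((g >= 1).astype(int) == a_flag) & (h == h_flag)
                cells[(name, a_flag, h_flag)] = float(np.sum(source[mask]))

    def cell_or(a_flag: int, h_flag: int) -> float:
        return (cells[("case", a_flag, h_flag)] * cells[("control", 0, 0)]) / (
            cells[("case", 0, 0)] * cells[("control", a_flag, h_flag)]
        )

    or10, or01, or11 = cell_or(1, 0), cell_or(0, 1), cell_or(1, 1)
    p_dom_case = cells[("case", 1, 0)] + cells[("case", 1, 1)]
    p_dom_ctrl = cells[("control", 1, 0)] + cells[("control", 1, 1)]
    dom_or = (p_dom_case / (1 - p_dom_case)) / (p_dom_ctrl / (1 - p_dom_ctrl))
    return {
        "prevalence": prev,
        "cells": cells,
        "or10": or10,
        "or01": or01,
        "or11": or11,
        "sf_crude": or11 / (or10 * or01),
        "dominant_or_crude": dom_or,
    }


def simulate_cohort(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[SubjectRecord], dict]:
    """Draw one cohort; returns (records, truth).

    ``truth`` carries every generating parameter plus the closed-form
    quantities of :func:`expected_joint_cells`. Deterministic for a fixed
    ``cfg.seed`` (or a supplied generator).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    prev = population_prevalence(cfg)
    cap = cfg.population_cap_factor * (cfg.n_cases + cfg.n_controls)
    if cap * prev < cfg.n_cases * 1.05 or cap * (1 - prev) < cfg.n_controls * 1.05:
        raise ValueError(
            f"target counts unreachable: population cap {cap} at prevalence {prev:.4g} "
            f"cannot supply {cfg.n_cases} cases and {cfg.n_controls} controls"
        )

    p, t = cfg.maf, cfg.tag_allele_freq
    genotypes = np.empty(0, dtype=np.int64)
    copies = np.empty(0, dtype=np.int64)
    u_age = np.empty(0)
    u_sex = np.empty(0)
    status = np.empty(0, dtype=bool)
    n_draw = 0
    while True:
        need_more = (status.sum() < cfg.n_cases) or ((~status).sum() < cfg.n_controls)
        if not need_more:
            break
        batch = int(
            min(
                cap - n_draw,
                max(2_000, 1.3 * max(cfg.n_cases / prev, cfg.n_controls / (1 - prev))),
            )
        )
        if batch <= 0:
            raise ValueError("population cap reached before target counts were met")
        n_draw += batch
        g = rng.choice(3, size=batch, p=[(1 - p) ** 2, 2 * p * (1 - p), p * p])
        c = rng.choice(3, size=batch, p=[(1 - t) ** 2, 2 * t * (1 - t), t * t])
        ua = rng.random(batch)
        us = rng.random(batch)
        h = (c >= 1).astype(int)
        risk = expit(
            cfg.beta0 + cfg.beta_geno * g + cfg.beta_hla * h + cfg.beta_interaction * (g >= 1) * h
        )
        s = rng.random(batch) < risk
        genotypes = np.concatenate([genotypes, g])
        copies = np.concatenate([copies, c])
        u_age = np.concatenate([u_age, ua])
        u_sex = np.concatenate([u_sex, us])
        status = np.concatenate([status, s])

    case_idx = np.flatnonzero(status)[: cfg.n_cases]
    ctrl_idx = np.flatnonzero(~status)[: cfg.n_controls]
    idx = np.concatenate([case_idx, ctrl_idx])
    is_case = np.concatenate([np.ones(len(case_idx), bool), np.zeros(len(ctrl_idx), bool)])

    g = genotypes[idx]
    cp = copies[idx]
    z_latent = stats.norm.ppf(u_age[idx])
    female_frac = np.where(is_case, cfg.case_female_frac, cfg.control_female_frac)
    female = u_sex[idx] < female_frac

    n_case = len(case_idx)
    gc = g[:n_case]

    def encode(coding: str, dosage: np.ndarray) -> np.ndarray:
        if coding == "log_additive":
            return dosage.astype(float)
        if coding == "dominant":
            return (dosage >= 1).astype(float)
        if coding == "recessive":
            return (dosage == 2).astype(float)
        raise ValueError(f"unknown phenotype effect coding {coding!r}")

    # cases: onset and duration are drawn, current age is their sum (so the
    # onset distribution is never truncated by an independently drawn age);
    # controls: age straight from the offset normal
    aoo = np.maximum(
        cfg.aoo_mean
        + cfg.aoo_beta_geno * encode(cfg.aoo_coding, gc)
        + cfg.aoo_sd * z_latent[:n_case],
        5.0,
    )
    duration = np.clip(
        cfg.duration_mean + cfg.duration_sd * rng.standard_normal(n_case), 0.5, 60.0
    )
    age = np.empty(len(idx))
    age[:n_case] = aoo + duration
    age[n_case:] = np.clip(
        cfg.control_age_mean + cfg.control_age_sd * z_latent[n_case:], 18.0, 100.0
    )
    edss = np.clip(
        np.round((cfg.edss_mean + cfg.edss_sd * rng.standard_normal(n_case)) * 2) / 2, 0.0, 10.0
    )
    msss = np.clip(
        cfg.msss_mean
        + cfg.msss_beta_geno * encode(cfg.msss_coding, gc)
        + cfg.msss_sd * rng.standard_normal(n_case),
        0.01,
        9.99,
    )
    p_sp = expit(cfg.sp_logit0 + cfg.sp_beta_carrier * (gc >= 1))
    sp = rng.random(n_case) < p_sp

    records: list[SubjectRecord] = []
    for i in range(len(idx)):
        case = bool(is_case[i])
        j = i  # case rows come first
        records.append(
            SubjectRecord(
                subject_id=f"S{i + 1:05d}",
                status="case" if case else "control",
                genotype=int(g[i]),
                hla_carrier=bool(cp[i] >= 1),
                hla_copies=int(cp[i]),
                sex="female" if female[i] else "male",
                age=float(round(age[i], 1)),
                ms_course=("SP" if sp[j] else "RR") if case else None,
                aoo=float(round(aoo[j], 1)) if case else None,
                duration=float(round(duration[j], 1)) if case else None,
                edss=float(edss[j]) if case else None,
                msss=float(round(msss[j], 2)) if case else None,
            )
        )

    truth = dataclasses.asdict(cfg)
    truth.update(expected_joint_cells(cfg))
    truth["cells"] = {f"{k[0]}_{k[1]}{k[2]}": v for k, v in truth["cells"].items()}
    truth["n_population_drawn"] = int(n_draw)
    return records, truth


# ---------------------------------------------------------------------------
# Parameter-recovery experiments


@dataclass
class RecoveryResult:
    estimator: str
    truth: float
    table: pd.DataFrame  # per-replicate estimate, ci_low, ci_high, covered, ok
    bias: float  # mean(log est) - log truth for ratio estimands, plain for slopes
    rmse: float
    coverage: float
    n_failed: int


def _estimate_once(cohort: Sequence[SubjectRecord], estimator: str, cfg: SimConfig):
    if estimator == "sf":
        res = synergy_from_table(classify_joint_exposure(cohort))
        return res.sf, res.sf_ci
    if estimator == "dominant_or":
        n = [[0, 0], [0, 0]]  # [case][carrier]
        for r in cohort:
            if r.genotype is None:
                continue
            n[int(r.is_case)][int(r.genotype >= 1)] += 1
        res = crude_or(Counts2x2(a=n[1][1], b=n[1][0], c=n[0][1], d=n[0][0]), model="dominant")
        return res.or_hat, (res.ci_low, res.ci_high)
    if estimator == "log_additive_or":
        frame = cohort_to_frame(cohort)
        frame["axh"] = frame["a_carrier"] * frame["hla"]
        cols = ["genotype", "hla"] + (["axh"] if cfg.beta_interaction != 0 else [])
        sub = frame[["is_case", *cols]].dropna()
        fit = fit_logistic(sub["is_case"].to_numpy(), sub[cols])
        from .association import Z975

        b, se = float(fit.params["genotype"]), float(fit.bse["genotype"])
        return math.exp(b), (math.exp(b - Z975 * se), math.exp(b + Z975 * se))
    if estimator == "aoo_slope":
        frame = cohort_to_frame([r for r in cohort if r.is_case])
        sub = frame[["aoo", "genotype"]].dropna()
        import statsmodels.api as sm

        X = sm.add_constant(sub["genotype"].to_numpy())
        fit = sm.OLS(sub["aoo"].to_numpy(), X).fit()
        lo, hi = fit.conf_int()[1]
        return float(fit.params[1]), (float(lo), float(hi))
    raise ValueError(f"unknown estimator {estimator!r}")


_TRUTHS = {
    "sf": lambda cfg, t: t["sf_crude"],
    "dominant_or": lambda cfg, t: t["dominant_or_crude"],
    "log_additive_or": lambda cfg, t: math.exp(cfg.beta_geno),
    "aoo_slope": lambda cfg, t: cfg.aoo_beta_geno,
}


def recovery_experiment(
    cfg: SimConfig,
    n_reps: int,
    estimator: str = "sf",
    seed: Optional[int] = None,
) -> RecoveryResult:
    """Simulate ``n_reps`` cohorts under ``cfg`` and re-estimate one estimand.

    Estimators: ``sf`` (crude 8-cell synergy factor), ``dominant_or`` and
    ``log_additive_or`` (the latter adjusted for HLA carrier status, matching
    the generating model so its truth is exp(beta_geno)), ``aoo_slope``
    (case-only per-allele regression of age of onset). Coverage is the
    fraction of per-replicate 95% CIs containing the closed-form truth.
    Replicates where the estimator fails are flagged, never dropped silently.
    """
    if estimator not in _TRUTHS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {sorted(_TRUTHS)}")
    master = np.random.default_rng(cfg.seed if seed is None else seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=n_reps)
    truth_info = expected_joint_cells(cfg)
    truth = float(_TRUTHS[estimator](cfg, truth_info))

    rows = []
    for s in rep_seeds:
        rep_cfg = dataclasses.replace(cfg, seed=int(s))
        try:
            cohort, _ = simulate_cohort(rep_cfg)
            est, (lo, hi) = _estimate_once(cohort, estimator, cfg)
            rows.append((est, lo, hi, lo <= truth <= hi, True))
        except (ValueError, RuntimeError):
            rows.append((math.nan, math.nan, math.nan, False, False))
    table = pd.DataFrame(rows, columns=["estimate", "ci_low", "ci_high", "covered", "ok"])
    ok = table[table["ok"]]
    ratio_scale = estimator in ("sf", "dominant_or", "log_additive_or")
    if len(ok):
        if ratio_scale:
            err = np.log(ok["estimate"].to_numpy()) - math.log(truth)
        else:
            err = ok["estimate"].to_numpy() - truth
        bias = float(np.mean(err))
        rmse = float(np.sqrt(np.mean(err**2)))
        coverage = float(ok["covered"].mean())
    else:
        bias = rmse = coverage = math.nan
    return RecoveryResult(
        estimator=estimator,
        truth=truth,
        table=table,
        bias=bias,
        rmse=rmse,
        coverage=coverage,
        n_failed=int((~table["ok"]).sum()),
    )
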