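"""Hardy-Weinberg testing and odds-ratio estimation under genetic inheritance models.

Implements the standard candidate-gene toolkit for a biallelic SNP:

* Hardy-Weinberg equilibrium goodness-of-fit (Pearson chi-square, 1 df, allele
  frequency estimated from the tested counts, no continuity correction).
* Crude odds ratios from 2x2 tables with the Woolf log-interval
  (CI = exp(ln OR ± z·SE), SE = sqrt(1/a + 1/b + 1/c + 1/d)) and the
  Haldane-Anscombe +0.5 correction applied only when a cell is zero.
* Covariate-adjusted odds ratios by maximum-likelihood logistic regression
  under codominant, dominant, recessive, over-dominant and log-additive
  codings, with both per-contrast Wald p-values and a per-model
  likelihood-ratio p.
* The allele-contrast ("allelic") model is computed crude at chromosome level
  (each subject contributes two alleles); covariate adjustment is ill-defined
  per chromosome, so it is never adjusted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import (
    Counts2x2,
    GenotypeCounts,
    SubjectRecord,
    allele_counts,
    cohort_to_frame,
    genotype_counts,
)

__all__ = [
    "HweResult",
    "ORResult",
    "LogisticFit",
    "SeparationError",
    "ConvergenceError",
    "GENETIC_MODELS",
    "DEFAULT_SCAN_MODELS",
    "hwe_chi_square",
    "crude_or",
    "fit_logistic",
    "association_scan",
    "stratified_scan",
]

#: 97.5% normal quantile fixed for CI reproducibility
Z975 = 1.959964

#: genotype dosage (0/1/2 copies of A) -> design column(s); codominant is two indicators
GENETIC_MODELS: Mapping[str, Callable[[np.ndarray], dict[str, np.ndarray]]] = {
    "codominant": lambda g: {"geno_CA": (g == 1).astype(float), "geno_AA": (g == 2).astype(float)},
    "dominant": lambda g: {"geno_dom": (g >= 1).astype(float)},
    "recessive": lambda g: {"geno_rec": (g == 2).astype(float)},
    "overdominant": lambda g: {"geno_het": (g == 1).astype(float)},
    "log_additive": lambda g: {"geno_add": g.astype(float)},
}

#: output order mirrors the conventional association-table layout
DEFAULT_SCAN_MODELS = (
    "allelic",
    "codominant",
    "dominant",
    "recessive",
    "overdominant",
    "log_additive",
)

_CONTRAST_LABELS = {
    "allelic": "Allele contrast (A vs. C)",
    "codominant_CA": "Codominant (CA vs. CC)",
    "codominant_AA": "Codominant (AA vs. CC)",
    "dominant": "Dominant (AA + CA vs. CC)",
    "recessive": "Recessive (AA vs. CA + CC)",
    "overdominant": "Over-dominant (CA vs. CC + AA)",
    "log_additive": "Log-additive",
}


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation detected in a logistic fit."""


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge within the iteration budget."""


@dataclass(frozen=True)
class HweResult:
    chi2: float
    df: int
    p: float
    expected_counts: tuple[float, float, float]


@dataclass(frozen=True)
class ORResult:
    """One odds ratio with its 95% CI and test.

    ``method`` records provenance: ``woolf_crude`` (cross-product with Woolf
    interval), ``woolf_haldane`` (same after +0.5 on all cells),
    ``logistic_wald`` (adjusted ML fit). ``lrt_p`` is the likelihood-ratio
    p for the genotype term(s) when the estimate comes from a regression.
    """

    model: str
    or_hat: float
    ci_low: float
    ci_high: float
    p: float
    method: str
    adjusted_for: tuple[str, ...] = ()
    lrt_p: Optional[float] = None
    estimable: bool = True
    note: str = ""

    @property
    def label(self) -> str:
        return _CONTRAST_LABELS.get(self.model, self.model)


def hwe_chi_square(g: GenotypeCounts) -> HweResult:
    """Hardy-Weinberg equilibrium test on observed CC/CA/AA counts.

    The minor-allele frequency q is estimated from the same counts; expected
    counts are (n(1-q)^2, 2nq(1-q), nq^2); the statistic is the Pearson
    chi-square with 1 df (3 genotype classes, 1 estimated parameter), without
    continuity correction.
    """
    n = g.n
    n_c, n_a = allele_counts(g)
    if n_c == 0 or n_a == 0:
        raise ValueError("HWE undefined for monomorphic locus")
    q = n_a / (2 * n)
    expected = (n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q * q)
    observed = (g.n_cc, g.n_ca, g.n_aa)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return HweResult(chi2=float(chi2), df=1, p=float(stats.chi2.sf(chi2, 1)), expected_counts=expected)


def crude_or(t: Counts2x2, model: str = "crude") -> ORResult:
    """Crude odds ratio (a·d)/(b·c) with the Woolf log-scale interval.

    A single zero cell triggers the Haldane-Anscombe correction (+0.5 to all
    four cells, flagged in ``method``); a table with an empty margin has no
    defined OR and raises.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("odds ratio undefined: the 2x2 table has an empty margin")
    method = "woolf_crude"
    if t.has_zero_cell:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method = "woolf_haldane"
    or_hat = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_hat)
    p = 2.0 * stats.norm.sf(abs(log_or) / se)
    return ORResult(
        model=model,
        or_hat=or_hat,
        ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se),
        p=float(p),
        method=method,
    )


@dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    llf: float
    n_obs: int
    converged: bool
    n_iter: int

    def or_result(self, term: str, model: str, adjusted_for: tuple[str, ...],
                  lrt_p: Optional[float] = None) -> ORResult:
        beta = float(self.params[term])
        se = float(self.bse[term])
        return ORResult(
            model=model,
            or_hat=math.exp(beta),
            ci_low=math.exp(beta - Z975 * se),
            ci_high=math.exp(beta + Z975 * se),
            p=float(self.pvalues[term]),
            method="logistic_wald",
            adjusted_for=adjusted_for,
            lrt_p=lrt_p,
        )


_SEPARATION_BOUND = 15.0  # |log-odds| beyond this is numerically degenerate


def fit_logistic(outcome: np.ndarray, design: pd.DataFrame, add_intercept: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton-Raphson).

    Raises :class:`SeparationError` when a coefficient diverges past
    |beta| > 15 (complete or quasi-complete separation) and
    :class:`ConvergenceError` if the optimizer does not converge within 100
    iterations at tolerance 1e-10.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    X = design.astype(float).copy()
    if add_intercept:
        X.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=0)
        except np.linalg.LinAlgError as exc:  # singular Hessian mid-iteration
            raise SeparationError(f"logistic fit failed (singular Hessian): {exc}") from exc
    if np.max(np.abs(res.params.to_numpy())) > _SEPARATION_BOUND:
        raise SeparationError(
            "coefficient diverged beyond |beta| > 15; data are (quasi-)separated"
        )
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"logistic regression did not converge in {res.mle_retvals.get('iterations')} iterations"
        )
    return LogisticFit(
        params=res.params,
        bse=res.bse,
        zvalues=res.tvalues,
        pvalues=res.pvalues,
        llf=float(res.llf),
        n_obs=int(res.nobs),
        converged=True,
        n_iter=int(res.mle_retvals.get("iterations", -1)),
    )


def _inestimable(model: str, adjusted_for: tuple[str, ...], note: str) -> ORResult:
    return ORResult(
        model=model, or_hat=math.nan, ci_low=math.nan, ci_high=math.nan, p=math.nan,
        method="inestimable", adjusted_for=adjusted_for, estimable=False, note=note,
    )


def association_scan(
    cohort: Sequence[SubjectRecord],
    models: Iterable[str] = DEFAULT_SCAN_MODELS,
    covariates: Sequence[str] = ("age", "is_male", "hla"),
    comparison: Optional[tuple[Callable[[SubjectRecord], bool], Callable[[SubjectRecord], bool]]] = None,
) -> list[ORResult]:
    """Odds ratios for one group comparison under a set of inheritance models.

    ``comparison`` is a (case-selector, control-selector) pair of predicates;
    the default compares cases to controls. The allelic model is always a
    crude chromosome-level 2x2; genotype models are logistic fits adjusted
    for ``covariates`` (columns of :func:`cohort_to_frame`: ``age``,
    ``is_male``, ``hla``). Inestimable contrasts (an empty exposed stratum)
    are returned flagged, not dropped.
    """
    if comparison is None:
        sel_case = lambda r: r.status == "case"  # noqa: E731
        sel_ctrl = lambda r: r.status == "control"  # noqa: E731
    else:
        sel_case, sel_ctrl = comparison
    covariates = tuple(covariates)

    subjects = [r for r in cohort if r.genotype is not None and (sel_case(r) or sel_ctrl(r))]
    if not any(sel_case(r) for r in subjects) or not any(sel_ctrl(r) for r in subjects):
        raise ValueError("both comparison groups must be non-empty after genotype filtering")

    frame = cohort_to_frame(subjects)
    frame["y"] = [1.0 if sel_case(r) else 0.0 for r in subjects]

    results: list[ORResult] = []
    for model in models:
        if model == "allelic":
            g_case = genotype_counts(subjects, where=sel_case, group_label="case")
            g_ctrl = genotype_counts(subjects, where=sel_ctrl, group_label="control")
            (c_c, a_c), (c_k, a_k) = allele_counts(g_case), allele_counts(g_ctrl)
            results.append(
                crude_or(Counts2x2(a=a_c, b=c_c, c=a_k, d=c_k), model="allelic")
            )
            continue
        if model not in GENETIC_MODELS:
            raise ValueError(f"unknown genetic model {model!r}")

        cols = GENETIC_MODELS[model](frame["genotype"].to_numpy())
        sub = frame[["y", *covariates]].copy()
        for name, vals in cols.items():
            sub[name] = vals
        sub = sub.dropna()
        term_names = list(cols)
        if sub.empty or any(sub[t].sum() == 0 for t in term_names) or \
                any((sub[t] == 0).sum() == 0 for t in term_names if model != "codominant"):
            results.append(_inestimable(model, covariates, "empty exposed or reference stratum"))
            continue
        design = sub[term_names + list(covariates)]
        try:
            full = fit_logistic(sub["y"].to_numpy(), design)
            lrt_p: Optional[float] = None
            if covariates:
                reduced = fit_logistic(sub["y"].to_numpy(), sub[list(covariates)])
            else:
                base = sm.Logit(sub["y"].to_numpy(), np.ones((len(sub), 1))).fit(disp=0)
                reduced = LogisticFit(
                    params=pd.Series(base.params), bse=pd.Series(base.bse),
                    zvalues=pd.Series(base.tvalues), pvalues=pd.Series(base.pvalues),
                    llf=float(base.llf), n_obs=int(base.nobs), converged=True, n_iter=0,
                )
            lr_stat = 2.0 * (full.llf - reduced.llf)
            lrt_p = float(stats.chi2.sf(max(lr_stat, 0.0), df=len(term_names)))
        except (SeparationError, ConvergenceError) as exc:
            results.append(_inestimable(model, covariates, str(exc)))
            continue

        if model == "codominant":
            results.append(full.or_result("geno_CA", "codominant_CA", covariates, lrt_p))
            results.append(full.or_result("geno_AA", "codominant_AA", covariates, lrt_p))
        else:
            results.append(full.or_result(term_names[0], model, covariates, lrt_p))
    return results


def stratified_scan(
    cohort: Sequence[SubjectRecord],
    stratifier: str = "hla_carrier",
    models: Iterable[str] = DEFAULT_SCAN_MODELS,
    covariates: Sequence[str] = ("age", "is_male"),
    comparison: Optional[tuple] = None,
) -> dict[str, list[ORResult]]:
    """Run :func:`association_scan` separately in each stratum of a binary flag.

    The stratifier is automatically removed from the covariate list (it is
    constant within stratum). Returns ``{"positive": [...], "negative": [...]}``;
    a constant stratifier yields a single stratum with a warning.
    """
    strat_cols = {stratifier, "hla"} if stratifier == "hla_carrier" else {stratifier}
    covariates = tuple(c for c in covariates if c not in strat_cols)
    values = {getattr(r, stratifier) for r in cohort if getattr(r, stratifier) is not None}
    out: dict[str, list[ORResult]] = {}
    if len(values) < 2:
        warnings.warn(f"stratifier {stratifier!r} is constant; returning a single stratum", stacklevel=2)
    for value in sorted(values, reverse=True):
        label = "positive" if value else "negative"
        stratum = [r for r in cohort if getattr(r, stratifier) == value]
        out[label] = association_scan(stratum, models=models, covariates=covariates, comparison=comparison)
    return out
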