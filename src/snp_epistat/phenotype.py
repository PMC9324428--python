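"""Genotype-phenotype linear regression for case-only quantitative traits.

Age of onset (AOO) and the MS severity score (MSSS) are regressed on the SNP
genotype under each inheritance coding by ordinary least squares, with study
covariates (sex, HLA carrier status, and AOO for severity models). The
"best model" reported alongside descriptive per-genotype means is purely a
reporting convention — the coding with the smallest genotype-term p-value
(ties broken by AIC) — not a formal inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association import GENETIC_MODELS
from .cohort import CODE_LABELS, SubjectRecord, cohort_to_frame

__all__ = [
    "PhenotypeResult",
    "phenotype_regression",
    "select_best_model",
    "phenotype_scan",
    "DEFAULT_PHENOTYPE_COVARIATES",
]

#: covariate sets used for each phenotype, whole cohort vs within-stratum
DEFAULT_PHENOTYPE_COVARIATES = {
    ("aoo", "whole"): ("is_male", "hla"),
    ("aoo", "stratum"): ("is_male",),
    ("msss", "whole"): ("aoo", "is_male", "hla"),
    ("msss", "stratum"): ("aoo", "is_male"),
}

_PHENO_MODELS = ("dominant", "recessive", "overdominant", "log_additive", "codominant")


@dataclass(frozen=True)
class PhenotypeResult:
    phenotype: str
    stratum: str
    model: str
    genotype_stats: dict  # "CC"/"CA"/"AA" -> (mean, sd, n)
    slope: Optional[float]
    se: Optional[float]
    p: float
    adjusted_for: tuple[str, ...]
    n: int
    aic: float
    degenerate: bool = False


def _genotype_descriptives(frame: pd.DataFrame, phenotype: str) -> dict:
    out = {}
    for code, label in CODE_LABELS.items():
        vals = frame.loc[frame["genotype"] == code, phenotype].dropna().to_numpy()
        mean = float(np.mean(vals)) if vals.size else math.nan
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else math.nan
        out[label] = (mean, sd, int(vals.size))
    return out


def phenotype_regression(
    cohort: Sequence[SubjectRecord],
    phenotype: str,
    model: str = "dominant",
    covariates: Sequence[str] = (),
    stratum: str = "whole",
    where: Optional[Callable[[SubjectRecord], bool]] = None,
) -> PhenotypeResult:
    """OLS fit of a case phenotype on one encoded genotype term plus covariates.

    Only cases enter; ``where`` restricts further (e.g. to an HLA stratum).
    Covariates name columns of :func:`cohort_to_frame` (``is_male``, ``hla``,
    ``aoo``, ``age``). For the two-column codominant coding the reported p is
    the joint F test of both genotype indicators and slope is ``None``.
    A phenotype with zero residual variance is returned flagged degenerate
    with slope 0 and p 1; a rank-deficient design raises, naming the columns.
    """
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    cases = [r for r in cohort if r.status == "case" and (where is None or where(r))]
    frame = cohort_to_frame(cases) if cases else pd.DataFrame()
    if frame.empty:
        raise ValueError("no cases selected")
    cols = list(dict.fromkeys(["genotype", phenotype, *covariates]))
    sub = frame[cols].dropna()
    if len(sub) < 3 or sub["genotype"].nunique() < 2:
        raise ValueError("need >= 3 complete cases spanning >= 2 genotype groups")

    descriptives = _genotype_descriptives(frame, phenotype)
    terms = GENETIC_MODELS[model](sub["genotype"].to_numpy())
    design = pd.DataFrame(terms, index=sub.index)
    for c in covariates:
        design[c] = sub[c]
    design.insert(0, "const", 1.0)

    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        bad = [
            c for c in design.columns if c != "const"
            and np.linalg.matrix_rank(design.drop(columns=c).to_numpy()) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or list(design.columns)}")

    y = sub[phenotype].to_numpy(dtype=float)
    covariates = tuple(covariates)
    if np.ptp(y) == 0:
        return PhenotypeResult(
            phenotype=phenotype, stratum=stratum, model=model,
            genotype_stats=descriptives, slope=0.0, se=0.0, p=1.0,
            adjusted_for=covariates, n=len(sub), aic=math.nan, degenerate=True,
        )

    fit = sm.OLS(y, design).fit()
    term_names = list(terms)
    if model == "codominant":
        contrast = np.zeros((2, design.shape[1]))
        for i, t in enumerate(term_names):
            contrast[i, design.columns.get_loc(t)] = 1.0
        ftest = fit.f_test(contrast)
        slope, se, p = None, None, float(ftest.pvalue)
    else:
        t = term_names[0]
        slope = float(fit.params[t])
        se = float(fit.bse[t])
        p = float(fit.pvalues[t])
    return PhenotypeResult(
        phenotype=phenotype, stratum=stratum, model=model,
        genotype_stats=descriptives, slope=slope, se=se, p=p,
        adjusted_for=covariates, n=len(sub), aic=float(fit.aic),
    )


def select_best_model(fits: Sequence[PhenotypeResult]) -> PhenotypeResult:
    """Reporting convention: the fit with the smallest genotype-term p; ties
    broken by smaller AIC. Not a formal model-selection inference."""
    if not fits:
        raise ValueError("need at least one candidate fit")
    return min(fits, key=lambda f: (f.p, f.aic if not math.isnan(f.aic) else math.inf))


def phenotype_scan(
    cohort: Sequence[SubjectRecord],
    phenotypes: Iterable[str] = ("aoo", "msss"),
    models: Iterable[str] = _PHENO_MODELS,
    strata: Iterable[str] = ("whole", "hla_positive", "hla_negative"),
) -> list[PhenotypeResult]:
    """Best-model summary per phenotype and HLA stratum (report-table layout).

    Stratum regressions drop the carrier covariate (constant within stratum)
    and use the within-stratum covariate sets of
    ``DEFAULT_PHENOTYPE_COVARIATES``.
    """
    stratum_filters: dict[str, Optional[Callable[[SubjectRecord], bool]]] = {
        "whole": None,
        "hla_positive": lambda r: r.hla_carrier is True,
        "hla_negative": lambda r: r.hla_carrier is False,
    }
    results = []
    for pheno in phenotypes:
        for stratum in strata:
            kind = "whole" if stratum == "whole" else "stratum"
            covs = DEFAULT_PHENOTYPE_COVARIATES[(pheno, kind)]
            fits = []
            for model in models:
                try:
                    fits.append(
                        phenotype_regression(
                            cohort, pheno, model=model, covariates=covs,
                            stratum=stratum, where=stratum_filters[stratum],
                        )
                    )
                except ValueError:
                    continue
            if fits:
                results.append(select_best_model(fits))
    return results
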