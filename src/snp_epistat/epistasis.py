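"""Synergy-factor (SF) analysis of multiplicative gene-gene interaction.

Two binary carrier traits (here: at least one copy of the SNP minor allele,
and at least one copy of the HLA tagging allele) partition subjects into four
joint-exposure groups. With the double-negative group as reference, the
synergy factor is

    SF = OR_11 / (OR_10 * OR_01),

the ratio of the observed joint-exposure odds ratio to the one predicted if
the two factors acted independently on the odds scale. SF < 1 is antagonism
(sub-multiplicative joint effect), SF > 1 synergy.

Two estimation routes are provided and agree exactly when no covariates are
used (the 8-cell table is the saturated logistic model):

* ``crude_8cell`` — cross-product ORs from the 8 cells;
  SE(ln SF) = sqrt(sum of reciprocals of all 8 cells), normal (Wald) test.
* ``logistic_interaction`` — logistic fit of status on f1 + f2 + f1:f2
  (+ covariates); SF = exp(interaction coefficient), Wald test. This is the
  route for covariate-adjusted SF.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .association import Z975, ORResult, crude_or, fit_logistic
from .cohort import Counts2x2, SubjectRecord, cohort_to_frame

__all__ = [
    "JointExposureTable",
    "SynergyResult",
    "classify_joint_exposure",
    "synergy_factor_from_ors",
    "synergy_analysis",
    "synergy_from_table",
    "synergy_logistic",
]

FactorSpec = Union[str, Callable[[SubjectRecord], Optional[bool]]]

_NAMED_FACTORS: dict[str, Callable[[SubjectRecord], Optional[bool]]] = {
    "a_carrier": lambda r: r.a_carrier,
    "hla_carrier": lambda r: r.hla_carrier,
    "male_sex": lambda r: None if r.sex is None else r.sex == "male",
    "female_sex": lambda r: None if r.sex is None else r.sex == "female",
}


def _as_factor(f: FactorSpec) -> Callable[[SubjectRecord], Optional[bool]]:
    if callable(f):
        return f
    try:
        return _NAMED_FACTORS[f]
    except KeyError:
        raise ValueError(f"unknown factor {f!r}; use one of {sorted(_NAMED_FACTORS)} or a callable")


@dataclass(frozen=True)
class JointExposureTable:
    """Case and control counts over the four (factor1, factor2) carrier cells.

    Suffix ``xy`` means factor1 status x, factor2 status y (1 = carrier);
    ``c``/``k`` prefix cases/controls. ``c00``/``k00`` is the double-negative
    reference cell.
    """

    c00: int
    c10: int
    c01: int
    c11: int
    k00: int
    k10: int
    k01: int
    k11: int

    def __post_init__(self) -> None:
        if min(self.cells()) < 0:
            raise ValueError("cell counts must be nonnegative")

    def cells(self) -> tuple[int, ...]:
        return (self.c00, self.c10, self.c01, self.c11, self.k00, self.k10, self.k01, self.k11)

    @property
    def n_cases(self) -> int:
        return self.c00 + self.c10 + self.c01 + self.c11

    @property
    def n_controls(self) -> int:
        return self.k00 + self.k10 + self.k01 + self.k11

    def to_subject_rows(self) -> pd.DataFrame:
        """Expand to one row per subject (y, f1, f2) — the saturated-data view."""
        rows = []
        for (f1, f2), case_n, ctrl_n in [
            ((0, 0), self.c00, self.k00),
            ((1, 0), self.c10, self.k10),
            ((0, 1), self.c01, self.k01),
            ((1, 1), self.c11, self.k11),
        ]:
            rows.extend([(1.0, f1, f2)] * case_n)
            rows.extend([(0.0, f1, f2)] * ctrl_n)
        return pd.DataFrame(rows, columns=["y", "f1", "f2"])


def classify_joint_exposure(
    cohort: Sequence[SubjectRecord],
    factor1: FactorSpec = "a_carrier",
    factor2: FactorSpec = "hla_carrier",
) -> JointExposureTable:
    """Cross-classify complete-case subjects into the 8 joint-exposure cells."""
    f1 = _as_factor(factor1)
    f2 = _as_factor(factor2)
    counts = {(y, a, b): 0 for y in (0, 1) for a in (0, 1) for b in (0, 1)}
    for rec in cohort:
        v1, v2 = f1(rec), f2(rec)
        if v1 is None or v2 is None:
            continue
        counts[(int(rec.is_case), int(v1), int(v2))] += 1
    table = JointExposureTable(
        c00=counts[(1, 0, 0)], c10=counts[(1, 1, 0)], c01=counts[(1, 0, 1)], c11=counts[(1, 1, 1)],
        k00=counts[(0, 0, 0)], k10=counts[(0, 1, 0)], k01=counts[(0, 0, 1)], k11=counts[(0, 1, 1)],
    )
    if 0 in table.cells():
        warnings.warn("joint-exposure table has an empty cell", stacklevel=2)
    return table


def synergy_factor_from_ors(or11: float, or10: float, or01: float) -> float:
    """SF = OR_11 / (OR_10 * OR_01); defined for positive odds ratios only."""
    if min(or11, or10, or01) <= 0:
        raise ValueError("odds ratios must be positive")
    return or11 / (or10 * or01)


@dataclass(frozen=True)
class SynergyResult:
    or10: ORResult
    or01: ORResult
    or11: ORResult
    predicted_or: float
    sf: float
    sf_ci: tuple[float, float]
    z: float
    p: float
    method: str
    adjusted_for: tuple[str, ...] = ()


def synergy_from_table(t: JointExposureTable, continuity: bool = True) -> SynergyResult:
    """Crude 8-cell synergy factor with Woolf-style normal inference on ln SF.

    Empty cells get the +0.5 Haldane-Anscombe correction on all 8 cells when
    ``continuity`` is true (they already trigger a warning at classification);
    two empty cells within one case/control margin leave the SF undefined.
    """
    cells = t.cells()
    if t.c00 == 0 and t.k00 == 0:
        raise ValueError("reference (double-negative) cell empty in both groups")
    for margin in (cells[:4], cells[4:]):
        if sum(1 for v in margin if v == 0) >= 2:
            raise ValueError("two empty cells in one case/control margin; SF undefined")
    shift = 0.0
    method = "crude_8cell"
    if 0 in cells:
        if not continuity:
            raise ValueError("empty cell; rerun with continuity=True for Haldane-Anscombe")
        shift = 0.5
        method = "crude_8cell_haldane"
    c00, c10, c01, c11, k00, k10, k01, k11 = (v + shift for v in cells)

    or10 = crude_or(Counts2x2(t.c10, t.c00, t.k10, t.k00), model="f1_only")
    or01 = crude_or(Counts2x2(t.c01, t.c00, t.k01, t.k00), model="f2_only")
    or11 = crude_or(Counts2x2(t.c11, t.c00, t.k11, t.k00), model="joint")

    ln_sf = (
        math.log((c11 * k00) / (c00 * k11))
        - math.log((c10 * k00) / (c00 * k10))
        - math.log((c01 * k00) / (c00 * k01))
    )
    se = math.sqrt(sum(1.0 / v for v in (c00, c10, c01, c11, k00, k10, k01, k11)))
    z = ln_sf / se
    p = 2.0 * stats.norm.sf(abs(z))
    sf = math.exp(ln_sf)
    return SynergyResult(
        or10=or10,
        or01=or01,
        or11=or11,
        predicted_or=or10.or_hat * or01.or_hat,
        sf=sf,
        sf_ci=(math.exp(ln_sf - Z975 * se), math.exp(ln_sf + Z975 * se)),
        z=float(z),
        p=float(p),
        method=method,
    )


def synergy_logistic(
    cohort: Sequence[SubjectRecord],
    factor1: FactorSpec = "a_carrier",
    factor2: FactorSpec = "hla_carrier",
    covariates: Sequence[str] = (),
) -> SynergyResult:
    """Synergy factor as exp(interaction coefficient) of a logistic model.

    Fits status ~ f1 + f2 + f1:f2 + covariates on complete cases; ``covariates``
    name columns of :func:`cohort_to_frame` (e.g. ``age``, ``is_male``). With no
    covariates this reproduces the crude 8-cell SF exactly (saturated model).
    """
    f1 = _as_factor(factor1)
    f2 = _as_factor(factor2)
    frame = cohort_to_frame(cohort)
    frame["f1"] = [None if f1(r) is None else float(f1(r)) for r in cohort]
    frame["f2"] = [None if f2(r) is None else float(f2(r)) for r in cohort]
    cols = ["is_case", "f1", "f2", *covariates]
    sub = frame[cols].apply(pd.to_numeric, errors="coerce").dropna()
    if sub.empty:
        raise ValueError("no complete-case subjects for the interaction model")
    sub["f1f2"] = sub["f1"] * sub["f2"]
    design = sub[["f1", "f2", "f1f2", *covariates]]
    fit = fit_logistic(sub["is_case"].to_numpy(), design)

    covariates = tuple(covariates)
    or10 = fit.or_result("f1", "f1_only", covariates)
    or01 = fit.or_result("f2", "f2_only", covariates)
    b = fit.params
    beta11 = float(b["f1"] + b["f2"] + b["f1f2"])
    # SE of the joint contrast needs the full covariance; recover it from the fit
    sf = math.exp(float(b["f1f2"]))
    se_int = float(fit.bse["f1f2"])
    z = float(b["f1f2"]) / se_int
    or11 = ORResult(
        model="joint",
        or_hat=math.exp(beta11),
        ci_low=math.nan,
        ci_high=math.nan,
        p=math.nan,
        method="logistic_wald",
        adjusted_for=covariates,
        note="CI for the joint contrast not reported (requires covariance of terms)",
    )
    return SynergyResult(
        or10=or10,
        or01=or01,
        or11=or11,
        predicted_or=or10.or_hat * or01.or_hat,
        sf=sf,
        sf_ci=(math.exp(float(b["f1f2"]) - Z975 * se_int), math.exp(float(b["f1f2"]) + Z975 * se_int)),
        z=z,
        p=float(fit.pvalues["f1f2"]),
        method="logistic_interaction",
        adjusted_for=covariates,
    )


def synergy_analysis(
    data: Union[JointExposureTable, Sequence[SubjectRecord]],
    mode: str = "crude_8cell",
    factor1: FactorSpec = "a_carrier",
    factor2: FactorSpec = "hla_carrier",
    covariates: Sequence[str] = (),
) -> SynergyResult:
    """Dispatch synergy-factor estimation.

    ``data`` is either an aggregated :class:`JointExposureTable` or a cohort
    of records. ``mode="crude_8cell"`` is the default; covariates force the
    ``logistic_interaction`` route (and require subject-level data for
    subject-specific covariates; an aggregated table is expanded to pseudo
    subject rows, which is only valid when covariates are empty).
    """
    if mode not in ("crude_8cell", "logistic_interaction"):
        raise ValueError(f"unknown mode {mode!r}")
    if covariates and mode == "crude_8cell":
        raise ValueError("covariate adjustment requires mode='logistic_interaction'")
    if isinstance(data, JointExposureTable):
        if mode == "crude_8cell":
            return synergy_from_table(data)
        if covariates:
            raise ValueError("an aggregated table carries no covariates; pass the cohort instead")
        rows = data.to_subject_rows()
        rows["f1f2"] = rows["f1"] * rows["f2"]
        fit = fit_logistic(rows["y"].to_numpy(), rows[["f1", "f2", "f1f2"]])
        b, se = float(fit.params["f1f2"]), float(fit.bse["f1f2"])
        return SynergyResult(
            or10=fit.or_result("f1", "f1_only", ()),
            or01=fit.or_result("f2", "f2_only", ()),
            or11=ORResult("joint", math.exp(float(fit.params["f1"] + fit.params["f2"] + b)),
                          math.nan, math.nan, math.nan, "logistic_wald"),
            predicted_or=math.exp(float(fit.params["f1"] + fit.params["f2"])),
            sf=math.exp(b),
            sf_ci=(math.exp(b - Z975 * se), math.exp(b + Z975 * se)),
            z=b / se,
            p=float(fit.pvalues["f1f2"]),
            method="logistic_interaction",
        )
    if mode == "crude_8cell":
        return synergy_from_table(classify_joint_exposure(data, factor1, factor2))
    return synergy_logistic(data, factor1, factor2, covariates)
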