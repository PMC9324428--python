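"""Analytic power for a one-stage case-control genetic association test.

The design is parameterized by sample sizes, disease prevalence K, risk-allele
frequency p, genotype relative risk (GRR) and a penetrance model. Population
genotype frequencies follow Hardy-Weinberg equilibrium at p; genotype
penetrances are proportional to the model's risk ratios with the baseline
penetrance f0 solved so that the population prevalence equals K:

    additive        1 : g : 2g-1     (risk added per allele on the penetrance scale)
    multiplicative  1 : g : g^2      (per-allele relative risk)
    dominant        1 : g : g
    recessive       1 : 1 : g

Expected genotype frequencies are penetrance-conditioned: cases in proportion
to f_i * HWE_i / K, controls (sampled as unaffected) to (1-f_i) * HWE_i / (1-K).

Power is for the two-sided 1-df allele-frequency comparison: the z statistic
(p_case - p_control) / sqrt(p_case(1-p_case)/2N_case + p_control(1-p_control)/2N_control)
with the variance evaluated at the alternative; the non-centrality is z^2 and
power is the upper tail of the non-central chi-square(1) beyond the central
critical value at alpha. At GRR = 1 the non-centrality vanishes and power
equals alpha exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = ["PowerSpec", "PowerResult", "expected_genotype_freqs", "power_case_control"]

_PENETRANCE_RATIOS: Mapping[str, callable] = {
    "additive": lambda g: np.array([1.0, g, 2.0 * g - 1.0]),
    "multiplicative": lambda g: np.array([1.0, g, g * g]),
    "dominant": lambda g: np.array([1.0, g, g]),
    "recessive": lambda g: np.array([1.0, 1.0, g]),
}


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for an analytic power calculation."""

    n_cases: int
    n_controls: int
    prevalence: float
    raf: float
    grr: float
    model: str = "additive"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0 < self.raf < 1:
            raise ValueError("risk-allele frequency must be in (0, 1)")
        if self.grr <= 0:
            raise ValueError("genotype relative risk must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.model not in _PENETRANCE_RATIOS:
            raise ValueError(f"unknown model {self.model!r}; choose from {sorted(_PENETRANCE_RATIOS)}")
        if self.model == "additive" and 2.0 * self.grr - 1.0 <= 0:
            raise ValueError("additive model needs grr > 0.5 (homozygote risk ratio 2*grr-1 > 0)")


@dataclass(frozen=True)
class PowerResult:
    power: float
    ncp: float
    case_geno_freqs: tuple[float, float, float]
    control_geno_freqs: tuple[float, float, float]


def expected_genotype_freqs(spec: PowerSpec) -> tuple[np.ndarray, np.ndarray]:
    """Expected case and control genotype frequencies (0/1/2 risk alleles).

    Raises when the implied top penetrance exceeds 1 (parameters inconsistent
    with the stated prevalence).
    """
    p = spec.raf
    hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    ratios = _PENETRANCE_RATIOS[spec.model](spec.grr)
    f0 = spec.prevalence / float(hwe @ ratios)
    pen = f0 * ratios
    if np.any(pen > 1.0):
        raise ValueError("parameters inconsistent with prevalence: penetrance exceeds 1")
    case = pen * hwe / spec.prevalence
    control = (1.0 - pen) * hwe / (1.0 - spec.prevalence)
    return case, control


def power_case_control(spec: PowerSpec) -> PowerResult:
    """Two-sided analytic power of the 1-df allele-frequency test."""
    case_g, ctrl_g = expected_genotype_freqs(spec)
    p_case = case_g[1] / 2.0 + case_g[2]
    p_ctrl = ctrl_g[1] / 2.0 + ctrl_g[2]
    n1, n2 = 2.0 * spec.n_cases, 2.0 * spec.n_controls
    var = p_case * (1 - p_case) / n1 + p_ctrl * (1 - p_ctrl) / n2
    ncp = (p_case - p_ctrl) ** 2 / var
    crit = stats.chi2.ppf(1.0 - spec.alpha, df=1)
    power = float(stats.ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 else spec.alpha
    return PowerResult(
        power=power,
        ncp=float(ncp),
        case_geno_freqs=tuple(float(x) for x in case_g),
        control_geno_freqs=tuple(float(x) for x in ctrl_g),
    )
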