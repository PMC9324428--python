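"""Shared fixtures: published-count cohort reconstruction and synthetic cohorts."""

from __future__ import annotations

import itertools

import pytest

from snp_epistat import SimConfig, SubjectRecord, simulate_cohort

# Genotype (CC/CA/AA) counts cross-classified by HLA carrier status, as
# reported for the study this package models. Rebuilding subjects from these
# margins reproduces every crude (count-derivable) statistic of the study.
STUDY_COUNTS = {
    # (status, hla_carrier): (n_CC, n_CA, n_AA)
    ("case", True): (154, 116, 28),
    ("case", False): (131, 120, 30),
    ("control", True): (99, 110, 21),
    ("control", False): (439, 392, 84),
}

# course split of case genotypes: RR (239, 218, 54), SP (46, 18, 4)
SP_CASE_GENOTYPES = (46, 18, 4)


def build_study_cohort() -> list[SubjectRecord]:
    """Subjects reconstructed from the published genotype x HLA x course margins."""
    records: list[SubjectRecord] = []
    counter = itertools.count(1)
    sp_left = list(SP_CASE_GENOTYPES)
    for (status, hla), counts in STUDY_COUNTS.items():
        for geno, n in enumerate(counts):
            for _ in range(n):
                course = None
                if status == "case":
                    course = "SP" if sp_left[geno] > 0 else "RR"
                    if sp_left[geno] > 0:
                        sp_left[geno] -= 1
                records.append(
                    SubjectRecord(
                        subject_id=f"P{next(counter):05d}",
                        status=status,
                        genotype=geno,
                        hla_carrier=hla,
                        ms_course=course,
                    )
                )
    return records


@pytest.fixture(scope="session")
def study_cohort() -> list[SubjectRecord]:
    return build_study_cohort()


@pytest.fixture(scope="session")
def default_sim():
    """One cohort from the default generator (study-scale n, fixed seed)."""
    cfg = SimConfig(seed=11)
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth
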