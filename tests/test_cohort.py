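"""Cohort parsing, aggregation, and group-summary behaviour."""

from __future__ import annotations

import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snp_epistat import (
    GenotypeCounts,
    SubjectRecord,
    allele_counts,
    genotype_counts,
    parse_cohort,
    simulate_cohort,
    summarize_cohort,
    SimConfig,
)
from snp_epistat.cohort import CohortParseError


CSV_HEADER = "subject_id,status,genotype,hla_carrier,sex,age,ms_course,aoo,duration,edss,msss\n"


def test_parse_small_csv_preserves_missing_genotype():
    text = CSV_HEADER + (
        "s1,case,CC,1,female,40,RR,30,10,3.5,4.2\n"
        "s2,case,CA,0,male,45,SP,25,20,6,7.1\n"
        "s3,control,AA,0,female,50,,,,,\n"
        "s4,control,,1,male,60,,,,,\n"
    )
    records, report = parse_cohort(io.StringIO(text))
    assert len(records) == 4
    assert report.n_rejected == 0
    assert [r.genotype for r in records] == [0, 1, 2, None]
    assert report.missing_per_column.get("genotype") == 1
    assert records[0].aoo == 30 and records[2].aoo is None  # control phenotype blanked


def test_parse_rejects_unknown_genotype_naming_row():
    text = CSV_HEADER + "s1,case,CC,1,female,40,RR,30,10,3,4\ns2,control,CT,0,male,50,,,,,\n"
    with pytest.raises(CohortParseError, match="row 3.*CT"):
        parse_cohort(io.StringIO(text))


def test_parse_duplicate_id_is_hard_error():
    text = CSV_HEADER + "s1,case,CC,,,,,,,,\ns1,control,CA,,,,,,,,\n"
    with pytest.raises(CohortParseError, match="duplicate"):
        parse_cohort(io.StringIO(text))


def test_parse_unparseable_status_rejected_not_fatal():
    text = CSV_HEADER + "s1,case,CC,,,,,,,,\ns2,banana,CA,,,,,,,,\ns3,control,AA,,,,,,,,\n"
    records, report = parse_cohort(io.StringIO(text))
    assert len(records) == 2
    assert report.n_rejected == 1
    assert report.rejected_rows[0][0] == 3


def test_simulated_cohort_roundtrips_through_csv(default_sim, tmp_path):
    _, cohort, _ = default_sim
    frame = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in cohort],
            "status": [r.status for r in cohort],
            "genotype": [{0: "CC", 1: "CA", 2: "AA"}[r.genotype] for r in cohort],
            "hla_carrier": [int(r.hla_carrier) for r in cohort],
            "hla_copies": [r.hla_copies for r in cohort],
            "sex": [r.sex for r in cohort],
            "age": [r.age for r in cohort],
            "ms_course": [r.ms_course or "" for r in cohort],
            "aoo": [r.aoo if r.aoo is not None else "" for r in cohort],
            "duration": [r.duration if r.duration is not None else "" for r in cohort],
            "edss": [r.edss if r.edss is not None else "" for r in cohort],
            "msss": [r.msss if r.msss is not None else "" for r in cohort],
        }
    )
    path = tmp_path / "cohort.csv"
    frame.to_csv(path, index=False)
    records, report = parse_cohort(path)
    assert report.n_rejected == 0
    assert len(records) == 1724
    assert sum(r.is_case for r in records) == 579
    assert sum(not r.is_case for r in records) == 1145
    assert records[:50] == cohort[:50]


def test_genotype_counts_study_groups(study_cohort):
    ms = genotype_counts(study_cohort, where=lambda r: r.is_case)
    ctrl = genotype_counts(study_cohort, where=lambda r: not r.is_case)
    sp = genotype_counts(study_cohort, where=lambda r: r.ms_course == "SP")
    assert (ms.n_cc, ms.n_ca, ms.n_aa) == (285, 236, 58)
    assert (ctrl.n_cc, ctrl.n_ca, ctrl.n_aa) == (538, 502, 105)
    assert (sp.n_cc, sp.n_ca, sp.n_aa) == (46, 18, 4)


def test_genotype_counts_empty_selection_errors(study_cohort):
    with pytest.raises(ValueError):
        genotype_counts(study_cohort, where=lambda r: False)


def test_complementary_filters_partition_totals(default_sim):
    _, cohort, _ = default_sim
    total = genotype_counts(cohort)
    cases = genotype_counts(cohort, where=lambda r: r.is_case)
    ctrls = genotype_counts(cohort, where=lambda r: not r.is_case)
    assert (cases.n_cc + ctrls.n_cc, cases.n_ca + ctrls.n_ca, cases.n_aa + ctrls.n_aa) == (
        total.n_cc,
        total.n_ca,
        total.n_aa,
    )


@pytest.mark.parametrize(
    "counts, expected, freq_a",
    [
        ((285, 236, 58), (806, 352), 30.40),
        ((538, 502, 105), (1578, 712), 31.09),
        ((0, 0, 5), (0, 10), 100.0),
    ],
)
def test_allele_counts_and_frequencies(counts, expected, freq_a):
    g = GenotypeCounts(*counts)
    n_c, n_a = allele_counts(g)
    assert (n_c, n_a) == expected
    assert round(100 * n_a / (n_a + n_c), 2) == freq_a


@given(
    st.tuples(
        st.integers(min_value=0, max_value=10_000),
        st.integers(min_value=0, max_value=10_000),
        st.integers(min_value=0, max_value=10_000),
    ).filter(lambda t: sum(t) > 0)
)
@settings(max_examples=200, derandomize=True)
def test_allele_counts_conserve_chromosomes(counts):
    g = GenotypeCounts(*counts)
    n_c, n_a = allele_counts(g)
    assert n_c + n_a == 2 * g.n

# ---------------------------------------------------------------------------
# summaries


def _carrier_records(n_pos_case, n_case, n_pos_ctrl, n_ctrl):
    recs = []
    for i in range(n_case):
        recs.append(
            SubjectRecord(f"c{i}", "case", genotype=0, hla_carrier=i < n_pos_case, age=40.0,
                          sex="female")
        )
    for i in range(n_ctrl):
        recs.append(
            SubjectRecord(f"k{i}", "control", genotype=0, hla_carrier=i < n_pos_ctrl, age=50.0,
                          sex="female")
        )
    return recs


def test_summary_reproduces_carrier_percentages():
    cohort = _carrier_records(298, 579, 230, 1145)
    summary = summarize_cohort(cohort)
    carrier = next(v for v in summary.variables if v.variable == "hla_carrier")
    _, pct_cases = carrier.group_stats["cases"]["True"]
    _, pct_ctrl = carrier.group_stats["controls"]["True"]
    assert round(pct_cases, 2) == 51.47
    assert round(pct_ctrl, 2) == 20.09
    assert carrier.test == "pearson_chi2"
    assert carrier.p < 1e-4


def test_summary_identical_groups_give_p_one():
    cohort = _carrier_records(100, 300, 100, 300)
    summary = summarize_cohort(cohort)
    carrier = next(v for v in summary.variables if v.variable == "hla_carrier")
    assert carrier.p == pytest.approx(1.0)


def test_summary_welch_detects_mean_age_gap():
    rng = np.random.default_rng(3)
    recs = [
        SubjectRecord(f"a{i}", "case", genotype=0, age=float(40 + 15 * rng.standard_normal()))
        for i in range(500)
    ] + [
        SubjectRecord(f"b{i}", "control", genotype=0, age=float(50 + 15 * rng.standard_normal()))
        for i in range(500)
    ]
    summary = summarize_cohort(recs)
    age = next(v for v in summary.variables if v.variable == "age")
    assert age.test == "welch_t"
    assert age.p < 1e-3


def test_summary_zero_variance_falls_back_to_mann_whitney():
    recs = [SubjectRecord(f"a{i}", "case", genotype=0, age=40.0) for i in range(10)] + [
        SubjectRecord(f"b{i}", "control", genotype=0, age=float(45 + i)) for i in range(10)
    ]
    with pytest.warns(UserWarning, match="zero variance"):
        summary = summarize_cohort(recs)
    age = next(v for v in summary.variables if v.variable == "age")
    assert age.test == "mann_whitney"


def test_summary_controls_only_is_descriptive():
    recs = [SubjectRecord(f"b{i}", "control", genotype=0, age=float(45 + i)) for i in range(10)]
    with pytest.warns(UserWarning, match="fewer than 2"):
        summary = summarize_cohort(recs)
    age = next(v for v in summary.variables if v.variable == "age")
    assert age.p is None
    mean, sd, n = age.group_stats["controls"]
    assert n == 10 and math.isclose(mean, 49.5)


def test_subject_record_invariant_checks():
    with pytest.raises(ValueError):
        SubjectRecord("x", "case", genotype=3)
    with pytest.raises(ValueError):
        SubjectRecord("x", "case", hla_carrier=False, hla_copies=2)
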