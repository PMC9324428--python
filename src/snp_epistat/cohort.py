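"""Cohort data model, CSV I/O, and group summaries for a candidate-SNP case-control study.

The study design this package targets is a single biallelic SNP (alleles C and A,
A minor) genotyped in unrelated cases and controls, with an optional second binary
genetic factor — carriage of a tagging allele for an HLA risk haplotype — plus
demographic covariates (age, sex) and, for cases, clinical phenotypes: disease
course (relapsing-remitting vs secondary progressive), age of onset (AOO), disease
duration, EDSS disability score, and the MSSS severity score.

Genotypes are coded internally as the number of copies of the minor A allele
(0 = CC, 1 = CA, 2 = AA). The minor allele is fixed by the schema, never
re-estimated per file, so effect directions cannot flip between datasets.
Missing cells are preserved as ``None`` and handled per analysis by
complete-case deletion.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectRecord",
    "GenotypeCounts",
    "Counts2x2",
    "LoadReport",
    "CohortSummary",
    "VariableSummary",
    "parse_cohort",
    "cohort_to_frame",
    "genotype_counts",
    "allele_counts",
    "summarize_cohort",
    "DEFAULT_SCHEMA",
]

#: count of minor (A) alleles per genotype string
GENOTYPE_CODES = {"CC": 0, "CA": 1, "AC": 1, "AA": 2}
CODE_LABELS = {0: "CC", 1: "CA", 2: "AA"}

#: rs3135388-style tag genotype -> HLA carrier flag (T allele tags the haplotype)
TAG_GENOTYPE_CARRIER = {"CC": (False, 0), "CT": (True, 1), "TC": (True, 1), "TT": (True, 2)}

_CASE_TOKENS = {"case", "cases", "ms", "patient", "1"}
_CONTROL_TOKENS = {"control", "controls", "ctrl", "healthy", "0"}

DEFAULT_SCHEMA: Mapping[str, str] = {
    "subject_id": "subject_id",
    "status": "status",
    "genotype": "genotype",
    "hla_carrier": "hla_carrier",
    "hla_copies": "hla_copies",
    "hla_tag_genotype": "hla_tag_genotype",
    "sex": "sex",
    "age": "age",
    "ms_course": "ms_course",
    "aoo": "aoo",
    "duration": "duration",
    "edss": "edss",
    "msss": "msss",
}


class CohortParseError(ValueError):
    """Hard error while reading a cohort table (bad genotype symbol, duplicate id)."""


@dataclass(frozen=True)
class SubjectRecord:
    """One study participant.

    ``genotype`` is the minor-allele (A) dosage 0/1/2, or ``None`` when missing.
    ``hla_carrier`` is true iff the subject carries at least one copy of the
    tagging allele. Clinical fields are ``None`` for controls.
    """

    subject_id: str
    status: str  # "case" | "control"
    genotype: Optional[int] = None
    hla_carrier: Optional[bool] = None
    hla_copies: Optional[int] = None
    sex: Optional[str] = None  # "female" | "male"
    age: Optional[float] = None
    ms_course: Optional[str] = None  # "RR" | "SP" (cases only)
    aoo: Optional[float] = None
    duration: Optional[float] = None
    edss: Optional[float] = None
    msss: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be 'case' or 'control', got {self.status!r}")
        if self.genotype is not None and self.genotype not in (0, 1, 2):
            raise ValueError(f"genotype dosage must be 0/1/2, got {self.genotype!r}")
        if self.hla_copies is not None and self.hla_carrier is not None:
            if self.hla_carrier != (self.hla_copies >= 1):
                raise ValueError(
                    f"subject {self.subject_id}: hla_carrier inconsistent with hla_copies"
                )

    @property
    def is_case(self) -> bool:
        return self.status == "case"

    @property
    def a_carrier(self) -> Optional[bool]:
        """Carries at least one copy of the minor A allele (dominant coding)."""
        return None if self.genotype is None else self.genotype >= 1


@dataclass(frozen=True)
class GenotypeCounts:
    """Aggregated genotype counts (CC/CA/AA) for one group of subjects."""

    n_cc: int
    n_ca: int
    n_aa: int
    group_label: str = ""

    def __post_init__(self) -> None:
        if min(self.n_cc, self.n_ca, self.n_aa) < 0:
            raise ValueError("genotype counts must be nonnegative")
        if self.n == 0:
            raise ValueError("genotype counts must total at least 1")

    @property
    def n(self) -> int:
        return self.n_cc + self.n_ca + self.n_aa

    def as_array(self) -> np.ndarray:
        return np.array([self.n_cc, self.n_ca, self.n_aa], dtype=float)

    def frequencies(self) -> np.ndarray:
        return self.as_array() / self.n


@dataclass(frozen=True)
class Counts2x2:
    """2x2 exposure table: a=exposed cases, b=unexposed cases, c=exposed controls, d=unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 cells must be nonnegative")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass
class LoadReport:
    """Outcome of parsing one cohort file: rows kept, rows rejected, missingness."""

    n_parsed: int
    n_rejected: int
    rejected_rows: list = field(default_factory=list)  # (row_number, reason)
    missing_per_column: dict = field(default_factory=dict)

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        payload = json.dumps(
            {
                "n_parsed": self.n_parsed,
                "n_rejected": self.n_rejected,
                "rejected_rows": [
                    {"row": int(r), "reason": reason} for r, reason in self.rejected_rows
                ],
                "missing_per_column": self.missing_per_column,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _clean(value: object) -> Optional[str]:
    if value is None:
        return None
    text = str(value).strip()
    if text == "" or text.lower() in ("na", "nan", "none"):
        return None
    return text


def _parse_float(value: object, column: str, row: int) -> Optional[float]:
    text = _clean(value)
    if text is None:
        return None
    try:
        return float(text)
    except ValueError:
        raise CohortParseError(f"row {row}: cannot parse {column}={text!r} as a number")


def parse_cohort(
    source: Union[str, Path, pd.DataFrame],
    schema: Optional[Mapping[str, str]] = None,
) -> tuple[list[SubjectRecord], LoadReport]:
    """Read a subject-level cohort table into :class:`SubjectRecord` objects.

    Parameters
    ----------
    source
        Path to a comma-separated UTF-8 file with a header row, or an
        already-loaded DataFrame. Empty cells are missing values.
    schema
        Optional map from canonical field names (see ``DEFAULT_SCHEMA``) to
        the column names actually present in the file.

    Returns
    -------
    (records, report)
        Parsed records plus a :class:`LoadReport`. Rows whose status cannot
        be interpreted are rejected (counted, not fatal); an unknown genotype
        symbol or a duplicate subject id is a hard :class:`CohortParseError`.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)

    if isinstance(source, pd.DataFrame):
        frame = source.copy()
    else:
        frame = pd.read_csv(source, dtype=str, keep_default_na=False)

    def col(name: str) -> Optional[str]:
        c = colmap[name]
        return c if c in frame.columns else None

    if col("status") is None or col("genotype") is None:
        raise CohortParseError(
            "cohort table must contain status and genotype columns "
            f"(looked for {colmap['status']!r}, {colmap['genotype']!r})"
        )

    records: list[SubjectRecord] = []
    rejected: list[tuple[int, str]] = []
    missing: dict[str, int] = {k: 0 for k in colmap}
    seen_ids: set[str] = set()

    for idx, row in frame.iterrows():
        rowno = int(idx) + 2  # 1-based, after header

        status_raw = _clean(row[col("status")])
        if status_raw is None or status_raw.lower() not in (_CASE_TOKENS | _CONTROL_TOKENS):
            rejected.append((rowno, f"unparseable status {status_raw!r}"))
            continue
        status = "case" if status_raw.lower() in _CASE_TOKENS else "control"

        geno_raw = _clean(row[col("genotype")])
        if geno_raw is None:
            genotype = None
            missing["genotype"] += 1
        else:
            key = geno_raw.upper()
            if key not in GENOTYPE_CODES:
                raise CohortParseError(
                    f"row {rowno}: unknown genotype symbol {geno_raw!r} (expected CC/CA/AA or blank)"
                )
            genotype = GENOTYPE_CODES[key]

        sid_col = col("subject_id")
        sid = _clean(row[sid_col]) if sid_col else None
        if sid is None:
            sid = f"row{rowno}"
        if sid in seen_ids:
            raise CohortParseError(f"row {rowno}: duplicate subject_id {sid!r}")
        seen_ids.add(sid)

        hla_carrier: Optional[bool] = None
        hla_copies: Optional[int] = None
        tag_col = col("hla_tag_genotype")
        tag_raw = _clean(row[tag_col]) if tag_col else None
        if tag_raw is not None:
            key = tag_raw.upper()
            if key not in TAG_GENOTYPE_CARRIER:
                raise CohortParseError(
                    f"row {rowno}: unknown tag genotype {tag_raw!r} (expected CC/CT/TT)"
                )
            hla_carrier, hla_copies = TAG_GENOTYPE_CARRIER[key]
        carrier_col = col("hla_carrier")
        if carrier_col is not None:
            raw = _clean(row[carrier_col])
            if raw is None:
                if hla_carrier is None:
                    missing["hla_carrier"] += 1
            else:
                flag = raw.lower()
                if flag in ("1", "true", "yes", "pos", "positive", "+"):
                    hla_carrier = True
                elif flag in ("0", "false", "no", "neg", "negative", "-"):
                    hla_carrier = False
                else:
                    raise CohortParseError(f"row {rowno}: unparseable hla_carrier {raw!r}")
        copies_col = col("hla_copies")
        if copies_col is not None:
            raw = _clean(row[copies_col])
            if raw is not None:
                hla_copies = int(float(raw))
                if hla_copies not in (0, 1, 2):
                    raise CohortParseError(f"row {rowno}: hla_copies must be 0/1/2, got {raw!r}")
                if hla_carrier is None:
                    hla_carrier = hla_copies >= 1

        sex_col = col("sex")
        sex_raw = _clean(row[sex_col]) if sex_col else None
        sex: Optional[str] = None
        if sex_raw is not None:
            token = sex_raw.lower()
            if token in ("f", "female", "2"):
                sex = "female"
            elif token in ("m", "male", "1"):
                sex = "male"
            else:
                raise CohortParseError(f"row {rowno}: unparseable sex {sex_raw!r}")
        elif sex_col:
            missing["sex"] += 1

        course: Optional[str] = None
        course_col = col("ms_course")
        course_raw = _clean(row[course_col]) if course_col else None
        if course_raw is not None and status == "case":
            token = course_raw.upper()
            if token in ("RR", "RRMS", "RR-MS"):
                course = "RR"
            elif token in ("SP", "SPMS", "SP-MS"):
                course = "SP"
            else:
                raise CohortParseError(f"row {rowno}: unparseable ms_course {course_raw!r}")

        def num(name: str) -> Optional[float]:
            c = col(name)
            if c is None:
                return None
            v = _parse_float(row[c], name, rowno)
            if v is None:
                missing[name] += 1
            return v

        age = num("age")
        aoo = num("aoo") if status == "case" else None
        duration = num("duration") if status == "case" else None
        edss = num("edss") if status == "case" else None
        msss = num("msss") if status == "case" else None

        records.append(
            SubjectRecord(
                subject_id=sid,
                status=status,
                genotype=genotype,
                hla_carrier=hla_carrier,
                hla_copies=hla_copies,
                sex=sex,
                age=age,
                ms_course=course,
                aoo=aoo,
                duration=duration,
                edss=edss,
                msss=msss,
            )
        )

    report = LoadReport(
        n_parsed=len(records),
        n_rejected=len(rejected),
        rejected_rows=rejected,
        missing_per_column={k: v for k, v in missing.items() if v},
    )
    return records, report


def cohort_to_frame(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (missing -> NaN/None) for model fitting."""
    frame = pd.DataFrame([asdict(r) for r in cohort])
    frame["is_case"] = (frame["status"] == "case").astype(int)
    frame["is_male"] = frame["sex"].map({"male": 1.0, "female": 0.0})
    frame["a_carrier"] = frame["genotype"].map(lambda g: None if g is None else float(g >= 1))
    frame["hla"] = frame["hla_carrier"].map(lambda h: None if h is None else float(h))
    for c in ("genotype", "age", "aoo", "duration", "edss", "msss", "a_carrier", "hla"):
        frame[c] = pd.to_numeric(frame[c], errors="coerce")
    return frame


def genotype_counts(
    cohort: Iterable[SubjectRecord],
    where: Optional[Callable[[SubjectRecord], bool]] = None,
    group_label: str = "",
) -> GenotypeCounts:
    """Tally CC/CA/AA over the subjects selected by ``where`` (complete-case:
    subjects with missing genotype are excluded)."""
    tally = [0, 0, 0]
    for rec in cohort:
        if rec.genotype is None:
            continue
        if where is not None and not where(rec):
            continue
        tally[rec.genotype] += 1
    if sum(tally) == 0:
        raise ValueError("selection contains no subjects with a non-missing genotype")
    return GenotypeCounts(n_cc=tally[0], n_ca=tally[1], n_aa=tally[2], group_label=group_label)


def allele_counts(g: GenotypeCounts) -> tuple[int, int]:
    """Chromosome-level allele counts (n_C, n_A); conserves 2n chromosomes."""
    n_c = 2 * g.n_cc + g.n_ca
    n_a = g.n_ca + 2 * g.n_aa
    return n_c, n_a


# ---------------------------------------------------------------------------
# Group summaries


@dataclass
class VariableSummary:
    variable: str
    kind: str  # "continuous" | "categorical"
    group_stats: dict  # label -> (mean, sd, n) or {level: (count, pct)}
    p: Optional[float]
    test: Optional[str]


@dataclass
class CohortSummary:
    group_labels: tuple[str, str]
    variables: list[VariableSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.variables:
            row: dict = {"variable": v.variable, "kind": v.kind, "test": v.test, "p": v.p}
            for label, stat in v.group_stats.items():
                if v.kind == "continuous":
                    mean, sd, n = stat
                    row[label] = f"{mean:.2f} ± {sd:.2f}" if n else ""
                else:
                    row[label] = "; ".join(
                        f"{lvl}: {cnt} ({pct:.2f}%)" for lvl, (cnt, pct) in stat.items()
                    )
            rows.append(row)
        return pd.DataFrame(rows)


_CONTINUOUS = ("age", "aoo", "duration", "edss", "msss")
_CATEGORICAL = ("sex", "ms_course", "hla_carrier")


def _cont_stats(values: np.ndarray) -> tuple[float, float, int]:
    if values.size == 0:
        return math.nan, math.nan, 0
    return float(np.mean(values)), float(np.std(values, ddof=1)) if values.size > 1 else 0.0, int(values.size)


def summarize_cohort(
    cohort: Sequence[SubjectRecord],
    grouping: str = "case_control",
    mann_whitney: Iterable[str] = (),
) -> CohortSummary:
    """Table-1-style two-group summary with between-group tests.

    Continuous variables use Welch's t by default (per-variable switch to
    Mann-Whitney via ``mann_whitney``); categorical variables use Pearson's
    chi-square without continuity correction. A zero-variance group silently
    falls back to Mann-Whitney with a warning.

    ``grouping`` is ``"case_control"`` or ``"ms_by_sex"`` (female vs male cases).
    """
    if grouping == "case_control":
        labels = ("controls", "cases")
        groups = (
            [r for r in cohort if r.status == "control"],
            [r for r in cohort if r.status == "case"],
        )
    elif grouping == "ms_by_sex":
        labels = ("female cases", "male cases")
        groups = (
            [r for r in cohort if r.status == "case" and r.sex == "female"],
            [r for r in cohort if r.status == "case" and r.sex == "male"],
        )
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if sum(len(g) for g in groups) < 2:
        raise ValueError("summary needs at least 2 subjects")
    descriptive_only = min(len(g) for g in groups) < 2
    if descriptive_only:
        warnings.warn(
            "a summary group has fewer than 2 subjects; reporting descriptives without tests",
            stacklevel=2,
        )

    mann_whitney = set(mann_whitney)
    variables: list[VariableSummary] = []

    for var in _CONTINUOUS:
        samples = [
            np.array([getattr(r, var) for r in grp if getattr(r, var) is not None], dtype=float)
            for grp in groups
        ]
        stats_by_group = {lbl: _cont_stats(s) for lbl, s in zip(labels, samples)}
        if all(s.size == 0 for s in samples):
            continue
        p: Optional[float] = None
        test: Optional[str] = None
        if not descriptive_only and all(s.size >= 2 for s in samples):
            use_mw = var in mann_whitney
            if not use_mw and any(np.var(s) == 0 for s in samples):
                warnings.warn(
                    f"{var}: zero variance in a group; falling back to Mann-Whitney",
                    stacklevel=2,
                )
                use_mw = True
            if use_mw:
                test = "mann_whitney"
                p = float(stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided").pvalue)
            else:
                test = "welch_t"
                p = float(stats.ttest_ind(samples[0], samples[1], equal_var=False).pvalue)
        variables.append(VariableSummary(var, "continuous", stats_by_group, p, test))

    for var in _CATEGORICAL:
        per_group = []
        for grp in groups:
            vals = [getattr(r, var) for r in grp if getattr(r, var) is not None]
            per_group.append(pd.Series(vals, dtype=object).value_counts().sort_index())
        levels = sorted(set(per_group[0].index) | set(per_group[1].index), key=str)
        if not levels:
            continue
        table = np.array(
            [[int(cnt.get(lvl, 0)) for lvl in levels] for cnt in per_group], dtype=float
        )
        stats_by_group = {}
        for lbl, rowvals in zip(labels, table):
            tot = rowvals.sum()
            stats_by_group[lbl] = {
                str(lvl): (int(c), 100.0 * c / tot if tot else math.nan)
                for lvl, c in zip(levels, rowvals)
            }
        p = None
        test = None
        keep = table.sum(axis=0) > 0
        if not descriptive_only and keep.sum() >= 2 and (table.sum(axis=1) > 0).all():
            test = "pearson_chi2"
            chi2, p_val, _, _ = stats.chi2_contingency(table[:, keep], correction=False)
            p = float(p_val)
        variables.append(VariableSummary(var, "categorical", stats_by_group, p, test))

    return CohortSummary(group_labels=labels, variables=variables)
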