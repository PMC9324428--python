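"""End-to-end analysis pipeline: cohort file in, study-style tables out.

Runs the requested analyses (group summary, Hardy-Weinberg, whole-cohort
model scan, HLA-stratified scan, course comparison, synergy-factor
interaction, phenotype regressions) and renders each as a TSV table plus a
single machine-readable ``results.json`` holding the same numbers at full
precision. Rendered tables round odds ratios and percentages to 2 decimals
and p-values to 2-4 significant figures; the JSON is the source of truth.

Analyses whose required columns are missing are skipped with a logged
reason; the pipeline only fails if every requested analysis fails.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .association import ORResult, association_scan, hwe_chi_square, stratified_scan
from .cohort import SubjectRecord, allele_counts, genotype_counts, parse_cohort, summarize_cohort
from .epistasis import classify_joint_exposure, synergy_analysis
from .phenotype import phenotype_scan

__all__ = ["AnalysisConfig", "run_pipeline"]

logger = logging.getLogger("snp_epistat")

ALL_ANALYSES = ("summary", "hwe", "scan", "stratified", "rr_sp", "epistasis", "phenotype")


@dataclass
class AnalysisConfig:
    input: Union[str, Path, Sequence[SubjectRecord]]
    out_dir: Union[str, Path] = "snp_epistat_report"
    analyses: Sequence[str] = ALL_ANALYSES
    scan_covariates: Sequence[str] = ("age", "is_male", "hla")
    stratified_covariates: Sequence[str] = ("age", "is_male")
    epistasis_covariates: Sequence[str] = ("age", "is_male")
    seed: int = 0
    verbosity: int = logging.INFO

    def fingerprint(self) -> str:
        payload = {
            k: str(v) for k, v in dataclasses.asdict(self).items() if k not in ("input",)
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _fmt_p(p: Optional[float]) -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return ""
    if p < 1e-4:
        return "<0.0001"
    return f"{p:.2g}" if p >= 0.01 else f"{p:.1g}"


def _or_rows(results: Sequence[ORResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "model": r.label,
                "p": _fmt_p(r.p),
                "OR": f"{r.or_hat:.2f}" if r.estimable else "NE",
                "CI95": f"{r.ci_low:.2f}-{r.ci_high:.2f}" if r.estimable else "",
                "lrt_p": _fmt_p(r.lrt_p),
                "method": r.method,
                "adjusted_for": ",".join(r.adjusted_for),
            }
        )
    return pd.DataFrame(rows)


def _or_json(results: Sequence[ORResult]) -> list[dict]:
    return [dataclasses.asdict(r) for r in results]


def run_pipeline(cfg: AnalysisConfig) -> dict:
    """Execute the configured analyses; returns {"results": ..., "paths": ...}."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(cfg.verbosity)

    try:
        if isinstance(cfg.input, (str, Path)):
            cohort, load_report = parse_cohort(cfg.input)
            (out / "load_report.json").write_text(load_report.to_json())
        else:
            cohort = list(cfg.input)
        logger.info(
            "version=%s config=%s n_subjects=%d", __version__, cfg.fingerprint(), len(cohort)
        )

        results: dict = {"version": __version__, "config_hash": cfg.fingerprint(), "analyses": {}}
        paths: dict = {}
        failures: list[str] = []
        n_cases = sum(1 for r in cohort if r.is_case)
        n_controls = len(cohort) - n_cases

        def attempt(name: str, fn) -> None:
            if name not in cfg.analyses:
                return
            try:
                fn()
                logger.info("analysis %s: ok", name)
            except (ValueError, RuntimeError, KeyError) as exc:
                failures.append(name)
                logger.warning("analysis %s skipped: %s", name, exc)

        def do_summary() -> None:
            summary = summarize_cohort(cohort)
            frame = summary.to_frame()
            path = out / "table_summary.tsv"
            frame.to_csv(path, sep="\t", index=False)
            paths["summary"] = path
            results["analyses"]["summary"] = {
                "n_cases": n_cases,
                "n_controls": n_controls,
                "variables": [dataclasses.asdict(v) for v in summary.variables],
            }

        def do_hwe() -> None:
            payload = {}
            rows = []
            for label, pred in (("cases", lambda r: r.is_case), ("controls", lambda r: not r.is_case)):
                g = genotype_counts(cohort, where=pred, group_label=label)
                res = hwe_chi_square(g)
                n_c, n_a = allele_counts(g)
                payload[label] = {
                    "counts": [g.n_cc, g.n_ca, g.n_aa],
                    "allele_counts": [n_c, n_a],
                    "chi2": res.chi2,
                    "p": res.p,
                    "expected": list(res.expected_counts),
                }
                rows.append(
                    {
                        "group": label,
                        "CC/CA/AA": f"{g.n_cc}/{g.n_ca}/{g.n_aa}",
                        "freq_A": f"{100 * n_a / (n_a + n_c):.2f}%",
                        "chi2": f"{res.chi2:.2f}",
                        "p": _fmt_p(res.p),
                    }
                )
            pd.DataFrame(rows).to_csv(out / "table_hwe.tsv", sep="\t", index=False)
            paths["hwe"] = out / "table_hwe.tsv"
            results["analyses"]["hwe"] = payload

        def do_scan() -> None:
            scan = association_scan(cohort, covariates=cfg.scan_covariates)
            _or_rows(scan).to_csv(out / "table_scan.tsv", sep="\t", index=False)
            paths["scan"] = out / "table_scan.tsv"
            results["analyses"]["scan"] = _or_json(scan)

        def do_stratified() -> None:
            strat = stratified_scan(cohort, covariates=cfg.stratified_covariates)
            frames = []
            for label, res in strat.items():
                frame = _or_rows(res)
                frame.insert(0, "stratum", label)
                frames.append(frame)
            pd.concat(frames).to_csv(out / "table_stratified.tsv", sep="\t", index=False)
            paths["stratified"] = out / "table_stratified.tsv"
            results["analyses"]["stratified"] = {k: _or_json(v) for k, v in strat.items()}

        def do_rr_sp() -> None:
            comparisons = {
                "RR_vs_controls": (lambda r: r.ms_course == "RR", lambda r: not r.is_case),
                "SP_vs_controls": (lambda r: r.ms_course == "SP", lambda r: not r.is_case),
                "SP_vs_RR": (lambda r: r.ms_course == "SP", lambda r: r.ms_course == "RR"),
            }
            if not any(r.ms_course == "SP" for r in cohort):
                raise ValueError("no secondary-progressive cases in cohort")
            payload = {}
            frames = []
            for label, comp in comparisons.items():
                res = association_scan(cohort, covariates=cfg.scan_covariates, comparison=comp)
                payload[label] = _or_json(res)
                frame = _or_rows(res)
                frame.insert(0, "comparison", label)
                frames.append(frame)
            pd.concat(frames).to_csv(out / "table_course.tsv", sep="\t", index=False)
            paths["rr_sp"] = out / "table_course.tsv"
            results["analyses"]["rr_sp"] = payload

        def do_epistasis() -> None:
            table = classify_joint_exposure(cohort)
            crude = synergy_analysis(table, mode="crude_8cell")
            try:
                adjusted = synergy_analysis(
                    cohort, mode="logistic_interaction", covariates=cfg.epistasis_covariates
                )
            except (ValueError, RuntimeError) as exc:
                logger.warning("adjusted synergy factor unavailable: %s", exc)
                adjusted = None
            rows = [
                {"cells": "cases (00,10,01,11)", "counts": f"{table.c00},{table.c10},{table.c01},{table.c11}"},
                {"cells": "controls (00,10,01,11)", "counts": f"{table.k00},{table.k10},{table.k01},{table.k11}"},
                {"cells": "SF crude", "counts": f"{crude.sf:.2f} (p={_fmt_p(crude.p)})"},
            ]
            if adjusted is not None:
                rows.append(
                    {"cells": "SF adjusted", "counts": f"{adjusted.sf:.2f} (p={_fmt_p(adjusted.p)})"}
                )
            pd.DataFrame(rows).to_csv(out / "table_epistasis.tsv", sep="\t", index=False)
            paths["epistasis"] = out / "table_epistasis.tsv"
            results["analyses"]["epistasis"] = {
                "cells": {
                    "cases": [table.c00, table.c10, table.c01, table.c11],
                    "controls": [table.k00, table.k10, table.k01, table.k11],
                },
                "crude": {"sf": crude.sf, "ci": list(crude.sf_ci), "z": crude.z, "p": crude.p},
                "adjusted": None
                if adjusted is None
                else {
                    "sf": adjusted.sf,
                    "ci": list(adjusted.sf_ci),
                    "z": adjusted.z,
                    "p": adjusted.p,
                    "covariates": list(cfg.epistasis_covariates),
                },
            }

        def do_phenotype() -> None:
            fits = phenotype_scan(cohort)
            if not fits:
                raise ValueError("no phenotype regression was estimable")
            rows = []
            payload = []
            for f in fits:
                means = {
                    lbl: f"{m:.2f} ± {s:.2f}" if not math.isnan(m) else ""
                    for lbl, (m, s, _) in f.genotype_stats.items()
                }
                rows.append(
                    {
                        "phenotype": f.phenotype,
                        "stratum": f.stratum,
                        **means,
                        "best_model": f.model,
                        "p": _fmt_p(f.p),
                    }
                )
                payload.append(
                    {
                        "phenotype": f.phenotype,
                        "stratum": f.stratum,
                        "best_model": f.model,
                        "slope": f.slope,
                        "se": f.se,
                        "p": f.p,
                        "adjusted_for": list(f.adjusted_for),
                        "genotype_stats": f.genotype_stats,
                        "n": f.n,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "table_phenotype.tsv", sep="\t", index=False)
            paths["phenotype"] = out / "table_phenotype.tsv"
            results["analyses"]["phenotype"] = payload

        attempt("summary", do_summary)
        attempt("hwe", do_hwe)
        attempt("scan", do_scan)
        attempt("stratified", do_stratified)
        attempt("rr_sp", do_rr_sp)
        attempt("epistasis", do_epistasis)
        attempt("phenotype", do_phenotype)

        requested = [a for a in cfg.analyses if a in ALL_ANALYSES]
        if requested and len(failures) == len(requested):
            raise RuntimeError(f"all requested analyses failed: {failures}")

        results["skipped"] = failures
        results_path = out / "results.json"
        results_path.write_text(json.dumps(results, indent=2, default=str))
        paths["results"] = results_path
        paths["log"] = log_path
        return {"results": results, "paths": paths}
    finally:
        logger.removeHandler(handler)
        handler.close()
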