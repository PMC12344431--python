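"""Reproducible end-to-end runs: config, manifest, structured outputs.

``run_pipeline`` reads a YAML config, executes annotate → windows → overlaps →
summarise → statistics for the requested analysis mode, and writes TSV result
tables plus a JSON run manifest (config snapshot, seed, SHA-256 input digests,
per-stage record counts, package version) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .catalog import load_catalog, packaged_catalog_path
from .cyp2c19 import attach_phenotypes, load_allele_table
from .episodes import build_cohort
from .stats import (AnalysisConfig, AnalysisResults, RegressionResult,
                    UnivariateResult, run_analysis)

logger = logging.getLogger(__name__)

_MODE_ALIASES = {"main": "main", "a": "a_exclude_topical",
                 "b": "b_contraindicated_only", "c": "c_drop_duration_covariate",
                 "d": "d_replace_with_n_prescriptions"}
_MODE_TO_FILTER = {"main": "default", "a_exclude_topical": "exclude_topical",
                   "b_contraindicated_only": "contraindicated_only",
                   "c_drop_duration_covariate": "default",
                   "d_replace_with_n_prescriptions": "default"}

_CONFIG_SCHEMA: dict[str, tuple[type, ...]] = {
    # field -> accepted types; None marks optional fields
    "events": (str,),
    "covariates": (str,),
    "catalog": (str, type(None)),
    "diplotypes": (str, type(None)),
    "mode": (str, type(None)),
    "alpha": (float, int, type(None)),
    "n_tests": (int, type(None)),
    "seed": (int, type(None)),
    "out_dir": (str,),
}
_REQUIRED = ("events", "covariates", "out_dir")


class ConfigError(ValueError):
    """Raised when a run config does not validate against the schema."""


def validate_config(raw: Mapping[str, Any]) -> dict[str, Any]:
    unknown = set(raw) - set(_CONFIG_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    missing = [k for k in _REQUIRED if not raw.get(k)]
    if missing:
        raise ConfigError(f"missing required config field(s): {missing}")
    for key, types in _CONFIG_SCHEMA.items():
        if key in raw and not isinstance(raw[key], types):
            raise ConfigError(f"config field {key!r} has wrong type "
                              f"{type(raw[key]).__name__}")
    mode = _MODE_ALIASES.get(raw.get("mode") or "main")
    if mode is None:
        raise ConfigError(f"unknown mode {raw.get('mode')!r}")
    return {**dict(raw), "mode": mode}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _univariate_frame(results: list[UnivariateResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variable": r.variable, "test": r.test, "statistic": r.statistic,
        "p_value": r.p_value, "significant": r.significant,
        "untestable": r.untestable,
        "n_missing_ddi": r.n_missing.get(True), "n_missing_non_ddi": r.n_missing.get(False),
    } for r in results])


def _regression_frame(results: Mapping[str, list[RegressionResult]] | list[RegressionResult],
                      label: str) -> pd.DataFrame:
    rows = []
    items = (results.items() if isinstance(results, Mapping)
             else [(label, results)])
    for model, terms in items:
        for t in terms:
            rows.append({"model": model, "term": t.term, "estimate": t.estimate,
                         "ci_low": t.ci_low, "ci_high": t.ci_high,
                         "p_value": t.p_value, "n_used": t.n_used, "flag": t.flag})
    return pd.DataFrame(rows)


def summary_text(results: AnalysisResults) -> str:
    """Plain-text summary mirroring the univariate-comparison and adjusted-OR
    table structure of the analysis."""
    lines = [f"analysis mode: {results.mode}",
             f"Bonferroni threshold: {results.alpha_bonf:.3e}",
             f"participants: {results.counts.get('participants', 'n/a')} "
             f"(DDI {results.counts.get('participants_ddi', 'n/a')}, "
             f"non-DDI {results.counts.get('participants_non_ddi', 'n/a')})",
             "", "univariate screen (DDI vs non-DDI):"]
    for r in results.univariate:
        mark = "untestable" if r.untestable else (
            "significant" if r.significant else "ns")
        lines.append(f"  {r.variable:<28s} {r.test:<12s} p={r.p_value:.3e}  {mark}"
                     if not r.untestable else f"  {r.variable:<28s} {r.test:<12s} {mark}")
    lines.append("")
    lines.append("adjusted odds ratios (one model per predictor):")
    for model, terms in results.logistic.items():
        for t in terms:
            if model in t.term:
                lines.append(f"  {model:<28s} OR={t.estimate:.2f} "
                             f"(95% CI {t.ci_low:.2f}-{t.ci_high:.2f}) "
                             f"p={t.p_value:.3e} n={t.n_used}")
    if results.duration:
        lines.append("")
        lines.append("longest co-prescription overlap vs CYP2C19 phenotype (NM reference):")
        for t in results.duration:
            if t.flag == "untestable":
                lines.append("  untestable (no contrast between phenotype groups)")
            else:
                lines.append(f"  {t.term}: {t.estimate:+.1f} days "
                             f"(95% CI {t.ci_low:.1f}..{t.ci_high:.1f}) "
                             f"p={t.p_value:.3f} n={t.n_used}")
    return "\n".join(lines) + "\n"


def run_pipeline(config_path: str | Path) -> Path:
    """Execute one configured analysis run; returns the output directory."""
    config_path = Path(config_path)
    raw = yaml.safe_load(config_path.read_text())
    if not isinstance(raw, Mapping):
        raise ConfigError("config must be a YAML mapping")
    cfg = validate_config(raw)

    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    log_file = out_dir / "run.log"
    handler = logging.FileHandler(log_file, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("rxddi")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    try:
        return _run(cfg, config_path, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: dict[str, Any], config_path: Path, out_dir: Path) -> Path:
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    catalog_path = Path(cfg.get("catalog") or packaged_catalog_path())
    inputs = {"events": Path(cfg["events"]), "covariates": Path(cfg["covariates"]),
              "catalog": catalog_path}
    if cfg.get("diplotypes"):
        inputs["diplotypes"] = Path(cfg["diplotypes"])
    for name, path in inputs.items():
        if not path.exists():
            raise ConfigError(f"missing input file for {name!r}: {path}")
    digests = {name: _sha256(path) for name, path in inputs.items()}

    events = pd.read_csv(inputs["events"], sep="\t", parse_dates=["date"])
    covariates = pd.read_csv(inputs["covariates"], sep="\t")
    catalog = load_catalog(inputs["catalog"])
    mode = cfg["mode"]
    timings["load"] = time.perf_counter() - t0
    logger.info("loaded %d events, %d participants", len(events), len(covariates))

    t1 = time.perf_counter()
    build = build_cohort(events, covariates, catalog,
                         mode=_MODE_TO_FILTER[mode])
    cohort = build.cohort
    if "diplotypes" in inputs:
        diplotypes = pd.read_csv(inputs["diplotypes"], sep="\t")
        cohort = attach_phenotypes(cohort, diplotypes, load_allele_table())
    timings["exposure"] = time.perf_counter() - t1
    logger.info("cohort: %s", build.counts)

    t2 = time.perf_counter()
    analysis_cfg = AnalysisConfig(alpha=float(cfg.get("alpha") or 0.05),
                                  n_tests=int(cfg.get("n_tests") or 34),
                                  mode=mode)
    results = run_analysis(cohort, analysis_cfg, counts=build.counts)
    timings["stats"] = time.perf_counter() - t2

    logistic_frame = _regression_frame(results.logistic, "logistic")
    build.windows.to_csv(out_dir / "windows.tsv", sep="\t", index=False)
    build.instances.to_csv(out_dir / "instances.tsv", sep="\t", index=False)
    cohort.to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
    _univariate_frame(results.univariate).to_csv(
        out_dir / "univariate.tsv", sep="\t", index=False)
    logistic_frame.to_csv(out_dir / "logistic.tsv", sep="\t", index=False)
    if results.duration is not None:
        _regression_frame(results.duration, "duration_vs_cyp2c19").to_csv(
            out_dir / "duration_model.tsv", sep="\t", index=False)
    (out_dir / "summary.txt").write_text(summary_text(results))

    complete_case = {m: int(terms[0].n_used) for m, terms in results.logistic.items()
                     if terms}
    manifest = {
        "version": __version__,
        "config": {k: (str(v) if isinstance(v, Path) else v) for k, v in cfg.items()},
        "config_file": str(config_path),
        "seed": cfg.get("seed"),
        "mode": mode,
        "input_digests": digests,
        "counts": {**build.counts, "complete_case_n": complete_case},
        "alpha_bonf": results.alpha_bonf,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")
    logger.info("run complete in %.1fs", time.perf_counter() - t0)
    return out_dir


def write_simulation(out_dir: str | Path, n: int, seed: int, **overrides) -> Path:
    """Generate a synthetic cohort and write the pipeline's input files."""
    from .synth import GeneratorConfig, generate_cohort

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(GeneratorConfig(n_participants=n, seed=seed,
                                             **overrides))
    events = cohort.events.copy()
    events["date"] = events["date"].dt.strftime("%Y-%m-%d")
    events.to_csv(out_dir / "events.tsv", sep="\t", index=False)
    cohort.covariates.to_csv(out_dir / "covariates.tsv", sep="\t", index=False)
    cohort.diplotypes.to_csv(out_dir / "diplotypes.tsv", sep="\t", index=False)
    (out_dir / "truth.json").write_text(json.dumps(cohort.truth, indent=2,
                                                   sort_keys=True) + "\n")
    return out_dir
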