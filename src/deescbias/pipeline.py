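"""End-to-end pipeline: inclusion -> classification -> propensity -> Cox ->
confounder sweep -> strength table, with machine-readable outputs.

Every stage logs one structured line (stage name, input/output row counts)
and every random step logs its seed.  The results JSON is schema-versioned
and deterministic: running the same configuration twice produces
byte-identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bias import ConfounderScenario, default_grid, run_sweep, strength_table
from .cohort import AnalysisCohort, apply_inclusion, read_cohort
from .errors import DeescbiasError, SeparationError
from .propensity import fit_propensity
from .ranking import (
    DE_ESCALATION,
    RankTable,
    classify_cohort,
    summarize_flows,
)
from .simulate import GeneratorConfig, generate, make_fixture
from .survival import build_intervals, fit_cox, make_analysis_set

log = logging.getLogger("deescbias")

RESULTS_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    source: str = "synthetic"  # synthetic | fixture | user
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    patients_path: str | None = None
    events_path: str | None = None
    rank_table_path: str | None = None
    synonyms_path: str | None = None
    horizon: int = 30
    scenario: ConfounderScenario = field(default_factory=ConfounderScenario)
    grid_step: float = 0.01
    outdir: str | None = None

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        scen = ConfounderScenario(**raw.pop("scenario", {}))
        cfg = PipelineConfig(generator=gen, scenario=scen, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.source not in ("synthetic", "fixture", "user"):
            raise DeescbiasError(f"unknown cohort source {self.source!r}")
        if self.source == "user":
            for p in (self.patients_path,):
                if p is None or not Path(p).exists():
                    raise DeescbiasError(f"cohort file not found: {p}")


def _load_cohort(config: PipelineConfig) -> tuple[AnalysisCohort, dict]:
    if config.source == "fixture":
        return make_fixture(), {}
    if config.source == "synthetic":
        log.info("stage=generate seed=%d n=%d", config.generator.seed, config.generator.n_patients)
        cohort, report = generate(config.generator)
        return cohort, {"generation_report": asdict(report)}
    cohort = read_cohort(config.patients_path, config.events_path)
    return cohort, {}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and optionally writes) results."""
    config.validate()
    results: dict = {"schema_version": RESULTS_SCHEMA_VERSION, "package_version": __version__}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        cohort, extra = _load_cohort(config)
        results.update(extra)
        log.info("stage=load source=%s n=%d", config.source, len(cohort))

        stage = "inclusion"
        cohort, tally = apply_inclusion(cohort)
        results["exclusions"] = tally
        results["n_included"] = len(cohort)
        log.info("stage=inclusion n_out=%d excluded=%s", len(cohort), tally)

        stage = "classify"
        table = (
            RankTable.from_csv(config.rank_table_path, config.synonyms_path)
            if config.rank_table_path
            else RankTable.default()
        )
        classified = classify_cohort(cohort, table)
        counts, edges = summarize_flows(classified)
        results["classification_counts"] = counts
        results["flows"] = edges.to_dict(orient="records")
        log.info("stage=classify counts=%s", counts)

        stage = "propensity"
        analysis = make_analysis_set(cohort.patients, classified)
        outcome = (analysis["label"] == DE_ESCALATION).astype(int)
        try:
            model = fit_propensity(analysis, outcome)
        except SeparationError:
            log.warning("stage=propensity separation detected; retrying with ridge penalty")
            model = fit_propensity(analysis, outcome, ridge=True)
        results["propensity"] = {
            "auc": model.auc,
            "auc_ci": list(model.auc_ci),
            "n": model.n,
            "n_deescalated": model.n_events,
        }
        log.info("stage=propensity n=%d auc=%.3f", model.n, model.auc)

        # the estimation stages can fail on legitimately degenerate inputs
        # (e.g. no deaths in one exposure state on a tiny cohort); such
        # failures are recorded as skipped, not fatal
        stage = "cox"
        cov = pd.DataFrame({"propensity": model.scores})
        intervals = build_intervals(analysis, horizon=config.horizon, covariates=cov)
        sweep = strength = None
        try:
            crude = fit_cox(intervals)
            adjusted = fit_cox(intervals, covariates=["propensity"])
            results["cox"] = {
                "crude": _fit_dict(crude),
                "adjusted": _fit_dict(adjusted),
                "horizon": config.horizon,
            }
            log.info(
                "stage=cox events=%d crude_hr=%.3f adjusted_hr=%.3f",
                crude.n_events, crude.hr, adjusted.hr,
            )
        except DeescbiasError as exc:
            results["cox"] = {"skipped": str(exc)}
            log.warning("stage=cox skipped: %s", exc)

        stage = "sweep"
        try:
            grid = default_grid(config.scenario.overall_prevalence, config.grid_step)
            sweep = run_sweep(
                analysis, model.scores, config.scenario, grid=grid, horizon=config.horizon
            )
            results["sweep"] = sweep.frame.to_dict(orient="records")
            thr = sweep.crossing_threshold
            results["sweep_crossing_threshold"] = thr
            log.info(
                "stage=sweep points=%d seed=%d crossing=%s", len(grid), config.scenario.seed, thr
            )
        except DeescbiasError as exc:
            results["sweep"] = {"skipped": str(exc)}
            log.warning("stage=sweep skipped: %s", exc)

        stage = "strength"
        try:
            strength = strength_table(
                analysis, scores=model.scores, scenario=config.scenario, horizon=config.horizon
            )
            results["strength"] = strength.to_dict(orient="records")
            log.info("stage=strength rows=%d", len(strength))
        except DeescbiasError as exc:
            results["strength"] = {"skipped": str(exc)}
            log.warning("stage=strength skipped: %s", exc)
    except Exception as exc:
        if outdir:
            _write_results(results, outdir)  # persist partial outputs
        raise DeescbiasError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if outdir:
        _write_results(results, outdir)
        edges.to_csv(outdir / "flows.csv", index=False)
        if sweep is not None:
            sweep.frame.to_csv(outdir / "sweep.csv", index=False)
        if strength is not None:
            strength.to_csv(outdir / "strength.csv", index=False)
        classified.to_csv(outdir / "classification.csv", index=False)
        (outdir / "summary.txt").write_text(_summary_text(results))
    return results


def _fit_dict(fit) -> dict:
    return {
        "hr": fit.hr,
        "ci_low": fit.ci_low,
        "ci_high": fit.ci_high,
        "log_hr": fit.log_hr,
        "se": fit.se,
        "n_events": fit.n_events,
        "n_intervals": fit.n_intervals,
    }


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def _write_results(results: dict, outdir: Path) -> None:
    payload = json.dumps(results, indent=2, sort_keys=True, default=_json_default)
    (outdir / "results.json").write_text(payload + "\n")


def _summary_text(results: dict) -> str:
    lines = [f"deescbias v{results.get('package_version')} analysis summary", ""]
    if "n_included" in results:
        lines.append(f"included patients: {results['n_included']} (excluded: {results.get('exclusions')})")
    cc = results.get("classification_counts")
    if cc:
        lines.append(
            "course classification: "
            + ", ".join(f"{k}={v}" for k, v in sorted(cc.items()))
        )
    prop = results.get("propensity")
    if prop:
        lo, hi = prop["auc_ci"]
        lines.append(f"propensity AUC: {prop['auc']:.3f} (95% CI {lo:.3f}-{hi:.3f})")
    cox = results.get("cox")
    if cox and "skipped" not in cox:
        for kind in ("crude", "adjusted"):
            f = cox[kind]
            lines.append(
                f"{kind} HR for de-escalation: {f['hr']:.2f} "
                f"(95% CI {f['ci_low']:.2f}-{f['ci_high']:.2f}), {f['n_events']} events"
            )
    thr = results.get("sweep_crossing_threshold")
    if thr is not None:
        lines.append(
            f"CI upper bound crosses 1 at de-escalated stability prevalence {thr:.2f}"
        )
    strength = results.get("strength")
    if isinstance(strength, list) and strength:
        top = strength[0]
        lines.append(
            f"strongest confounder: {top['confounder']} ({top['pct_change']:+.1f}% change of crude HR)"
        )
    return "\n".join(lines) + "\n"
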