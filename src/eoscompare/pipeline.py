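"""End-to-end orchestration: simulate or load a cohort, run both decision
engines, compare, and write a reproducible report bundle.

A pipeline run is fully described by a :class:`PipelineConfig` (loadable
from YAML).  Identical config + seed produce byte-identical outputs; the
run manifest records the config hash, seed, package version and every
decision-engine threshold so a run can be audited and repeated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .cohort import outcomes_to_frame, read_cohort, write_cohort
from .comparison import StrategyComparison
from .nsc import NscConfig
from .sco import ScoConfig, TreatPolicy
from .simulate import CohortParams, generate_cohort
from .stats import CiMethod, McNemarVariant

__all__ = ["PipelineConfig", "ComparisonOptions", "run_pipeline", "load_config"]

logger = logging.getLogger("eoscompare")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonOptions:
    mcnemar: McNemarVariant = McNemarVariant.EXACT_BINOMIAL
    ci: CiMethod = CiMethod.WALD_PAIRED
    rounding: int = 2


@dataclass(frozen=True)
class PipelineConfig:
    output_dir: Path = Path("eoscompare-run")
    seed: int = 0
    simulate: Optional[CohortParams] = None
    input_cohort: Optional[Path] = None
    nsc: NscConfig = field(default_factory=NscConfig)
    sco: ScoConfig = field(default_factory=ScoConfig)
    comparison: ComparisonOptions = field(default_factory=ComparisonOptions)
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.simulate is None) == (self.input_cohort is None):
            raise ConfigError(
                "exactly one of 'simulate' and 'input_cohort' must be configured"
            )


def _build(cls, data: dict, path: str):
    """Construct a (frozen) dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) under {path!r}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[f.name] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration under {path!r}: {exc}") from exc


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top-level configuration must be a mapping")
    kwargs: dict = {}
    if "simulate" in raw and raw["simulate"] is not None:
        sim = dict(raw.pop("simulate"))
        sim.setdefault("seed", raw.get("seed", 0))
        kwargs["simulate"] = _build(CohortParams, sim, "simulate")
    else:
        raw.pop("simulate", None)
    if raw.get("input_cohort"):
        kwargs["input_cohort"] = Path(raw.pop("input_cohort"))
    else:
        raw.pop("input_cohort", None)
    if "nsc" in raw:
        kwargs["nsc"] = _build(NscConfig, raw.pop("nsc") or {}, "nsc")
    if "sco" in raw:
        sco_raw = dict(raw.pop("sco") or {})
        if "treat_policy" in sco_raw:
            sco_raw["treat_policy"] = TreatPolicy(sco_raw["treat_policy"])
        kwargs["sco"] = _build(ScoConfig, sco_raw, "sco")
    if "comparison" in raw:
        comp_raw = dict(raw.pop("comparison") or {})
        if "mcnemar" in comp_raw:
            comp_raw["mcnemar"] = McNemarVariant(comp_raw["mcnemar"])
        if "ci" in comp_raw:
            comp_raw["ci"] = CiMethod(comp_raw["ci"])
        kwargs["comparison"] = _build(ComparisonOptions, comp_raw, "comparison")
    if "output_dir" in raw:
        kwargs["output_dir"] = Path(raw.pop("output_dir"))
    for key in ("seed", "log_level"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ConfigError(f"unknown top-level key(s): {sorted(raw)}")
    return PipelineConfig(**kwargs)


def _config_digest(config: PipelineConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, (tuple, list)):
            return [enc(x) for x in obj]
        if hasattr(obj, "value"):
            return obj.value
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    blob = json.dumps(enc(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and write the report bundle into output_dir.

    Writes: the cohort CSVs (when simulated), per-strategy decision CSVs,
    a paired-tables TSV, the human-readable statistics report, the
    stratified rate summary, and ``manifest.json``.  Returns a dict of the
    written paths plus the fitted results object under ``"results"``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        params = dataclasses.replace(config.simulate, seed=config.seed)
        logger.info("simulating cohort: n=%d seed=%d", params.n, params.seed)
        records = generate_cohort(params)
        cohort_path = out / "cohort.csv"
        write_cohort(records, cohort_path)
    else:
        cohort_path = Path(config.input_cohort)
        logger.info("loading cohort from %s", cohort_path)
        records = read_cohort(cohort_path)

    model = StrategyComparison(
        records,
        nsc_config=config.nsc,
        sco_config=config.sco,
        mcnemar_variant=config.comparison.mcnemar,
        ci_method=config.comparison.ci,
    )
    results = model.fit()

    paths = {"cohort": cohort_path}
    sco_path = out / "decisions_sco.csv"
    nsc_path = out / "decisions_nsc.csv"
    outcomes_to_frame(results.outcomes_sco).to_csv(sco_path, index=False, lineterminator="\n")
    nsc_frame = outcomes_to_frame(results.outcomes_nsc)
    est = results.risk_estimates
    nsc_frame["category"] = [est[i].category.value for i in nsc_frame["id"]]
    nsc_frame["prior_per_1000"] = [est[i].prior_per_1000 for i in nsc_frame["id"]]
    nsc_frame["posterior_per_1000"] = [est[i].posterior_per_1000 for i in nsc_frame["id"]]
    nsc_frame["stratum"] = [est[i].stratum.value for i in nsc_frame["id"]]
    nsc_frame.to_csv(nsc_path, index=False, lineterminator="\n", float_format="%.6g")

    tables_path = out / "paired_tables.tsv"
    results.to_frame().to_csv(tables_path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")
    report_path = out / "report.txt"
    report_path.write_text(results.summary())
    rates_path = out / "rate_summary.tsv"
    results.rate_summary.to_csv(rates_path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")

    manifest = {
        "package": "eoscompare",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_digest(config),
        "n_records": len(records),
        "nsc_thresholds": {
            "incidence_per_1000": config.nsc.incidence_per_1000,
            "likelihood_ratios": [config.nsc.lr_well, config.nsc.lr_equivocal, config.nsc.lr_clinical],
            "strata_cutoffs_per_1000": list(config.nsc.strata_cutoffs_per_1000),
            "decision_thresholds_per_1000": list(config.nsc.decision_thresholds_per_1000),
        },
        "sco_thresholds": {
            "schedule_hours": list(config.sco.schedule_hours),
            "minor_persistence_hours": config.sco.minor_persistence_hours,
            "reeval_interval_hours": config.sco.reeval_interval_hours,
            "treat_policy": config.sco.treat_policy.value,
        },
        "outputs": {
            "decisions_sco": sco_path.name,
            "decisions_nsc": nsc_path.name,
            "paired_tables": tables_path.name,
            "report": report_path.name,
            "rate_summary": rates_path.name,
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    paths.update(
        decisions_sco=sco_path,
        decisions_nsc=nsc_path,
        paired_tables=tables_path,
        report=report_path,
        rate_summary=rates_path,
        manifest=manifest_path,
        results=results,
    )
    return paths
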