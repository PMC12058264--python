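"""End-to-end orchestration: simulate -> score -> STAT -> associate.

One :class:`RunConfig` (usually read from YAML) governs a whole run; the
pipeline writes every intermediate table, a log, and a manifest with the
config hash, seeds, package versions and per-stage row counts so a run can
be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import run_battery
from .io import read_dosages
from .risk import compute_scores, harmonize_dosages, load_risk_model
from .simulate import SimulationConfig, generate_cohort
from .toxicity import SITE_ENDPOINTS, Windows, load_toxicity_records, stat_table, summarize_endpoints

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Inputs and analysis settings for one pipeline run.

    Either ``simulation`` is set (the cohort is generated into the output
    directory) or the four input paths must point at existing files.
    """

    site: str = "prostate"
    out_dir: str = "radiotox_run"
    simulation: SimulationConfig | None = None
    risk_model_path: str | None = None
    genotypes_path: str | None = None
    toxicity_path: str | None = None
    covariates_path: str | None = None
    alpha: float = 0.05
    weight_scheme: str = "or"
    drop_ambiguous: bool = False
    use_delta: str = "auto"
    percentile: float = 90.0
    endpoints: dict[str, list[str]] | None = None
    windows: Windows = field(default_factory=Windows)

    def __post_init__(self) -> None:
        eps = self.endpoints or SITE_ENDPOINTS.get(self.site)
        if not eps or not eps.get("acute") or not eps.get("late"):
            raise ValueError(f"endpoint families for site {self.site!r} must be non-empty")
        if self.simulation is None:
            for name in ("risk_model_path", "genotypes_path", "toxicity_path", "covariates_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} is required when no simulation is configured")

    @classmethod
    def from_yaml(cls, path, overrides: dict | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides or {})
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        win = raw.pop("windows", None)
        if win is not None:
            win = Windows(**win)
            raw["windows"] = win
        return cls(simulation=sim, **raw)

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage in order and write the results bundle.

    Outputs under ``config.out_dir``: scores.tsv, harmonization.tsv,
    endpoint_summaries.tsv, stat.tsv, results.tsv, run.log, manifest.json
    (plus the simulated inputs when a simulation is configured).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("radiotox")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    counts: dict[str, int] = {}
    try:
        if config.simulation is not None:
            paths = _stage("simulate")(generate_cohort)(config.simulation, out / "inputs")
            rm_path, geno_path = paths["risk_model"], paths["dosages"]
            tox_path, cov_path = paths["toxicity"], paths["covariates"]
        else:
            rm_path, geno_path = config.risk_model_path, config.genotypes_path
            tox_path, cov_path = config.toxicity_path, config.covariates_path

        model = _stage("load_risk_model")(load_risk_model)(rm_path)
        counts["model_variants"] = len(model)
        panel = _stage("read_genotypes")(read_dosages)(geno_path)
        counts["samples"] = panel.n_samples
        harmonized, report = _stage("harmonize")(harmonize_dosages)(
            panel, model, drop_ambiguous=config.drop_ambiguous
        )
        counts["variants_retained"] = harmonized.n_variants
        scores = _stage("score")(compute_scores)(harmonized, model, config.weight_scheme)
        records = _stage("load_toxicity")(load_toxicity_records)(tox_path)
        counts["toxicity_records"] = len(records)
        summaries = _stage("summarize")(summarize_endpoints)(records, config.windows)
        counts["endpoint_summaries"] = len(summaries)
        stat = _stage("stat")(stat_table)(
            summaries, config.site, use_delta=config.use_delta, endpoints=config.endpoints
        )
        covariates = _stage("load_covariates")(pd.read_csv)(cov_path, sep="\t", index_col="patient_id")
        counts["covariate_rows"] = len(covariates)
        results = _stage("associate")(run_battery)(
            scores.scores,
            stat,
            summaries,
            covariates,
            site=config.site,
            endpoints=config.endpoints,
            alpha=config.alpha,
            percentile=config.percentile,
            use_delta_outcomes=config.use_delta,
        )
        counts["result_rows"] = len(results)

        outputs = {
            "scores": out / "scores.tsv",
            "harmonization": out / "harmonization.tsv",
            "endpoint_summaries": out / "endpoint_summaries.tsv",
            "stat": out / "stat.tsv",
            "results": out / "results.tsv",
            "manifest": out / "manifest.json",
            "log": out / "run.log",
        }
        scores.to_tsv(outputs["scores"])
        report.to_csv(outputs["harmonization"], sep="\t", index=False)
        summaries.to_csv(outputs["endpoint_summaries"], sep="\t", index=False)
        stat.to_csv(outputs["stat"], sep="\t")
        results.to_csv(outputs["results"], sep="\t", index=False, float_format="%.10g")
        manifest = {
            "radiotox_version": __version__,
            "config": json.loads(json.dumps(asdict(config), default=str)),
            "config_digest": config.digest(),
            "row_counts": counts,
        }
        with open(outputs["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=1)
        logger.info("pipeline complete: %s", counts)
        return outputs
    finally:
        root.removeHandler(handler)
        handler.close()
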