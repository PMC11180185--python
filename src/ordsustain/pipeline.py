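"""End-to-end pipeline: simulate/load -> fit -> assign -> characterize -> report.

A :class:`RunConfig` (loadable from YAML) fixes every input path, model
parameter and seed; :func:`run_pipeline` executes the stages in order into
a run directory and writes a manifest carrying the package version, the
seed and a hash of the configuration.  Re-running an identical
configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .characterize import peripheral_trajectory, stage_correlation, subtype_comparison
from .inference import FitConfig
from .io import (
    read_covariates,
    read_scores,
    write_covariates,
    write_exclusion_log,
    write_model,
    write_scores,
    write_truth,
)
from .model import OrdinalSuStaIn
from .simulate import simulate_cohort, simulate_covariates

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "ordsustain_run"
    scores_csv: str | None = None  # simulate a cohort when absent
    covariates_csv: str | None = None
    sigma: float = 0.5
    n_subtypes: int = 2
    confidence_threshold: float = 0.5
    window_width: int = 10
    window_step: int = 1
    loess_span: float = 0.75
    seed: int = 0
    n_simulated_subjects: int = 300
    missing_rate: float = 0.1
    fit: FitConfig = field(default_factory=lambda: FitConfig(n_mcmc_iterations=2000))
    force: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.confidence_threshold < 1:
            raise ValueError("confidence threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fit = FitConfig(**raw.pop("fit", {}))
        return cls(fit=fit, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the pipeline; returns the run directory."""
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise FileExistsError(
            f"{out} already contains outputs; set force=true to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)
    for path_field in ("scores_csv", "covariates_csv"):
        value = getattr(config, path_field)
        if value is not None and not Path(value).exists():
            raise FileNotFoundError(f"stage 'input': {path_field} {value!r} not found")
    t0 = time.time()
    fit_cfg = dataclasses.replace(config.fit, seed=config.seed)

    # --- stage: inputs ----------------------------------------------------
    truth = None
    if config.scores_csv is None:
        logger.info("stage simulate: N=%d", config.n_simulated_subjects)
        table, truth = simulate_cohort(
            n_subjects=config.n_simulated_subjects,
            noise_sd=0.5,
            missing_rate=config.missing_rate,
            seed=config.seed,
        )
        covariates = simulate_covariates(table, truth, seed=config.seed + 1)
        write_scores(table, out / "scores.csv")
        write_covariates(covariates, out / "covariates.csv")
        write_truth(truth, out / "truth.json")
    else:
        table = read_scores(config.scores_csv)
        covariates = (
            read_covariates(config.covariates_csv)
            if config.covariates_csv
            else None
        )

    # --- stage: fit -------------------------------------------------------
    logger.info("stage fit: %d subtypes", config.n_subtypes)
    model = OrdinalSuStaIn(table, sigma=config.sigma)
    write_exclusion_log(model.exclusion_log, out / "exclusions.csv")
    results = model.fit(n_subtypes=config.n_subtypes, config=fit_cfg)
    write_model(results.subtype_model, out / "model.json")

    # --- stage: assign ----------------------------------------------------
    logger.info("stage assign")
    assignments = results.assign(confidence_threshold=config.confidence_threshold)
    assignments.to_csv(out / "assignments.csv", index=False)
    results.positional_variance().to_frame().to_csv(
        out / "positional_variance.csv", index=False
    )
    results.staging_histogram().to_csv(out / "staging_histogram.csv")

    # --- stage: characterize ---------------------------------------------
    if covariates is not None:
        logger.info("stage characterize")
        corr_rows = []
        for name in ("total_brain_lb", "age_at_death"):
            if name in covariates:
                try:
                    for res in stage_correlation(
                        assignments, covariates[name], by_subtype=True
                    ):
                        corr_rows.append(
                            {
                                "covariate": name,
                                "subtype": res.group,
                                "rho": res.rho,
                                "pvalue": res.pvalue,
                                "n": res.n,
                                "degenerate": res.degenerate,
                            }
                        )
                except ValueError as exc:
                    logger.warning("correlation for %s skipped: %s", name, exc)
        pd.DataFrame(corr_rows).to_csv(out / "stage_correlations.csv", index=False)
        if assignments[assignments["included"]]["subtype"].nunique() >= 2:
            for name, kind in (
                ("plaque_total", "continuous"),
                ("tangle_total", "continuous"),
            ):
                if name in covariates:
                    subtype_comparison(
                        covariates[name], kind, assignments, covariates, fdr=True
                    ).to_csv(out / f"comparison_{name}.csv", index=False)
        if "nonbrain_total" in covariates.columns:
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                peripheral_trajectory(
                    assignments, covariates["nonbrain_total"], span=config.loess_span
                ).to_csv(out / "peripheral_trajectory.csv", index=False)

    # --- manifest ---------------------------------------------------------
    manifest = {
        "package": "ordsustain",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "wall_time_s": round(time.time() - t0, 2),
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
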