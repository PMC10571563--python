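"""Configuration-driven orchestration of the full mediation pipeline.

One run = (generate or read a cohort) -> impute debulking -> for every
requested (deprivation index, mediator) pair: pilot fit, Gibbs variable
selection, refit with the selected modifiers, mediation effect tables and
convergence diagnostics — with per-pair derived seeds so any pair is
independently reproducible, and a JSON manifest recording config, seeds and
output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
import traceback
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import CohortTable, exposure_spec, read_cohort, summarize_cohort
from .impute import apply_consensus, consensus_mode, impute_mi
from .jointmodel import (
    JointModelSpec,
    build_model_data,
    diagnostics,
    drop_missing_mediator,
    fit_two_phase,
)
from .mediation import mediation_summary
from .simulate import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline invocation: data source, exposures, mediators, MCMC sizes."""

    exposures: tuple = ("URB",)
    mediators: tuple = ("stage3",)
    output_dir: str = "results/run"
    seed: int = 0
    cohort_path: str | None = None          # read this file...
    schema: dict | None = None
    generator: GeneratorConfig | None = None  # ...or generate synthetically
    m_imputations: int = 25
    chains: int = 2
    iterations: int = 1200
    burn_in: int = 400
    contrast: tuple = (0.0, 1.0)
    model_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exposures or not self.mediators:
            raise ValueError("need at least one exposure and one mediator")


def pair_seed(global_seed: int, exposure: str, mediator: str) -> int:
    """Stable per-pair seed: hash of (global seed, exposure, mediator)."""
    return zlib.crc32(f"{global_seed}:{exposure}:{mediator}".encode()) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohort(config: RunConfig) -> CohortTable:
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path, schema=config.schema)
    gen = config.generator or GeneratorConfig(seed=config.seed)
    return generate_cohort(gen, truth_draws=10_000).cohort


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full two-phase analysis for every (exposure, mediator) pair.

    Writes, under ``config.output_dir``: the descriptive summary, the
    consensus-imputed cohort's imputation diagnostics, one effects table and
    one GVS report per pair, and ``manifest.json``. A failing pair is logged
    with its traceback and the remaining pairs still run; the manifest's
    ``status`` records any partial failure.
    """
    outdir = Path(config.output_dir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("ok")
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"output directory {outdir} is not writable: {exc}") from exc

    t_start = _time.time()
    cohort = _load_cohort(config)
    summarize_cohort(cohort).to_csv(outdir / "descriptives.csv", index=False)

    imps = impute_mi(cohort, m=config.m_imputations, seed=config.seed + 7)
    imps.coefficients.to_csv(outdir / "imputation_coefficients.csv", index=False)
    completed = apply_consensus(cohort, consensus_mode(imps))

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _jsonable(dataclasses.asdict(config)),
        "n": completed.n,
        "pairs": {},
        "outputs": {},
        "status": "ok",
    }

    for exposure in config.exposures:
        for mediator in config.mediators:
            key = f"{exposure}__{mediator}"
            seed = pair_seed(config.seed, exposure, mediator)
            try:
                manifest["pairs"][key] = _run_pair(
                    completed, exposure, mediator, seed, config, outdir)
            except Exception:
                logger.error("pair %s failed:\n%s", key, traceback.format_exc())
                manifest["pairs"][key] = {"status": "failed",
                                          "traceback": traceback.format_exc()}
                manifest["status"] = "partial_failure"

    for path in sorted(outdir.glob("*.csv")):
        manifest["outputs"][path.name] = _sha256(path)
    manifest["runtime_s"] = round(_time.time() - t_start, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline finished in %.1fs (%s)", manifest["runtime_s"],
                manifest["status"])
    return manifest


def _run_pair(completed: CohortTable, exposure: str, mediator: str, seed: int,
              config: RunConfig, outdir: Path) -> dict:
    cohort_cc = drop_missing_mediator(completed, mediator)
    data = build_model_data(cohort_cc, exposure_spec(exposure), mediator)
    spec = JointModelSpec(
        exposure=exposure_spec(exposure), mediator=mediator,
        chains=config.chains, iterations=config.iterations,
        burn_in=config.burn_in, seed=seed, **config.model_overrides)
    result = fit_two_phase(data, spec)
    summary = mediation_summary(result.draws, data, contrast=config.contrast)

    key = f"{exposure}__{mediator}"
    gvs_df = pd.DataFrame(
        [{"modifier": m, "inclusion_frequency": f,
          "selected": m in result.selected}
         for m, f in result.gvs_report.inclusion.items()])
    gvs_df.to_csv(outdir / f"gvs_{key}.csv", index=False)
    table = summary.table.copy()
    table.insert(0, "mediator", mediator)
    table.insert(0, "exposure", exposure)
    table.to_csv(outdir / f"effects_{key}.csv", index=False)
    diagnostics(result.draws).to_csv(outdir / f"diagnostics_{key}.csv", index=False)

    direct_row = summary.table[summary.table["effect"] == "direct"].iloc[0]
    return {
        "status": "ok",
        "seed": seed,
        "n_fit": data.n,
        "selected_modifiers": sorted(result.selected),
        "inclusion": result.gvs_report.inclusion,
        "direct_hr": float(direct_row["mean"]),
        "direct_ci": [float(direct_row["lo"]), float(direct_row["hi"])],
        "well_estimated": bool(direct_row["well_estimated"]),
        "max_rhat": None if pd.isna(result.refit_report.max_rhat)
        else float(result.refit_report.max_rhat),
        "converged": bool(result.refit_report.converged),
        "exposure_direction": exposure_spec(exposure).direction,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def compare_runs(manifests: list) -> pd.DataFrame:
    """Cross-index summary of direct effects and well-estimated flags.

    Accepts manifest dicts or paths to manifest.json files; all runs must
    cover the same mediator set.
    """
    loaded = []
    for m in manifests:
        if not isinstance(m, dict):
            m = json.loads(Path(m).read_text())
        loaded.append(m)
    if len(loaded) < 2:
        raise ValueError("need at least two completed manifests to compare")

    def mediators_of(man):
        return sorted({k.split("__")[1] for k in man["pairs"]})

    base = mediators_of(loaded[0])
    for man in loaded[1:]:
        if mediators_of(man) != base:
            raise ValueError(f"mediator sets differ: {base} vs {mediators_of(man)}")

    rows = []
    for run_idx, man in enumerate(loaded):
        for key, pair in man["pairs"].items():
            if pair.get("status") != "ok":
                continue
            exposure, mediator = key.split("__")
            rows.append({
                "run": run_idx, "exposure": exposure, "mediator": mediator,
                "direction": pair.get("exposure_direction", ""),
                "direct_hr": pair["direct_hr"],
                "lo": pair["direct_ci"][0], "hi": pair["direct_ci"][1],
                "well_estimated": pair["well_estimated"],
            })
    return pd.DataFrame(rows)
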