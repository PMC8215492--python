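"""End-to-end pipeline: cohort generation, statistics, simulation, calibration.

Artifacts written into the output directory (all text, UTF-8, LF):

- ``cohort.csv``      — synthetic subject table (if the cohort block is enabled)
- ``stats.csv``       — group-comparison results (if analysis is enabled)
- ``trajectory.csv``  — simulated model trajectory
- ``fit.json``        — calibration output (if cohort + calibration enabled)
- ``run.log``         — timestamped log (the only artifact with timestamps)

Every data artifact carries the configuration hash and the global seed in a
leading ``#`` comment (CSV) or dedicated fields (JSON), so a rerun with the
same configuration and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import calibrate, stats
from .cohort import generate_cohort, write_cohort
from .config import RunConfig, config_hash, derive_seed
from .errors import PipelineError
from .model import ModelState, simulate

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig, outdir, seed: int | None = None, verbose: bool = False) -> dict:
    """Execute the configured stages in order: generate, analyze, simulate, fit.

    ``seed`` overrides ``config.seed``; per-stage substream seeds are derived
    deterministically from it (see :func:`marrow_reservoir.config.derive_seed`).
    Returns a mapping from artifact name to path for the stages that ran.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    global_seed = config.seed if seed is None else seed
    chash = config_hash(config)
    comment = f"config={chash} seed={global_seed}"

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("marrow_reservoir")
    root.addHandler(handler)
    root.setLevel(logging.DEBUG if verbose else logging.INFO)
    artifacts: dict[str, Path] = {"log": log_path}

    try:
        logger.info("pipeline start (config %s, seed %d)", chash, global_seed)
        cohort_df = None
        if config.cohort is not None:
            cohort_df = _generate(config, global_seed, outdir, comment, artifacts)
        if cohort_df is not None and config.analysis is not None:
            _analyze(config, cohort_df, global_seed, outdir, comment, artifacts)
        _simulate(config, outdir, comment, artifacts)
        if cohort_df is not None and config.calibration is not None:
            _fit(config, cohort_df, global_seed, outdir, chash, artifacts)
        logger.info("pipeline done: %s", ", ".join(sorted(artifacts)))
    finally:
        root.removeHandler(handler)
        handler.close()
    return artifacts


@_stage("generate")
def _generate(config, global_seed, outdir, comment, artifacts):
    cohort_df = generate_cohort(config.cohort, seed=derive_seed(global_seed, "cohort"))
    path = outdir / "cohort.csv"
    write_cohort(cohort_df, path, comment=comment)
    logger.info("generated cohort with %d subjects", len(cohort_df))
    artifacts["cohort"] = path
    return cohort_df


@_stage("analyze")
def _analyze(config, cohort_df, global_seed, outdir, comment, artifacts):
    results = stats.analyze_cohort(
        cohort_df,
        plan=config.analysis.plan,
        alpha=config.analysis.alpha,
        n_mc=config.analysis.n_mc,
        seed=derive_seed(global_seed, "stats"),
    )
    path = outdir / "stats.csv"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# {comment}\n")
        results.to_csv(fh, index=False, lineterminator="\n")
    logger.info("analysis produced %d result rows", len(results))
    artifacts["stats"] = path


@_stage("simulate")
def _simulate(config, outdir, comment, artifacts):
    m = config.model
    initial = ModelState(t=0.0, m=m.params.m0, c=m.params.c0)
    traj = simulate(m.params, m.signal, initial=initial, t_end=m.t_end, h=m.h)
    path = outdir / "trajectory.csv"
    traj.to_csv(path, comment=comment)
    logger.info("simulated trajectory with %d grid points", len(traj.times))
    artifacts["trajectory"] = path
    return traj


@_stage("fit")
def _fit(config, cohort_df, global_seed, outdir, chash, artifacts):
    observed = calibrate.observed_stage_vector(cohort_df)
    k = config.calibration
    fit_config = calibrate.FitConfig(
        params=config.model.params,
        level=k.level,
        observable_map=calibrate.ObservableMap(a_m=k.a_m, b_m=k.b_m),
        stage_map=config.model.stage_map,
        h=k.h,
        weight_share=k.weight_share,
        weight_chemo=k.weight_chemo,
        grid_points=k.grid_points,
        n_starts=k.n_starts,
        jitter=k.jitter,
        seed=derive_seed(global_seed, "fit"),
    )
    result = calibrate.fit(observed, free_params=k.free_params, bounds=k.bounds, config=fit_config)
    path = outdir / "fit.json"
    payload = {
        "config": chash,
        "seed": config.seed if global_seed is None else global_seed,
        "theta_hat": result.theta_hat,
        "loss": result.loss,
        "n_evals": result.n_evals,
        "converged": result.converged,
        "observed": {
            "stage": observed["stage"].tolist(),
            "inflammatory_share_pct": observed["inflammatory_share_pct"].tolist(),
            "relative_chemotaxis": observed["relative_chemotaxis"].tolist(),
        },
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    logger.info("fit finished: loss=%.6g after %d evaluations", result.loss, result.n_evals)
    artifacts["fit"] = path
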