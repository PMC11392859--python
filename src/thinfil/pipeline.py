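"""Reproducible pipeline: WT steady state -> mutant grid search ->
expression sweep -> expression inference.

``run_pipeline`` executes the requested stages in dependency order,
resumes from existing artifacts (a stage whose outputs are already in
``out_dir`` is skipped), and writes a :class:`~thinfil.io.RunManifest`
recording every input, seed and artifact.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np

from .fitting import (
    DEFAULT_EXPRESSIONS,
    DEFAULT_GAMMA_SCALES,
    DEFAULT_KBC_SCALES,
    IvmaTargets,
    TwitchDeltaTargets,
    expression_sweep,
    grid_search_ivma,
    infer_expression,
)
from .io import RunManifest, read_json, read_table, write_json, write_table
from .model import MutationSpec, load_parameter_set
from .protocols import CaTransient, DEFAULT_PCA_GRID, fit_hill, run_pca_sweep

__all__ = ["run_pipeline", "PipelineDependencyError", "ALL_STAGES"]

log = logging.getLogger("thinfil.pipeline")

ALL_STAGES = ("simulate-pca", "fit-ivma", "expression-sweep", "infer-expression")


class PipelineDependencyError(RuntimeError):
    """An upstream artifact required by a requested stage is missing."""


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Run the configured stages and return the manifest.

    Config keys (all optional unless a stage needs them):
    ``stages`` (default: all four), ``seed``, ``param_set`` (steady-state
    set; default "set1"), ``kinetic_set`` (twitch set; default "set2"),
    ``n_traj``, ``n_repeats``, ``pca_grid``, ``gamma_scales``,
    ``kbc_scales``, ``expressions``, ``ivma_targets``
    (``{delta_pca50, pct_delta_vmax}``; required by fit-ivma),
    ``twitch_targets`` (``{pct_f_peak, pct_rt50, pct_nfti[, sem_*]}``;
    required by infer-expression), ``mutation``
    (``{gamma_scale, kbc_scale}``; used by expression-sweep when
    fit-ivma did not run), ``ca_transient`` (CaTransient fields).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    seed = int(config.get("seed", 0))
    stage_seeds = dict(zip(ALL_STAGES, _spawn_seeds(seed, len(ALL_STAGES))))
    manifest = RunManifest(config=dict(config), seeds={"master": seed, **stage_seeds})

    ss_name = config.get("param_set", "set1")
    kin_name = config.get("kinetic_set", "set2")
    ss_params = load_parameter_set(ss_name)
    kin_params = load_parameter_set(kin_name)
    manifest.parameter_sets = {"steady_state": str(ss_name), "kinetic": str(kin_name)}

    n_traj = int(config.get("n_traj", 1920))
    n_repeats = int(config.get("n_repeats", 10))
    pca_grid = np.asarray(config.get("pca_grid", DEFAULT_PCA_GRID), dtype=float)
    duration = float(config.get("duration", 10.0))
    window = float(config.get("window", 2.5))
    transient = CaTransient(**config.get("ca_transient", {}))

    def stage_done(paths: list[Path]) -> bool:
        return all(p.exists() for p in paths)

    # --- simulate-pca -----------------------------------------------------
    pca_csv = out_dir / "wt_pca_sweep.csv"
    pca_fit_json = out_dir / "wt_hill_fit.json"
    if "simulate-pca" in stages:
        if stage_done([pca_csv, pca_fit_json]):
            log.info("simulate-pca: artifacts exist, skipping")
            manifest.stages_skipped.append("simulate-pca")
        else:
            log.info("simulate-pca: WT sweep over %d pCa points", pca_grid.size)
            sweep = run_pca_sweep(
                ss_params, pca_grid, n_traj=n_traj,
                seed=stage_seeds["simulate-pca"],
                duration=duration, window=window,
            )
            write_table(sweep, pca_csv)
            fit = fit_hill(sweep[["pca", "force"]])
            write_json(dataclasses.asdict(fit), pca_fit_json)
            manifest.stages_run.append("simulate-pca")
        manifest.record("simulate-pca", "sweep", pca_csv)
        manifest.record("simulate-pca", "hill_fit", pca_fit_json)

    # --- fit-ivma ---------------------------------------------------------
    grid_csv = out_dir / "ivma_grid.csv"
    argmin_json = out_dir / "ivma_argmin.json"
    if "fit-ivma" in stages:
        if stage_done([grid_csv, argmin_json]):
            log.info("fit-ivma: artifacts exist, skipping")
            manifest.stages_skipped.append("fit-ivma")
        else:
            if "ivma_targets" not in config:
                raise PipelineDependencyError(
                    "fit-ivma requires config['ivma_targets'] "
                    "(delta_pca50, pct_delta_vmax)"
                )
            targets = IvmaTargets(**config["ivma_targets"])
            result = grid_search_ivma(
                ss_params,
                gamma_scales=config.get("gamma_scales", DEFAULT_GAMMA_SCALES),
                kbc_scales=config.get("kbc_scales", DEFAULT_KBC_SCALES),
                targets=targets,
                pca_grid=pca_grid,
                n_traj=n_traj,
                seed=stage_seeds["fit-ivma"],
                duration=duration,
                window=window,
            )
            write_table(result.cells, grid_csv)
            write_json(
                {
                    "gamma_scale": result.argmin[0],
                    "kbc_scale": result.argmin[1],
                    "sse": float(np.nanmin(result.sse_surface)),
                    "targets": dataclasses.asdict(targets),
                },
                argmin_json,
            )
            manifest.stages_run.append("fit-ivma")
        manifest.record("fit-ivma", "grid", grid_csv)
        manifest.record("fit-ivma", "argmin", argmin_json)

    # --- expression-sweep ---------------------------------------------------
    sweep_csv = out_dir / "expression_sweep.csv"
    if "expression-sweep" in stages:
        if stage_done([sweep_csv]):
            log.info("expression-sweep: artifact exists, skipping")
            manifest.stages_skipped.append("expression-sweep")
        else:
            if argmin_json.exists():
                am = read_json(argmin_json)
                mut = MutationSpec(
                    gamma_scale=am["gamma_scale"], kbc_scale=am["kbc_scale"]
                )
            elif "mutation" in config:
                mut = MutationSpec(**config["mutation"])
            else:
                raise PipelineDependencyError(
                    "expression-sweep needs the fit-ivma argmin artifact or "
                    "config['mutation'] with gamma_scale/kbc_scale"
                )
            sweep = expression_sweep(
                kin_params,
                mut,
                expressions=config.get("expressions", DEFAULT_EXPRESSIONS),
                transient=transient,
                n_traj=n_traj,
                n_repeats=n_repeats,
                seed=stage_seeds["expression-sweep"],
            )
            write_table(sweep, sweep_csv)
            manifest.stages_run.append("expression-sweep")
        manifest.record("expression-sweep", "sweep", sweep_csv)

    # --- infer-expression ---------------------------------------------------
    match_json = out_dir / "expression_match.json"
    if "infer-expression" in stages:
        if stage_done([match_json]):
            log.info("infer-expression: artifact exists, skipping")
            manifest.stages_skipped.append("infer-expression")
        else:
            if not sweep_csv.exists():
                raise PipelineDependencyError(
                    "infer-expression needs the expression-sweep artifact "
                    f"({sweep_csv})"
                )
            if "twitch_targets" not in config:
                raise PipelineDependencyError(
                    "infer-expression requires config['twitch_targets']"
                )
            targets = TwitchDeltaTargets(**config["twitch_targets"])
            sweep = read_table(sweep_csv)
            match = infer_expression(sweep, targets)
            write_json(
                {
                    "best_expression": match.best_expression,
                    "admissible": match.admissible,
                    "admissible_empty_flag": match.admissible_empty_flag,
                    "sse_by_expression": {
                        str(k): float(v) for k, v in match.sse.items()
                    },
                    "targets": dataclasses.asdict(targets),
                },
                match_json,
            )
            manifest.stages_run.append("infer-expression")
        manifest.record("infer-expression", "match", match_json)

    manifest_path = out_dir / "manifest.json"
    manifest.save(manifest_path)
    log.info("pipeline complete; manifest at %s", manifest_path)
    return manifest
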