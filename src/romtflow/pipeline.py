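"""End-to-end pipeline: (phantom | NIfTI series) -> preprocess -> rOMT solve
-> augmented-velocity pathlines -> clustering -> maps and summaries -> flux.

Driven by a plain dict configuration (see :func:`default_config`); every
stage is timed and recorded in a JSON run manifest together with a checksum
of each artifact, so any output is reproducible from the manifest's config
and seed alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .flux import compartment_mass, extract_boundary, net_directed_influx, step_flux
from .grid import ImageGrid
from .lagrangian import (
    cluster_and_filter,
    integrate_pathlines,
    rasterize_pathlines,
    select_start_points,
    summarize_by_mask,
    timeline_from_solutions,
)
from .phantoms import (
    PhantomSpec,
    add_noise,
    analytic_field,
    make_diffusion_phantom,
    make_translation_phantom,
)
from .preprocess import (
    DensitySeries,
    clip_negative,
    gaussian_smooth,
    normalize_total_intensity,
    percent_baseline,
)
from .solver import RomtConfig, solve_series

__all__ = ["default_config", "build_phantom", "run_pipeline"]

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def default_config() -> dict:
    return {
        "seed": 0,
        "phantom": None,  # or {"kind": "diffusion"|"translation", ...}
        "input": None,  # or {"series": path, "times": [...], "baseline_count": 1}
        "masks": {},  # name -> NIfTI path
        "preprocess": {"smooth_fwhm": 0.0, "normalize": True},
        "solver": {},  # RomtConfig overrides
        "glad": {
            "threshold": 0.12,
            "stride": 1,
            "step_dt": 0.1,
            "cluster_threshold": None,
            "min_cluster_size": 5,
            "n_points": 12,
            "use_augmented": True,
        },
        "flux": None,  # or {"from": mask name, "to": mask name}
    }


def build_phantom(cfg: dict, seed: int) -> DensitySeries:
    """Construct the synthetic series described by a phantom config block."""
    dims = tuple(cfg.get("dims", (32, 32, 32)))
    grid = ImageGrid(dims=dims, voxel_size=float(cfg.get("voxel_size", 1.0)))
    kind = cfg.get("kind", "diffusion")
    v_true = None
    if "v_true" in cfg and cfg["v_true"] is not None:
        v_true = analytic_field(grid, "constant", value=np.asarray(cfg["v_true"], float))
    spec = PhantomSpec(
        grid=grid,
        v_true=v_true,
        sigma2_true=float(cfg.get("sigma2_true", 0.5)),
        n_frames=int(cfg.get("n_frames", 8)),
        frame_dt=float(cfg.get("frame_dt", 1.0)),
        substeps=int(cfg.get("substeps", 16)),
        noise_sd=float(cfg.get("noise_sd", 0.0)),
        seed=seed,
    )
    sd = float(cfg.get("sd", 3.0))
    mass = float(cfg.get("mass", 1.0))
    if kind == "diffusion":
        series = make_diffusion_phantom(spec, sd=sd, mass=mass)
    elif kind == "translation":
        if spec.v_true is None:
            raise ValueError("translation phantom requires v_true")
        series = make_translation_phantom(spec, sd=sd, mass=mass, start=cfg.get("start"))
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    if spec.noise_sd > 0:
        series = add_noise(series, spec.noise_sd, seed)
    return series


def _percent_view(series: DensitySeries) -> DensitySeries:
    """Percent-of-baseline view of a series regardless of its current units."""
    if series.units == "percent_baseline":
        return series
    raw_view = replace(series, units="raw")
    return percent_baseline(raw_view)


def run_pipeline(config: dict, output_dir) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = default_config()
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    seed = int(cfg.get("seed", 0))
    manifest: dict = {
        "config": json.loads(json.dumps(cfg, default=str)),
        "seed": seed,
        "version": __version__,
        "stages": {},
        "outputs": {},
        "completed": False,
    }

    def record(path: Path) -> None:
        manifest["outputs"][path.name] = rio.file_checksum(path)

    def finish(error: str | None = None) -> dict:
        manifest["completed"] = error is None
        if error is not None:
            manifest["error"] = error
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    try:
        # ---- input -------------------------------------------------------
        t0 = time.perf_counter()
        if cfg.get("phantom"):
            series = build_phantom(cfg["phantom"], seed)
        elif cfg.get("input"):
            inp = cfg["input"]
            series = rio.read_series(
                inp["series"],
                times=inp.get("times"),
                baseline_count=int(inp.get("baseline_count", 1)),
            )
        else:
            raise ValueError("config must provide either 'phantom' or 'input'")
        grid = series.grid
        masks = {
            name: rio.read_mask(path, grid) for name, path in (cfg.get("masks") or {}).items()
        }
        record(rio.write_series(series, out / "input_series.nii.gz"))
        manifest["stages"]["input"] = {"seconds": time.perf_counter() - t0,
                                       "n_frames": series.n_frames, "dims": grid.dims}

        # ---- preprocess --------------------------------------------------
        t0 = time.perf_counter()
        pp = cfg["preprocess"]
        percent = _percent_view(series)  # seed-selection view
        work = series
        if pp.get("smooth_fwhm", 0.0) > 0:
            work = gaussian_smooth(work, float(pp["smooth_fwhm"]))
        work = clip_negative(work)
        if pp.get("normalize", True):
            work = normalize_total_intensity(work)
        manifest["stages"]["preprocess"] = {"seconds": time.perf_counter() - t0}

        # ---- solve -------------------------------------------------------
        t0 = time.perf_counter()
        solver_cfg = RomtConfig(seed=seed, **(cfg.get("solver") or {}))
        solutions = solve_series(work, solver_cfg)
        conv = [
            {"pair": k, "energy": s.energy, "converged": s.converged,
             "iterations": len(s.convergence), "warning": s.warning}
            for k, s in enumerate(solutions)
        ]
        (out / "convergence.json").write_text(json.dumps(conv, indent=2))
        record(out / "convergence.json")
        manifest["stages"]["solve"] = {
            "seconds": time.perf_counter() - t0, "n_pairs": len(solutions)}

        # ---- pathlines ---------------------------------------------------
        t0 = time.perf_counter()
        glad = cfg["glad"]
        seeds = select_start_points(
            percent, threshold=float(glad["threshold"]), stride=int(glad["stride"])
        )
        timeline = timeline_from_solutions(
            solutions, solver_cfg.sigma2, use_augmented=bool(glad["use_augmented"])
        )
        frame_minutes = float(np.median(np.diff(series.times))) if series.n_frames > 1 else 1.0
        pset = integrate_pathlines(
            timeline, seeds, grid, step_dt=float(glad["step_dt"]),
            speed_scale=1.0 / frame_minutes,
        )
        pset = cluster_and_filter(
            pset,
            cluster_threshold=glad["cluster_threshold"],
            min_cluster_size=int(glad["min_cluster_size"]),
            n_points=int(glad["n_points"]),
        )
        pset.provenance.update({"seed": seed, "config_hash": hash_config(cfg)})
        if len(pset):
            record(rio.write_trk(pset, out / "pathlines.trk"))
            record(rio.write_vtk_polylines(pset, out / "pathlines.vtk"))
        binary = rasterize_pathlines(pset, "binary")
        speed = rasterize_pathlines(pset, "speed")
        record(rio.write_scalar_field(binary, out / "pathline_map.nii.gz"))
        record(rio.write_scalar_field(speed, out / "speed_map.nii.gz"))
        manifest["stages"]["pathlines"] = {
            "seconds": time.perf_counter() - t0,
            "n_seeds": int(len(seeds)), "n_kept": len(pset)}

        # ---- summaries ---------------------------------------------------
        t0 = time.perf_counter()
        summary_masks = dict(masks) if masks else {"whole_volume": np.ones(grid.dims, bool)}
        table = summarize_by_mask(binary, speed, summary_masks)
        table.to_csv(out / "summary.csv", index=False)
        record(out / "summary.csv")
        manifest["stages"]["summarize"] = {"seconds": time.perf_counter() - t0}

        # ---- flux (optional) --------------------------------------------
        if cfg.get("flux"):
            t0 = time.perf_counter()
            fx = cfg["flux"]
            boundary = extract_boundary(
                masks[fx["from"]], masks[fx["to"]], grid,
                from_label=fx["from"], into_label=fx["to"],
            )
            flux_series, t_axis = [], []
            tcum = 0.0
            for sol in solutions:
                N = len(sol.velocities)
                for n, v in enumerate(sol.velocities):
                    fl = step_flux(
                        sol.interpolants[n], sol.interpolants[n + 1],
                        v, solver_cfg.sigma2, boundary,
                    )
                    flux_series.append(fl["total"])
                    tcum += 1.0 / N
                    t_axis.append(tcum)
            influx, rates = net_directed_influx(flux_series, solver_cfg.dt)
            pd.DataFrame({"time": t_axis, "directed_influx_rate": rates}).to_csv(
                out / "flux_curve.csv", index=False)
            record(out / "flux_curve.csv")
            manifest["stages"]["flux"] = {
                "seconds": time.perf_counter() - t0,
                "cumulative_directed_influx": influx,
                "target_mass_first_last": [
                    compartment_mass(work.frames[0], masks[fx["to"]]),
                    compartment_mass(work.frames[-1], masks[fx["to"]]),
                ],
            }
    except Exception as exc:  # record partial completion
        logger.exception("pipeline failed")
        return finish(error=f"{type(exc).__name__}: {exc}")
    return finish()


def hash_config(cfg: dict) -> str:
    import hashlib

    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
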