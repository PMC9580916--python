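"""Configurable end-to-end analysis pipeline.

A pipeline is an ordered list of stages (simulate, bgfilter, localize,
merge, drift, render, frc, nena, ...) with per-stage parameters; each
stage reads the running state (movie, localization table, drift trace)
and writes its intermediates plus a JSON run manifest into an artifact
directory.  Stages can be skipped or reordered as long as their inputs
are available.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .bgfilter import MedianFilterParams, temporal_median_filter
from .cluster import DbscanParams, dbscan, summarize_clusters
from .core_io import DriftTrace, LocalizationTable, write_localizations, write_movie
from .drift import CCParams, FiducialParams, apply_drift, estimate_drift_cc, estimate_drift_fiducial
from .link import LinkParams, link_localizations, merge_linked
from .localize import DetectionParams, localize_movie
from .precision import frc_resolution, nena_precision
from .render import RenderParams, render
from .simulate import EmitterModel, NoiseModel, make_smooth_drift, simulate_movie

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Run the configured stages in order; returns the manifest dict.

    ``config`` holds ``pixel_size_nm``, ``frame_interval_s``, ``seed`` and a
    ``stages`` list of ``{stage: <name>, ...params}`` mappings.  Artifacts
    (TIFF movies, CSV tables, JSON reports) and a ``manifest.json`` with
    parameters, seeds and output hashes are written to ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    pixel_size_nm = float(config.get("pixel_size_nm", 100.0))
    frame_interval_s = float(config.get("frame_interval_s", 0.1))

    movie = None
    raw_movie = None
    table: LocalizationTable | None = None
    trace: DriftTrace | None = None
    manifest: dict = {"version": __version__, "seed": seed, "stages": [], "outputs": {}}

    stages = config.get("stages", [])
    names = [s.get("stage") for s in stages]
    if "frc" in names and "track" in names:
        raise ValueError("pipeline config error: FRC requires static structural data and "
                         "cannot follow a tracking stage on dynamic data")

    for idx, stage_cfg in enumerate(stages):
        stage = stage_cfg.get("stage")
        params = {k: v for k, v in stage_cfg.items() if k != "stage"}
        t0 = time.perf_counter()
        outputs: dict = {}

        if stage == "simulate":
            n_frames = int(params.get("n_frames", 200))
            shape = tuple(params.get("shape", (32, 32)))
            rng = np.random.default_rng(seed)
            n_emitters = int(params.get("n_emitters", 10))
            positions = rng.uniform(4, min(shape) - 4, size=(n_emitters, 2))
            emitters = EmitterModel(
                positions,
                k_on=float(params.get("k_on", 0.05)),
                k_off=float(params.get("k_off", 0.5)),
                photons_per_frame=float(params.get("photons_per_frame", 3000.0)),
                psf_sigma_px=float(params.get("psf_sigma_px", 1.3)),
            )
            noise = NoiseModel(
                background_offset=float(params.get("background_offset", 20.0)),
                read_noise_sigma=float(params.get("read_noise_sigma", 1.0)),
            )
            drift_amp = float(params.get("drift_amplitude_px", 0.0))
            sim_drift = make_smooth_drift(n_frames, drift_amp, seed=seed + 1) if drift_amp else None
            movie, truth = simulate_movie(emitters, noise, sim_drift, n_frames, shape, seed)
            movie.pixel_size_nm = pixel_size_nm
            movie.frame_interval_s = frame_interval_s
            raw_movie = movie
            p = out_dir / "simulated.tif"
            write_movie(movie, p)
            truth.emissions.to_csv(out_dir / "truth_emissions.csv", index=False)
            outputs["movie"] = str(p)

        elif stage == "bgfilter":
            movie = temporal_median_filter(
                raw_movie, MedianFilterParams(int(params.get("window", 51))), clamp=False
            )
            p = out_dir / "filtered.tif"
            write_movie(
                type(movie)(np.clip(movie.data, 0, None), movie.pixel_size_nm, movie.frame_interval_s), p
            )
            outputs["movie"] = str(p)

        elif stage == "localize":
            det = DetectionParams(threshold_k=float(params.get("threshold_k", 3.0)))
            filtered = movie if movie is not raw_movie else None
            table = localize_movie(raw_movie, filtered, det)
            p = out_dir / "localizations.csv"
            write_localizations(table, p)
            outputs["table"] = str(p)

        elif stage == "merge":
            linked = link_localizations(
                table.sorted_by_frame(),
                LinkParams(float(params.get("max_jump_px", 0.5)), int(params.get("gap", 2))),
            )
            table = merge_linked(linked)
            p = out_dir / "merged.csv"
            write_localizations(table, p)
            outputs["table"] = str(p)

        elif stage == "track":
            table = link_localizations(
                table.sorted_by_frame(),
                LinkParams(float(params.get("max_jump_px", 3.0)), int(params.get("gap", 1))),
            )
            p = out_dir / "tracks.csv"
            write_localizations(table, p)
            outputs["table"] = str(p)

        elif stage == "drift_fiducial":
            n_frames = int(table.df["frame"].max()) + 1
            trace, fiducials = estimate_drift_fiducial(
                table,
                FiducialParams(
                    min_presence_fraction=float(params.get("min_presence_fraction", 0.9)),
                    link_radius_px=float(params.get("link_radius_px", 1.0)),
                ),
                n_frames,
            )
            table = apply_drift(table, trace)
            trace.to_frame().to_csv(out_dir / "drift_trace.csv", index=False)
            p = out_dir / "drift_corrected.csv"
            write_localizations(table, p)
            outputs.update(table=str(p), n_fiducials=len(fiducials))

        elif stage == "drift_cc":
            n_frames = int(table.df["frame"].max()) + 1
            trace = estimate_drift_cc(
                table,
                CCParams(
                    bin_frames=int(params.get("bin_frames", max(n_frames // 10, 1))),
                    zoom=int(params.get("zoom", 5)),
                ),
                n_frames,
            )
            table = apply_drift(table, trace)
            trace.to_frame().to_csv(out_dir / "drift_trace.csv", index=False)
            p = out_dir / "drift_corrected.csv"
            write_localizations(table, p)
            outputs["table"] = str(p)

        elif stage == "render":
            rp = RenderParams(
                zoom=int(params.get("zoom", 10)),
                method=params.get("method", "histogram"),
                gaussian_sigma_px=float(params.get("gaussian_sigma_px", 1.0)),
            )
            img = render(table, rp)
            p = out_dir / f"render_{rp.method}.tif"
            import tifffile

            tifffile.imwrite(p, img.data.astype(np.float32))
            (out_dir / f"render_{rp.method}.json").write_text(
                json.dumps({"zoom": img.zoom, "origin": list(img.origin), "n_dropped": img.n_dropped})
            )
            outputs["image"] = str(p)

        elif stage == "cluster":
            res = dbscan(table, DbscanParams(
                eps=float(params.get("eps", 0.5)),
                min_points=int(params.get("min_points", 5)),
                unit=params.get("unit", "px"),
            ))
            summarize_clusters(res, table).to_csv(out_dir / "clusters.csv", index=False)
            outputs["n_clusters"] = res.n_clusters

        elif stage == "frc":
            curve = frc_resolution(
                table, float(params.get("render_pixel_nm", 10.0)), seed=seed
            )
            outputs["resolution_nm"] = curve.resolution_nm
            (out_dir / "frc.json").write_text(json.dumps(
                {"q_per_nm": curve.q.tolist(), "frc": curve.frc.tolist(),
                 "threshold": curve.threshold, "resolution_nm": curve.resolution_nm}
            ))

        elif stage == "nena":
            fit = nena_precision(table)
            outputs["sigma_nm"] = fit.sigma_nm
            (out_dir / "nena.json").write_text(json.dumps(
                {"sigma_px": fit.sigma_px, "sigma_nm": fit.sigma_nm,
                 "n_distances": len(fit.distances)}
            ))

        else:
            raise ValueError(f"unknown pipeline stage: {stage!r}")

        manifest["stages"].append(
            {"index": idx, "stage": stage, "params": params,
             "elapsed_s": round(time.perf_counter() - t0, 3), "outputs": outputs}
        )

    for f in sorted(out_dir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    # elapsed timings vary run-to-run; hash identity is checked on outputs only
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
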