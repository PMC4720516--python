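"""End-to-end orchestration of the analysis stages.

``run_pipeline`` sequences: synthetic generation (or ingestion of a cell
table / image stack) -> segmentation -> quantification -> timeline ->
dynamics -> noise -> spatial correlation, writing every intermediate
artifact plus a manifest recording the seed, every parameter value, and
per-stage record counts.  Runs are deterministic under a fixed seed.

Modes
-----
synthetic   generate discs, render them, and push the rendered images
            through segmentation and quantification; segmented nuclei
            inherit cell-type labels from the nearest ground-truth
            centroid (manual annotation is out of scope).
cell_table  ingest a user CSV in the shared schema; segmentation and
            quantification are skipped.
images      segment and quantify a user TIFF; downstream stages need
            cell-type labels and are skipped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from furrow import io as fio
from furrow.core import DIFFERENTIATING_TYPES, DiscSample
from furrow.dynamics import (
    FitError,
    bootstrap_half_life,
    compare_decay_models,
    fit_decay,
    fit_hill,
    moving_average,
)
from furrow.noise import cv_profile, detrended_fluctuation_profile, spike_summary
from furrow.quantify import measure_nucleus
from furrow.segmentation import SegParams, segment_image
from furrow.spatial import loess_detrend, nearest_r8_distance, windowed_correlation
from furrow.synthetic import SyntheticConfig, generate_disc, render_image
from furrow.timeline import align_samples, calibrate_furrow, position_to_time

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "quantify", "timeline", "dynamics", "noise", "spatialcorr")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    mode: str = "synthetic"  # synthetic | cell_table | images
    seed: int = 0
    outdir: str = "furrow_run"
    input_path: Optional[str] = None
    n_discs: int = 4
    synthetic: Dict = field(default_factory=dict)  # SyntheticConfig overrides
    seg: Dict = field(default_factory=dict)  # SegParams overrides
    psf_sigma: float = 1.0
    background: float = 2.0
    progenitor_window: int = 130
    differentiating_window: int = 40
    smooth_window: int = 20
    noise_progenitor_window: int = 280
    noise_differentiating_window: int = 70
    noise_method: str = "both"  # cv | df | both
    n_boot: int = 1000
    boot_fraction: float = 0.7
    corr_span: float = 0.5
    corr_window_hr: float = 12.5
    corr_step_hr: float = 1.0
    match_radius_px: float = 5.0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "cell_table", "images"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("cell_table", "images") and not self.input_path:
            raise ValueError(f"mode {self.mode!r} requires input_path")
        if not 0 < self.boot_fraction <= 1:
            raise ValueError("boot_fraction must lie in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def seg_params(self) -> SegParams:
        base = dataclasses.asdict(SegParams.pipeline_defaults())
        base.update(self.seg)
        return SegParams(**base)


def _match_to_truth(
    objects, measured: pd.DataFrame, truth_cells: pd.DataFrame, radius: float
) -> pd.DataFrame:
    """Label segmented nuclei with the cell type of the nearest planted cell."""
    from scipy.spatial import cKDTree

    tree = cKDTree(truth_cells[["x_px", "y_px"]].to_numpy(dtype=float))
    d, idx = tree.query(measured[["x_px", "y_px"]].to_numpy(dtype=float))
    keep = d <= radius
    out = measured.loc[keep].copy()
    out["cell_type"] = truth_cells["cell_type"].to_numpy()[idx[keep]]
    # one measured nucleus per planted cell: keep the closest match
    out["_match"] = idx[keep]
    out["_dist"] = d[keep]
    out = out.sort_values("_dist").drop_duplicates("_match").drop(
        columns=["_match", "_dist"]
    )
    return out.sort_values("cell_id").reset_index(drop=True)


def _quantify_objects(objects, image, disc_id: str) -> pd.DataFrame:
    rows = []
    for obj in objects:
        yfp, rfp, size = measure_nucleus(obj, image[1], image[0])
        x, y = obj.centroid
        rows.append(
            dict(
                disc_id=disc_id,
                cell_id=obj.label,
                x_px=x,
                y_px=y,
                section=0,
                cell_type="progenitor",  # placeholder until labelled
                yfp_mean=yfp,
                rfp_mean=rfp,
                nuclear_size_px=size,
            )
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["normalized_level"] = df["yfp_mean"] / df["rfp_mean"]
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {s: {"status": "pending"} for s in STAGES},
    }
    current = "simulate"
    try:
        samples, truths = [], []
        t0 = time.perf_counter()

        # ---- simulate / ingest ----------------------------------------
        if config.mode == "synthetic":
            for d in range(config.n_discs):
                sc = SyntheticConfig(
                    **{**config.synthetic, "seed": config.seed * 1000 + d}
                )
                sample, truth = generate_disc(sc, disc_id=f"disc_{d}")
                samples.append(sample)
                truths.append(truth)
                fio.write_cell_table(sample, out / f"disc_{d}_truth_cells.csv")
                truth.table.to_csv(out / f"disc_{d}_ground_truth.csv", index=False)
            manifest["stages"]["simulate"] = {
                "status": "complete",
                "n_discs": len(samples),
                "n_cells": int(sum(len(s) for s in samples)),
            }
        elif config.mode == "cell_table":
            sample = fio.read_cell_table(config.input_path)
            for disc_id, group in sample.cells.groupby("disc_id"):
                samples.append(
                    DiscSample(disc_id=str(disc_id), cells=group.reset_index(drop=True))
                )
            manifest["stages"]["simulate"] = {
                "status": "complete",
                "ingested": str(config.input_path),
                "n_discs": len(samples),
                "n_cells": int(sum(len(s) for s in samples)),
            }
        else:  # images
            manifest["stages"]["simulate"] = {"status": "skipped"}
        logger.info("simulate: %.2fs", time.perf_counter() - t0)

        # ---- segment + quantify ---------------------------------------
        current = "segment"
        params = config.seg_params()
        if config.mode == "cell_table":
            manifest["stages"]["segment"] = {"status": "skipped"}
            manifest["stages"]["quantify"] = {"status": "skipped"}
        else:
            seg_counts, measured_samples = [], []
            image_sets = []
            if config.mode == "synthetic":
                for d, sample in enumerate(samples):
                    img, mask, origin = render_image(
                        sample,
                        psf_sigma=config.psf_sigma,
                        background=config.background,
                        seed=config.seed * 1000 + 500 + d,
                        return_origin=True,
                    )
                    fio.write_image(img, out / f"disc_{d}_stack.tif")
                    fio.write_mask(mask, out / f"disc_{d}_truth_mask.tif")
                    image_sets.append((sample.disc_id, img, sample, origin))
            else:
                img = fio.read_image(config.input_path)
                if img.ndim != 3 or img.shape[0] != 2:
                    raise ValueError("images mode expects a 2-channel TIFF stack")
                image_sets.append(("disc_0", img, None, (0.0, 0.0)))
            for d, (disc_id, img, src, origin) in enumerate(image_sets):
                objects = segment_image(img[0], params)
                seg_counts.append(len(objects))
                obj_df = pd.DataFrame(
                    [
                        dict(
                            label=o.label,
                            section=0,
                            x_px=o.centroid[0],
                            y_px=o.centroid[1],
                            area_px=o.area,
                        )
                        for o in objects
                    ]
                )
                obj_df.to_csv(out / f"disc_{d}_objects.csv", index=False)
                measured = _quantify_objects(objects, img, disc_id)
                if len(measured):
                    # back to disc-frame coordinates for truth matching
                    measured["x_px"] = measured["x_px"] + origin[0]
                    measured["y_px"] = measured["y_px"] + origin[1]
                measured_samples.append((d, objects, measured, src))
            manifest["stages"]["segment"] = {
                "status": "complete",
                "objects_per_disc": seg_counts,
                "params": dataclasses.asdict(params),
            }

            current = "quantify"
            new_samples = []
            matched_counts = []
            for d, objects, measured, src in measured_samples:
                if src is not None:  # synthetic: inherit labels from truth
                    measured = _match_to_truth(
                        objects, measured, src.cells, config.match_radius_px
                    )
                matched_counts.append(len(measured))
                fio.write_cell_table(measured, out / f"disc_{d}_cells.csv")
                new_samples.append(
                    DiscSample(disc_id=f"disc_{d}", cells=measured)
                )
            manifest["stages"]["quantify"] = {
                "status": "complete",
                "cells_per_disc": matched_counts,
            }
            if config.mode == "images":
                # no cell-type labels without annotation: downstream skipped
                for s in ("timeline", "dynamics", "noise", "spatialcorr"):
                    manifest["stages"][s] = {
                        "status": "skipped",
                        "reason": "no cell-type labels in images mode",
                    }
                _write_manifest(manifest, out)
                return manifest
            samples = new_samples

        # ---- timeline --------------------------------------------------
        current = "timeline"
        calibs = []
        for sample in samples:
            cal = calibrate_furrow(sample.r8_positions)
            sample.calibration = cal
            df = sample.cells.copy()
            df["time_hr"] = position_to_time(df["x_px"].to_numpy(dtype=float), cal)
            sample.cells = df
            calibs.append(cal)
        offsets = align_samples(samples) if len(samples) > 1 else [0.0]
        for sample, off in zip(samples, offsets):
            sample.cells["time_hr"] = sample.cells["time_hr"] + off
        fio.write_json(
            {
                "per_disc": [
                    dict(
                        disc_id=s.disc_id,
                        mu_px=c.mu_px,
                        x_c1_px=c.x_c1_px,
                        hours_per_column=c.hours_per_column,
                        offset_hr=o,
                    )
                    for s, c, o in zip(samples, calibs, offsets)
                ],
                "alignment_anchor": "hill_midpoint_k",
            },
            out / "calibration.json",
        )
        pooled = pd.concat([s.cells for s in samples], ignore_index=True)
        fio.write_cell_table(pooled, out / "cells_timed.csv")
        manifest["stages"]["timeline"] = {
            "status": "complete",
            "mu_px": [c.mu_px for c in calibs],
            "offsets_hr": offsets,
        }

        # ---- dynamics --------------------------------------------------
        current = "dynamics"
        fits: dict = {}
        prof_rows = []
        prog = pooled[pooled["cell_type"] == "progenitor"].sort_values("time_hr")
        tp = prog["time_hr"].to_numpy(dtype=float)
        yp = prog["normalized_level"].to_numpy(dtype=float)
        w = min(config.progenitor_window, max(5, len(tp) // 2))
        sm = min(config.smooth_window, max(1, len(tp) // 4))
        profile = moving_average(tp, yp, w, sm, cell_type="progenitor")
        for ti, vi in zip(profile.times, profile.values):
            prof_rows.append(
                dict(cell_type="progenitor", time_hr=ti, mean_level=vi, n_cells=w)
            )
        t_peak = float(profile.times[int(np.argmax(profile.values))])
        rise = tp <= t_peak
        fall = tp >= t_peak
        hill = fit_hill(tp[rise], yp[rise])
        decay = fit_decay(tp[fall] - t_peak, yp[fall])
        boot = bootstrap_half_life(
            tp[fall] - t_peak,
            yp[fall],
            n_boot=config.n_boot,
            fraction=config.boot_fraction,
            seed=config.seed * 1000 + 77,
        )
        fits["progenitor"] = {
            "hill": dict(a=hill.a, b=hill.b, k=hill.k, n=hill.n, cost=hill.cost),
            "decay": dict(
                A=decay.A,
                B=decay.B,
                tau=decay.tau,
                half_life_hr=decay.half_life_hr,
                cost=decay.cost,
                t_peak_hr=t_peak,
            ),
            "bootstrap": dict(
                half_life_mean=boot.half_life_mean,
                half_life_interval=list(boot.half_life_interval),
                tau_interval=list(boot.tau_interval),
                n_boot=boot.n_boot,
                fraction=boot.fraction,
                interval_method="m_out_of_n_scaled_percentile",
            ),
            "decay_model_comparison": compare_decay_models(
                tp[fall] - t_peak, yp[fall]
            ),
        }
        prog_fits = {"hill": hill, "decay": decay, "t_peak": t_peak}
        diff_fits = {}
        for ct in DIFFERENTIATING_TYPES:
            sub = pooled[pooled["cell_type"] == ct].sort_values("time_hr")
            if len(sub) < 30 or np.ptp(sub["time_hr"].to_numpy()) < 4.0:
                fits[ct] = {"status": "skipped", "n_cells": int(len(sub))}
                continue
            tt = sub["time_hr"].to_numpy(dtype=float)
            yy = sub["normalized_level"].to_numpy(dtype=float)
            wd = min(config.differentiating_window, max(5, len(tt) // 2))
            smd = min(config.smooth_window, max(1, len(tt) // 4))
            pr = moving_average(tt, yy, wd, smd, cell_type=ct)
            for ti, vi in zip(pr.times, pr.values):
                prof_rows.append(
                    dict(cell_type=ct, time_hr=ti, mean_level=vi, n_cells=wd)
                )
            t0ct = float(tt.min())
            dfit = fit_decay(tt - t0ct, yy)
            dboot = bootstrap_half_life(
                tt - t0ct,
                yy,
                n_boot=config.n_boot,
                fraction=config.boot_fraction,
                seed=config.seed * 1000 + 100 + DIFFERENTIATING_TYPES.index(ct),
            )
            fits[ct] = {
                "decay": dict(
                    A=dfit.A,
                    B=dfit.B,
                    tau=dfit.tau,
                    half_life_hr=dfit.half_life_hr,
                    cost=dfit.cost,
                    t_onset_hr=t0ct,
                ),
                "bootstrap": dict(
                    half_life_mean=dboot.half_life_mean,
                    half_life_interval=list(dboot.half_life_interval),
                    tau_interval=list(dboot.tau_interval),
                    n_boot=dboot.n_boot,
                    fraction=dboot.fraction,
                    interval_method="m_out_of_n_scaled_percentile",
                ),
            }
            diff_fits[ct] = {"decay": dfit, "t0": t0ct}
        pd.DataFrame(prof_rows).to_csv(out / "profiles.csv", index=False)
        fio.write_json(fits, out / "fits.json")
        manifest["stages"]["dynamics"] = {
            "status": "complete",
            "fitted_types": sorted(k for k, v in fits.items() if "decay" in v),
        }

        # ---- noise -----------------------------------------------------
        current = "noise"
        noise_rows = []
        spikes: dict = {}

        def prog_trend(t):
            t = np.asarray(t, dtype=float)
            return np.where(
                t <= t_peak, prog_fits["hill"](t), prog_fits["decay"](t - t_peak)
            )

        groups = [("progenitor", tp, yp, config.noise_progenitor_window, prog_trend)]
        for ct, info in diff_fits.items():
            sub = pooled[pooled["cell_type"] == ct].sort_values("time_hr")
            groups.append(
                (
                    ct,
                    sub["time_hr"].to_numpy(dtype=float),
                    sub["normalized_level"].to_numpy(dtype=float),
                    config.noise_differentiating_window,
                    (lambda t, i=info: i["decay"](np.asarray(t, dtype=float) - i["t0"])),
                )
            )
        for ct, tt, yy, wn, trend in groups:
            if len(tt) < wn + 1:
                logger.warning("noise: %s has %d cells < window %d; skipped", ct, len(tt), wn)
                spikes[ct] = {"status": "skipped", "n_cells": int(len(tt))}
                continue
            made = []
            if config.noise_method in ("cv", "both"):
                made.append(cv_profile(tt, yy, wn, cell_type=ct))
            if config.noise_method in ("df", "both"):
                made.append(
                    detrended_fluctuation_profile(tt, yy, trend, wn, cell_type=ct)
                )
            spikes[ct] = {}
            for npf in made:
                for ti, vi in zip(npf.times, npf.values):
                    noise_rows.append(
                        dict(
                            cell_type=ct,
                            time_hr=ti,
                            noise_value=vi,
                            n_cells=wn,
                            method=npf.method,
                        )
                    )
                if len(npf.values) >= 10:
                    primary, _ranked = spike_summary(npf)
                    spikes[ct][npf.method] = (
                        None
                        if primary is None
                        else dict(
                            peak_time_hr=primary.peak_time_hr,
                            peak_value=primary.peak_value,
                            width_hr=primary.width_hr,
                        )
                    )
        pd.DataFrame(noise_rows).to_csv(out / "noise_profiles.csv", index=False)
        fio.write_json(spikes, out / "noise_spikes.json")
        manifest["stages"]["noise"] = {
            "status": "complete",
            "profiled_types": sorted(k for k, v in spikes.items() if "status" not in v),
        }

        # ---- spatial correlation --------------------------------------
        current = "spatialcorr"
        resid_all, dist_all, time_all = [], [], []
        for sample in samples:
            r25 = sample.of_type("R2R5").sort_values("time_hr")
            if len(r25) < 10:
                continue
            lv = r25["normalized_level"].to_numpy(dtype=float)
            tt = r25["time_hr"].to_numpy(dtype=float)
            resid = loess_detrend(tt, levels=lv, span=config.corr_span)
            d = nearest_r8_distance(
                r25[["x_px", "y_px"]].to_numpy(dtype=float), sample.r8_positions
            )
            resid_all.append(resid)
            dist_all.append(d)
            time_all.append(tt)
        if resid_all:
            windows = windowed_correlation(
                np.concatenate(resid_all),
                np.concatenate(dist_all),
                np.concatenate(time_all),
                window_span_hr=config.corr_window_hr,
                step_hr=config.corr_step_hr,
            )
            corr_df = pd.DataFrame(
                [
                    dict(
                        center_time_hr=wd.center_time_hr,
                        r=wd.r,
                        p_value=wd.p_value,
                        explained_variance=wd.explained_variance,
                        n_cells=wd.n_cells,
                    )
                    for wd in windows
                ]
            )
            with open(out / "spatial_correlation.csv", "w") as fh:
                fh.write(
                    "# per-window p-values; no multiple-testing correction "
                    "applied across windows\n"
                )
                corr_df.to_csv(fh, index=False)
            manifest["stages"]["spatialcorr"] = {
                "status": "complete",
                "n_windows": int(len(corr_df)),
            }
        else:
            manifest["stages"]["spatialcorr"] = {
                "status": "skipped",
                "reason": "too few R2/R5 cells",
            }
        _write_manifest(manifest, out)
        return manifest
    except Exception as e:
        manifest["stages"][current]["status"] = "failed"
        manifest["stages"][current]["error"] = str(e)
        _write_manifest(manifest, out)
        raise RuntimeError(f"pipeline stage {current!r} failed: {e}") from e


def _write_manifest(manifest: dict, out: Path) -> None:
    import furrow

    manifest["version"] = furrow.__version__
    fio.write_json(manifest, out / "manifest.json")
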