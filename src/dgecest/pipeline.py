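"""The two end-to-end pipelines.

Static glucoCEST: motion correction (reference = the 6-ppm frame) ->
normalization by S0 -> per-voxel B0 shift mapping -> B0 correction of the
spectra -> two-pool amplitude fitting -> baseline-minus-post glucoCEST maps
at 1.2 and 2 ppm.

Dynamic DGE: motion correction (reference = the second saturation frame) ->
normalization by S0 -> interleave splitting -> dynamic B0 correction from
the two static B0 maps -> temporal PCA denoising -> DGE(t) and time-block
means.  The correction stages are individually switchable so that
none / motion-only / fully corrected outputs can be compared.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamic as dyn
from . import io as dio
from . import motion as mo
from . import roi as roi_mod
from . import zspec as zs

logger = logging.getLogger(__name__)

GLUCOCEST_OFFSETS_PPM = (1.2, 2.0)
STATIC_MOCO_REFERENCE_OFFSET_PPM = 6.0
DYNAMIC_MOCO_REFERENCE_FRAME = 1  # the second saturation frame


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage {stage!r} failed: {error}")
        self.stage = stage
        self.error = error


def _stage(name: str, fn, *args, **kwargs):
    t0 = time.time()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
        raise PipelineError(name, exc) from exc
    logger.info("stage %-18s %.2f s", name, time.time() - t0)
    return out


# ---------------------------------------------------------------------------
# static

def static_pipeline(baseline_frames: np.ndarray, post_frames: np.ndarray,
                    schedule: zs.OffsetSchedule, motion: bool = True,
                    grid_resolution_ppm: float | None = None,
                    solute_pool: bool = True,
                    mask: np.ndarray | None = None) -> dict:
    """Run the full static glucoCEST analysis on two raw series.

    Returns a dict with the motion logs, normalized and B0-corrected
    spectrum volumes, B0 maps, two-pool amplitude maps and the glucoCEST
    maps (fractions of S0) at 1.2 and 2 ppm.
    """
    result = {"schedule": schedule}
    scans = {"baseline": np.asarray(baseline_frames, float),
             "post": np.asarray(post_frames, float)}
    if motion:
        offs = np.array([o for o, _ in schedule.entries])
        ref_cand = np.nonzero(~schedule.is_reference
                              & np.isclose(offs,
                                           STATIC_MOCO_REFERENCE_OFFSET_PPM)
                              )[0]
        ref_idx = int(ref_cand[0]) if ref_cand.size else int(
            np.nonzero(~schedule.is_reference)[0][0])
        for name in scans:
            scans[name], log = _stage(f"mocorr_{name}", mo.mocorr_series,
                                      scans[name], ref_idx)
            result[f"mocorr_log_{name}"] = log
    for name in scans:
        result[f"z_{name}"] = _stage(f"normalize_{name}", zs.normalize,
                                     scans[name], schedule)
        result[f"b0_{name}"] = _stage(
            f"fit_b0_{name}", zs.fit_b0_map, result[f"z_{name}"],
            grid_resolution_ppm=grid_resolution_ppm,
            solute_pool=solute_pool, mask=mask)
        result[f"z_{name}_corr"] = _stage(
            f"b0_correct_{name}", zs.correct_zspectrum_b0,
            result[f"z_{name}"], result[f"b0_{name}"])
        result[f"pools_{name}"] = _stage(
            f"two_pool_{name}", zs.fit_two_pool, result[f"z_{name}_corr"],
            mask=mask)
    for off in GLUCOCEST_OFFSETS_PPM:
        key = f"glucocest_{off}".replace(".", "p")
        result[key] = _stage(f"glucocest_{off}", zs.compute_glucocest,
                             result["z_baseline_corr"],
                             result["z_post_corr"], off)
    return result


# ---------------------------------------------------------------------------
# dynamic

def dynamic_pipeline(series: dyn.DynamicSeries,
                     b0_baseline: zs.B0Map | None = None,
                     b0_post: zs.B0Map | None = None,
                     infusion_start_s: float = 180.0,
                     motion: bool = True, dynamic_b0: bool = True,
                     pca: bool = True, pca_components: int = 3,
                     pca_joint: bool = False,
                     blocks: list | None = None,
                     t_baseline_s: float | None = None,
                     t_post_s: float | None = None,
                     mask: np.ndarray | None = None) -> dict:
    """Run the dynamic DGE analysis on one raw interleaved series.

    ``b0_baseline`` / ``b0_post`` are the static B0 maps bracketing the
    dynamic scan (required when ``dynamic_b0``); ``t_baseline_s`` /
    ``t_post_s`` place them on the dynamic clock.  Returns per-offset
    DGE results keyed ``dge_<offset>`` plus intermediates.
    """
    result = {}
    if motion:
        corrected, log = _stage("mocorr", mo.mocorr_series, series.frames,
                                DYNAMIC_MOCO_REFERENCE_FRAME)
        series = dyn.DynamicSeries(corrected, series.offsets_ppm,
                                   series.times_s, series.s0,
                                   series.normalized)
        result["mocorr_log"] = log
    series = _stage("normalize", dyn.normalize_dynamic, series)
    low, high = _stage("split", dyn.split_interleaved, series)
    if dynamic_b0:
        if b0_baseline is None or b0_post is None:
            raise PipelineError("dynamic_b0", ValueError(
                "dynamic B0 correction requires both static B0 maps"))
        ptimes = dyn.pair_times(low, high)
        b0_series = _stage("interp_b0", dyn.interpolate_b0_series,
                           b0_baseline, b0_post, ptimes, t_baseline_s,
                           t_post_s)
        result["b0_series"] = b0_series
        low, high = _stage("dynamic_b0", dyn.dynamic_b0_correct, low, high,
                           b0_series)
    if pca:
        if pca_joint:
            # joint mode: denoise the voxel x (2T) matrix of both series
            T = low.n_frames
            X = np.concatenate([low.frames, high.frames], axis=-1)
            joint = dyn.DynamicSeries(X, np.concatenate(
                [low.offsets_ppm, high.offsets_ppm]),
                np.arange(2 * T, dtype=float), series.s0, normalized=True)
            joint_dn, cumvar = _stage("pca", dyn.pca_denoise, joint,
                                      pca_components, mask)
            low = dyn.DynamicSeries(joint_dn.frames[..., :T],
                                    low.offsets_ppm, low.times_s,
                                    series.s0, True)
            high = dyn.DynamicSeries(joint_dn.frames[..., T:],
                                     high.offsets_ppm, high.times_s,
                                     series.s0, True)
            result["pca_cumvar"] = {"joint": cumvar}
        else:
            low, cv_low = _stage("pca_low", dyn.pca_denoise, low,
                                 pca_components, mask)
            high, cv_high = _stage("pca_high", dyn.pca_denoise, high,
                                   pca_components, mask)
            result["pca_cumvar"] = {float(low.offsets_ppm[0]): cv_low,
                                    float(high.offsets_ppm[0]): cv_high}
    for s in (low, high):
        off = float(s.offsets_ppm[0])
        key = f"dge_{off}".replace(".", "p")
        result[key] = _stage(f"dge_{off}", dyn.compute_dge, s,
                             infusion_start_s, blocks)
        result[f"series_{off}".replace(".", "p")] = s
    return result


# ---------------------------------------------------------------------------
# file-level orchestration

def _setup_run_dir(config: dio.PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.yaml")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s "
                                           "%(levelname)s %(message)s"))
    logging.getLogger("dgecest").addHandler(handler)
    logging.getLogger("dgecest").setLevel(logging.INFO)
    return out


def _finish_run_dir(out: Path, files: list):
    manifest = {"files": sorted(str(Path(f).relative_to(out))
                                for f in files)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    root = logging.getLogger("dgecest")
    for h in list(root.handlers):
        if isinstance(h, logging.FileHandler) and \
                Path(h.baseFilename) == (out / "run.log").resolve():
            h.close()
            root.removeHandler(h)


def _load_masks(masks_path) -> list:
    labels, _ = dio.read_nifti(masks_path)
    labels = np.asarray(labels)
    from .phantom import LABEL_NAMES
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        out.append(roi_mod.ROIMask(LABEL_NAMES.get(int(lab), str(int(lab))),
                                   labels == lab))
    return out


def run_static_pipeline(config: dio.PipelineConfig) -> dict:
    """File-level static run: read inputs, run, write maps + reports."""
    config.resolve_paths()
    out = _setup_run_dir(config)
    files = [out / "config.yaml", out / "run.log"]
    try:
        base_frames, schedule, _ = _stage(
            "read", dio.load_static_scan, config.baseline,
            str(config.baseline).replace(".nii.gz", ".json"))
        post_frames, _, _ = dio.load_static_scan(
            config.post, str(config.post).replace(".nii.gz", ".json"))
        res = static_pipeline(base_frames, post_frames, schedule,
                              motion=config.motion,
                              grid_resolution_ppm=config.grid_resolution_ppm)
        for name in ("baseline", "post"):
            files.append(dio.save_b0_map(out / f"b0_{name}.nii.gz",
                                         res[f"b0_{name}"]))
            files.append(Path(str(out / f"b0_{name}.json")))
            for k in ("ds_amplitude", "mt_amplitude", "ds_fwhm", "mt_fwhm"):
                files.append(dio.write_nifti(
                    out / f"{k}_{name}.nii.gz", res[f"pools_{name}"][k]))
        maps = {}
        for off in GLUCOCEST_OFFSETS_PPM:
            key = f"glucocest_{off}".replace(".", "p")
            files.append(dio.write_nifti(out / f"{key}.nii.gz", res[key]))
            maps[f"glucoCEST@{off}ppm[%]"] = res[key] * 100.0
        if config.masks:
            table = roi_mod.roi_table(maps, _load_masks(config.masks))
            table.to_csv(out / "roi_report.csv", index=False)
            files.append(out / "roi_report.csv")
        res["out_dir"] = out
        return res
    finally:
        _finish_run_dir(out, files)


def run_dynamic_pipeline(config: dio.PipelineConfig) -> dict:
    """File-level dynamic run; with ``compare_corrections`` both the fully
    corrected and the motion-only outputs are written."""
    config.resolve_paths()
    out = _setup_run_dir(config)
    files = [out / "config.yaml", out / "run.log"]
    try:
        series, refs, side = _stage(
            "read", dio.load_dynamic_scan, config.series,
            str(config.series).replace(".nii.gz", ".json"))
        infusion = (side.get("infusion_start_s", 180.0)
                    if config.infusion_start_s is None
                    else config.infusion_start_s)
        b0a = dio.load_b0_map(config.b0_baseline) if config.b0_baseline \
            else None
        b0b = dio.load_b0_map(config.b0_post) if config.b0_post else None
        variants = {"full": dict(motion=config.motion,
                                 dynamic_b0=config.dynamic_b0,
                                 pca=config.pca)}
        if config.compare_corrections:
            variants["motion_only"] = dict(motion=config.motion,
                                           dynamic_b0=False, pca=False)
        results = {}
        masks = _load_masks(config.masks) if config.masks else []
        for vname, flags in variants.items():
            res = dynamic_pipeline(
                series, b0a, b0b, infusion_start_s=infusion,
                pca_components=config.pca_components,
                pca_joint=config.pca_joint,
                t_baseline_s=config.t_baseline_s, t_post_s=config.t_post_s,
                **flags)
            prefix = "" if vname == "full" else f"{vname}_"
            for key, r in list(res.items()):
                if not key.startswith("dge_"):
                    continue
                files.append(dio.write_nifti(
                    out / f"{prefix}{key}_t.nii.gz", r.dge_t))
                for b, bmap in r.block_means.items():
                    files.append(dio.write_nifti(
                        out / f"{prefix}{key}_block{b}.nii.gz", bmap))
                if masks:
                    rows = []
                    for m in masks:
                        mean, sd, _ = roi_mod.roi_mean(r.dge_t, m)
                        for t, mu, s in zip(r.times_s, mean, sd):
                            rows.append((m.name, r.offset_ppm, t,
                                         100 * mu, 100 * s))
                    pd.DataFrame(rows, columns=[
                        "roi", "offset_ppm", "time_s", "dge_pct",
                        "sd_pct"]).to_csv(
                        out / f"{prefix}{key}_roi_timecourses.csv",
                        index=False)
                    files.append(out / f"{prefix}{key}_roi_timecourses.csv")
            if "pca_cumvar" in res:
                rows = [(str(k), i + 1, float(v))
                        for k, cv in res["pca_cumvar"].items()
                        for i, v in enumerate(cv)]
                pd.DataFrame(rows, columns=[
                    "series", "component", "cumulative_variance"]).to_csv(
                    out / f"{prefix}explained_variance.csv", index=False)
                files.append(out / f"{prefix}explained_variance.csv")
            results[vname] = res
        results["out_dir"] = out
        return results
    finally:
        _finish_run_dir(out, files)
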