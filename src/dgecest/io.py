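"""File formats and configuration.

Volumes travel as NIfTI (the affine is preserved untouched through all
stages); CEST-specific metadata that NIfTI has no fields for — per-frame
saturation offsets, acquisition times, reference-frame flags, infusion
start — lives in a JSON sidecar next to each image.  Simulator ground truth
is serialized alongside so tests can compare pipeline output against it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .dynamic import DynamicSeries
from .phantom import GlucoseKinetics, PhantomTruth
from .zspec import B0Map, LorentzianPool, OffsetSchedule


def write_nifti(path, data, affine=None, dtype=np.float64):
    img = nib.Nifti1Image(np.asarray(data).astype(dtype),
                          np.eye(4) if affine is None else affine)
    nib.save(img, str(path))
    return Path(path)


def read_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def _require(sidecar: dict, key: str, path):
    if key not in sidecar:
        raise ValueError(f"missing sidecar key {key!r} in {path}")
    return sidecar[key]


# ---------------------------------------------------------------------------
# static scans

def save_static_scan(base_path, frames: np.ndarray, meta: dict,
                     affine=None) -> tuple[Path, Path]:
    """Write a static series as ``<base>.nii.gz`` + ``<base>.json``."""
    base = Path(base_path)
    nii = write_nifti(base.with_suffix(".nii.gz"), frames, affine)
    side = dict(meta)
    side.setdefault("kind", "static")
    jpath = base.with_suffix(".json")
    jpath.write_text(json.dumps(side, indent=1, default=_jsonify))
    return nii, jpath


def load_static_scan(nifti_path, sidecar_path
                     ) -> tuple[np.ndarray, OffsetSchedule, dict]:
    """Read a static series; validates frame count and sidecar keys."""
    frames, _ = read_nifti(nifti_path)
    side = json.loads(Path(sidecar_path).read_text())
    sched_dict = _require(side, "schedule", sidecar_path)
    _require(sched_dict, "offsets_ppm", sidecar_path)
    _require(sched_dict, "is_reference", sidecar_path)
    schedule = OffsetSchedule.from_dict(sched_dict)
    if frames.shape[-1] != len(schedule):
        raise ValueError(
            f"length mismatch: {frames.shape[-1]} frames vs "
            f"{len(schedule)} sidecar entries")
    return np.asarray(frames, float), schedule, side


# ---------------------------------------------------------------------------
# dynamic scans

def save_dynamic_scan(base_path, series: DynamicSeries, refs: np.ndarray,
                      meta: dict | None = None, affine=None
                      ) -> tuple[Path, Path]:
    """Write a dynamic series (leading reference frames first) plus its
    sidecar."""
    base = Path(base_path)
    n_ref = refs.shape[-1]
    dur = float(np.median(np.diff(series.times_s))) if series.n_frames > 1 \
        else 7.2
    all_frames = np.concatenate([refs, series.frames], axis=-1)
    nii = write_nifti(base.with_suffix(".nii.gz"), all_frames, affine)
    ref_times = series.times_s[0] - dur * np.arange(n_ref, 0, -1)
    side = dict(meta or {})
    side.update({
        "kind": "dynamic",
        "offsets_ppm": [300.0] * n_ref + series.offsets_ppm.tolist(),
        "is_reference": [True] * n_ref + [False] * series.n_frames,
        "frame_time_s": ref_times.tolist() + series.times_s.tolist(),
        "normalized": bool(series.normalized),
    })
    jpath = base.with_suffix(".json")
    jpath.write_text(json.dumps(side, indent=1, default=_jsonify))
    return nii, jpath


def load_dynamic_scan(nifti_path, sidecar_path
                      ) -> tuple[DynamicSeries, np.ndarray, dict]:
    """Read a dynamic series; returns (series, reference frames, sidecar)."""
    frames, _ = read_nifti(nifti_path)
    side = json.loads(Path(sidecar_path).read_text())
    offs = np.asarray(_require(side, "offsets_ppm", sidecar_path), float)
    isref = np.asarray(_require(side, "is_reference", sidecar_path), bool)
    times = np.asarray(_require(side, "frame_time_s", sidecar_path), float)
    if frames.shape[-1] != offs.size:
        raise ValueError(
            f"length mismatch: {frames.shape[-1]} frames vs "
            f"{offs.size} sidecar entries")
    if np.any(np.diff(times) <= 0):
        raise ValueError("non-monotonic frame times in sidecar")
    frames = np.asarray(frames, float)
    refs = frames[..., isref]
    if refs.shape[-1] == 0:
        raise ValueError("dynamic sidecar has no reference frames")
    series = DynamicSeries(frames[..., ~isref], offs[~isref], times[~isref],
                           s0=refs[..., -1],
                           normalized=bool(side.get("normalized", False)))
    return series, refs, side


# ---------------------------------------------------------------------------
# ground truth

def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def save_truth(out_dir, truth: PhantomTruth) -> Path:
    """Serialize a phantom ground truth: scalars/pools to ``truth.json``,
    label map and B0 field as NIfTI."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_nifti(out / "truth_labels.nii.gz", truth.label_map,
                dtype=np.int16)
    write_nifti(out / "truth_b0.nii.gz", truth.b0_field)
    d = {
        "pool_params": {
            str(lab): [[p.amplitude, p.fwhm_ppm, p.center_ppm]
                       for p in pools]
            for lab, pools in truth.pool_params.items()},
        "glucose_sensitivity": {str(k): v for k, v in
                                truth.glucose_sensitivity.items()},
        "b0_drift_rate": truth.b0_drift_rate,
        "kinetics": {
            **{k: v for k, v in asdict(truth.kinetics).items()
               if not isinstance(v, dict)},
            "tissue_scale": {str(k): v for k, v in
                             truth.kinetics.tissue_scale.items()},
            "tissue_delay_s": {str(k): v for k, v in
                               truth.kinetics.tissue_delay_s.items()},
        },
        "noise_sigma": truth.noise_sigma,
        "motion_trace": (None if truth.motion_trace is None
                         else np.asarray(truth.motion_trace).tolist()),
        "seed": truth.seed,
        "s0_per_label": {str(k): v for k, v in truth.s0_per_label.items()},
        "max_concentration_mM": truth.max_concentration_mM,
    }
    path = out / "truth.json"
    path.write_text(json.dumps(d, indent=1, default=_jsonify))
    return path


def load_truth(truth_dir) -> PhantomTruth:
    d = json.loads((Path(truth_dir) / "truth.json").read_text())
    labels, _ = read_nifti(Path(truth_dir) / "truth_labels.nii.gz")
    b0, _ = read_nifti(Path(truth_dir) / "truth_b0.nii.gz")
    kin = d["kinetics"]
    kinetics = GlucoseKinetics(
        infusion_start_s=kin["infusion_start_s"],
        infusion_duration_s=kin["infusion_duration_s"],
        bolus_mM=kin["bolus_mM"], rise_lag_s=kin["rise_lag_s"],
        decay_halflife_s=kin["decay_halflife_s"],
        tissue_scale={int(k): v for k, v in kin["tissue_scale"].items()},
        tissue_delay_s={int(k): v for k, v in kin["tissue_delay_s"].items()})
    return PhantomTruth(
        label_map=np.asarray(labels).astype(np.int16),
        pool_params={int(k): tuple(LorentzianPool(*p) for p in v)
                     for k, v in d["pool_params"].items()},
        glucose_sensitivity={int(k): v for k, v in
                             d["glucose_sensitivity"].items()},
        b0_field=np.asarray(b0, float),
        b0_drift_rate=d["b0_drift_rate"], kinetics=kinetics,
        noise_sigma=d["noise_sigma"],
        motion_trace=(None if d["motion_trace"] is None
                      else np.asarray(d["motion_trace"], float)),
        seed=d["seed"],
        s0_per_label={int(k): v for k, v in d["s0_per_label"].items()},
        max_concentration_mM=d["max_concentration_mM"])


def save_b0_map(path, b0: B0Map, affine=None) -> Path:
    nii = write_nifti(path, b0.shift_ppm, affine)
    side = Path(str(path).replace(".nii.gz", "").replace(".nii", "")
                ).with_suffix(".json")
    side.write_text(json.dumps({
        "grid_resolution_ppm": b0.grid_resolution_ppm,
        "search_window_ppm": b0.search_window_ppm,
        "n_failed": int((~b0.converged).sum()),
    }, indent=1))
    return nii


def load_b0_map(path) -> B0Map:
    data, _ = read_nifti(path)
    side = Path(str(path).replace(".nii.gz", "").replace(".nii", "")
                ).with_suffix(".json")
    kw = {}
    if side.exists():
        d = json.loads(side.read_text())
        kw = {"grid_resolution_ppm": d.get("grid_resolution_ppm", 0.0078),
              "search_window_ppm": d.get("search_window_ppm", 1.0)}
    return B0Map(np.asarray(data, float), **kw)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Run configuration for the two pipelines.

    Paths are resolved before execution; the config is echoed verbatim into
    the output directory of every run.
    """

    out_dir: str = "."
    baseline: str | None = None
    post: str | None = None
    series: str | None = None
    b0_baseline: str | None = None
    b0_post: str | None = None
    masks: str | None = None
    protocol: str = "volunteer"
    grid_resolution_ppm: float = 0.0078
    pca_components: int = 3
    pca_joint: bool = False
    motion: bool = True
    dynamic_b0: bool = True
    pca: bool = True
    compare_corrections: bool = False
    infusion_start_s: float | None = None
    t_baseline_s: float | None = None
    t_post_s: float | None = None
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = (json.loads(text) if str(path).endswith(".json")
             else yaml.safe_load(text))
        return cls(**d)

    def to_file(self, path) -> Path:
        p = Path(path)
        if str(p).endswith(".json"):
            p.write_text(json.dumps(asdict(self), indent=1))
        else:
            p.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return p

    def resolve_paths(self):
        for name in ("baseline", "post", "series", "b0_baseline", "b0_post",
                     "masks"):
            v = getattr(self, name)
            if v is not None and not Path(v).exists():
                raise FileNotFoundError(f"config path {name} = {v!r} "
                                        "does not exist")
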