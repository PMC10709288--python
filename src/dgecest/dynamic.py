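"""Dynamic glucose-enhanced (DGE) analysis.

Interleave splitting of the two-offset dynamic series, linearly interpolated
dynamic B0 correction, temporal PCA denoising, per-time DGE computation and
time-block averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .zspec import B0Map

logger = logging.getLogger(__name__)

#: Default dynamic saturation offsets, ppm.
DYNAMIC_OFFSETS_PPM = (1.2, 2.0)


@dataclass
class DynamicSeries:
    """Image time series with per-frame offset labels.

    frames has shape ``spatial + (n_frames,)``; offsets_ppm and times_s are
    per-frame.  s0 is the reference image (last of the leading far
    off-resonance acquisitions); ``normalized`` records whether frames are
    already S/S0.
    """

    frames: np.ndarray
    offsets_ppm: np.ndarray
    times_s: np.ndarray
    s0: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.offsets_ppm = np.atleast_1d(
            np.asarray(self.offsets_ppm, dtype=float))
        self.times_s = np.atleast_1d(np.asarray(self.times_s, dtype=float))
        n = self.frames.shape[-1]
        if self.offsets_ppm.size != n or self.times_s.size != n:
            raise ValueError("per-frame offsets/times must match frame count")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[-1]

    @property
    def spatial_shape(self):
        return self.frames.shape[:-1]


@dataclass
class B0Series:
    """Per-pair B0 shift maps over the dynamic scan.

    shifts has shape ``spatial + (n_pairs,)``; times_s holds the pair times.
    """

    shifts: np.ndarray
    times_s: np.ndarray
    grid_resolution_ppm: float = 0.0078

    def __post_init__(self):
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.times_s = np.atleast_1d(np.asarray(self.times_s, dtype=float))
        if self.shifts.shape[-1] != self.times_s.size:
            raise ValueError("one map per pair time required")

    def __len__(self):
        return self.times_s.size


@dataclass(frozen=True)
class BlockDefinition:
    """One analysis time block, ``[start_s, end_s)`` relative to the start
    of the glucose infusion.  Block 1 is the pre-infusion baseline."""

    index: int
    start_s: float
    end_s: float

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ValueError("block end must exceed start")


def default_blocks() -> list[BlockDefinition]:
    """The four analysis windows: baseline, during infusion (0-3:20), and
    two post-infusion windows (3:20-6:40, 6:40-10:00 min:s)."""
    return [
        BlockDefinition(1, -np.inf, 0.0),
        BlockDefinition(2, 0.0, 200.0),
        BlockDefinition(3, 200.0, 400.0),
        BlockDefinition(4, 400.0, 600.0),
    ]


@dataclass
class DGEResult:
    """Per-time DGE maps plus their time-block means.

    dge_t has shape ``spatial + (n_frames,)`` (fraction of S0); block_means
    maps block index -> mean map over the frames in that block; baseline is
    the block-1 mean S/S0 map.
    """

    dge_t: np.ndarray
    times_s: np.ndarray
    block_means: dict
    baseline: np.ndarray
    offset_ppm: float | None = None
    block_counts: dict | None = None
    roi_timecourses: "object | None" = None


def normalize_dynamic(series: DynamicSeries,
                      s0: np.ndarray | None = None) -> DynamicSeries:
    """Divide all frames by the S0 reference image.

    Voxels with non-positive S0 become NaN (counted and logged).
    """
    if series.normalized:
        return series
    s0 = series.s0 if s0 is None else np.asarray(s0, dtype=float)
    if s0 is None:
        raise ValueError("no S0 image available for normalization")
    bad = ~(s0 > 0)
    if bad.any():
        logger.warning("normalize_dynamic: %d voxels with non-positive S0",
                       int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = series.frames / s0[..., None]
    z[bad] = np.nan
    return DynamicSeries(z, series.offsets_ppm, series.times_s, s0,
                         normalized=True)


def split_interleaved(series: DynamicSeries
                      ) -> tuple[DynamicSeries, DynamicSeries]:
    """Split a strictly alternating two-offset series into one series per
    offset, preserving original frame times.

    Raises if the labels do not alternate, listing the offending indices.
    """
    if not series.normalized:
        raise ValueError("split_interleaved expects a normalized series")
    labels = series.offsets_ppm
    if series.n_frames % 2:
        raise ValueError("interleaved series must have an even frame count")
    bad = np.nonzero(labels[1:] == labels[:-1])[0]
    if bad.size:
        raise ValueError(
            "offset labels do not alternate at frame indices "
            f"{(bad + 1).tolist()}")
    first, second = labels[0], labels[1]
    out = []
    for lab in (first, second):
        pick = labels == lab
        out.append(DynamicSeries(series.frames[..., pick], labels[pick],
                                 series.times_s[pick], series.s0,
                                 normalized=True))
    a, b = out
    if first <= second:
        return a, b
    return b, a


def interpolate_b0_series(b0_baseline: B0Map, b0_post: B0Map,
                          pair_times_s, t_baseline_s: float | None = None,
                          t_post_s: float | None = None) -> B0Series:
    """Voxel-wise linear interpolation between the baseline and
    post-infusion B0 maps, evaluated at each interleaved-pair time.

    ``t_baseline_s`` / ``t_post_s`` locate the two static maps on the
    dynamic-scan clock; they default to the first and last pair time.
    """
    pair_times = np.atleast_1d(np.asarray(pair_times_s, dtype=float))
    if b0_baseline.shift_ppm.shape != b0_post.shift_ppm.shape:
        raise ValueError("endpoint B0 maps must share a grid")
    t0 = float(pair_times[0]) if t_baseline_s is None else float(t_baseline_s)
    t1 = float(pair_times[-1]) if t_post_s is None else float(t_post_s)
    if t1 <= t0:
        raise ValueError("post-infusion map time must exceed baseline time")
    if pair_times.min() < t0 or pair_times.max() > t1:
        raise ValueError("pair times must lie within [t_baseline, t_post]")
    w = (pair_times - t0) / (t1 - t0)
    shifts = (b0_baseline.shift_ppm[..., None] * (1.0 - w)
              + b0_post.shift_ppm[..., None] * w)
    return B0Series(shifts, pair_times, b0_baseline.grid_resolution_ppm)


def dynamic_b0_correct_pair(z_low: np.ndarray, z_high: np.ndarray,
                            shift_ppm: np.ndarray,
                            offsets_ppm=DYNAMIC_OFFSETS_PPM
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Correct one interleaved pair of S/S0 maps for a B0 shift.

    The two measurements are treated as samples of the voxel's local
    Z-spectrum at true offsets ``(o1 - d, o2 - d)``; the unique line through
    them is evaluated at the nominal offsets ``o1, o2``, which for a locally
    linear spectrum restores the unshifted values exactly.
    """
    o1, o2 = offsets_ppm
    slope = (np.asarray(z_high, float) - np.asarray(z_low, float)) / (o2 - o1)
    d = np.asarray(shift_ppm, dtype=float)
    return z_low + slope * d, z_high + slope * d


def dynamic_b0_correct(series_low: DynamicSeries, series_high: DynamicSeries,
                       b0_series: B0Series
                       ) -> tuple[DynamicSeries, DynamicSeries]:
    """Apply the two-point dynamic B0 correction to both offset series.

    Pair ``k`` couples frame ``k`` of each series with B0 map ``k``.
    """
    if series_low.n_frames != series_high.n_frames:
        raise ValueError("offset series must have equal length")
    if len(b0_series) != series_low.n_frames:
        raise ValueError("need one B0 map per interleaved pair")
    zl = series_low.frames.copy()
    zh = series_high.frames.copy()
    for k in range(series_low.n_frames):
        zl[..., k], zh[..., k] = dynamic_b0_correct_pair(
            series_low.frames[..., k], series_high.frames[..., k],
            b0_series.shifts[..., k],
            (series_low.offsets_ppm[k], series_high.offsets_ppm[k]))
    return (replace(series_low, frames=zl),
            replace(series_high, frames=zh))


def pair_times(series_low: DynamicSeries,
               series_high: DynamicSeries) -> np.ndarray:
    """Representative time of each interleaved pair: the mean of its two
    frame times."""
    return (series_low.times_s + series_high.times_s) / 2.0


def pca_denoise(series: DynamicSeries, n_components: int = 3,
                mask: np.ndarray | None = None
                ) -> tuple[DynamicSeries, np.ndarray]:
    """Temporal PCA denoising of a dynamic series.

    In-mask voxel time courses are arranged as a voxels x time matrix, each
    voxel's temporal mean subtracted, and the matrix reconstructed from its
    first ``n_components`` right-singular (temporal) directions before the
    means are added back.  Out-of-mask voxels pass through unchanged.

    Returns the denoised series and the cumulative explained-variance
    fraction per component (full spectrum, so ``cumvar[n_components - 1]``
    is the fraction retained).
    """
    T = series.n_frames
    if not 1 <= n_components <= T:
        raise ValueError(
            f"n_components must be in [1, {T}], got {n_components}")
    zflat = series.frames.reshape(-1, T)
    if mask is None:
        rows = np.nonzero(np.isfinite(zflat).all(axis=1))[0]
    else:
        rows = np.nonzero(np.asarray(mask, bool).ravel()
                          & np.isfinite(zflat).all(axis=1))[0]
    out = series.frames.copy()
    X = zflat[rows]
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    power = s * s
    total = power.sum()
    if total == 0:
        cumvar = np.ones_like(power)
    else:
        cumvar = np.cumsum(power) / total
    k = n_components
    rec = (U[:, :k] * s[:k]) @ Vt[:k] + mean
    out.reshape(-1, T)[rows] = rec
    return replace(series, frames=out), cumvar


def compute_dge(series: DynamicSeries, infusion_start_s: float,
                blocks: list[BlockDefinition] | None = None) -> DGEResult:
    """Per-time DGE maps and block means from a normalized series.

    With frames already S/S0, ``DGE(t) = S_baseline - S(t)`` where
    S_baseline is the voxel-wise mean over the pre-infusion (block-1)
    frames.  Block means average the DGE frames whose times fall in each
    block's ``[start, end)`` window (relative to infusion start); frames
    beyond the last block are excluded and counted.
    """
    if not series.normalized:
        raise ValueError("compute_dge expects a normalized series")
    if blocks is None:
        blocks = default_blocks()
    blocks = sorted(blocks, key=lambda b: b.index)
    rel = series.times_s - infusion_start_s
    in_block = {b.index: (rel >= b.start_s) & (rel < b.end_s) for b in blocks}
    base_sel = in_block[blocks[0].index]
    if not base_sel.any():
        raise ValueError("no pre-infusion frames: baseline undefined")
    baseline = series.frames[..., base_sel].mean(axis=-1)
    dge_t = baseline[..., None] - series.frames
    block_means = {}
    counts = {}
    for b in blocks:
        sel = in_block[b.index]
        counts[b.index] = int(sel.sum())
        if sel.any():
            block_means[b.index] = dge_t[..., sel].mean(axis=-1)
    n_assigned = sum(counts.values())
    if n_assigned < series.n_frames:
        logger.info("compute_dge: %d frames beyond the defined blocks "
                    "excluded", series.n_frames - n_assigned)
    offset = (float(series.offsets_ppm[0])
              if np.unique(series.offsets_ppm).size == 1 else None)
    return DGEResult(dge_t, series.times_s, block_means, baseline, offset,
                     counts)
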