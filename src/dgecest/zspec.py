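"""Static Z-spectrum analysis.

Z-spectrum construction from a saturation-offset series, per-voxel B0 shift
mapping by Lorentzian fitting, B0-corrected spectra, two-pool amplitude
fitting, and static glucoCEST difference maps.

Conventions
-----------
All spectra are stored as dimensionless ``S/S0`` values ("Z"); saturation
offsets are in ppm relative to the nominal water frequency; B0 shifts are in
ppm (positive = water resonance displaced to positive offsets).  glucoCEST
maps are stored as fractions of S0; multiply by 100 for percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: Proton Larmor frequency at 3 T, MHz.
PROTON_FREQ_MHZ_3T = 127.7

#: Reference-image offset, ppm (far enough off-resonance that Z ~ 1).
REFERENCE_OFFSET_PPM = 300.0

#: Positive saturation offsets of the default full-Z-spectrum protocol.
_STATIC_POSITIVE_OFFSETS = (
    100.0, 50.0, 10.0, 8.0, 6.0, 5.0, 4.0, 3.5, 3.0, 2.5, 2.0,
    1.5, 1.2, 1.0, 0.8, 0.5, 0.25,
)


def b0_grid_step_ppm(resolution_hz: float = 1.0,
                     proton_freq_mhz: float = PROTON_FREQ_MHZ_3T) -> float:
    """Spectral resolution in ppm for a given resolution in Hz.

    At 3 T (127.7 MHz) a 1-Hz step corresponds to 0.0078 ppm after rounding
    to two significant figures, which is the default evaluation grid of the
    B0 shift search.
    """
    step = resolution_hz / proton_freq_mhz
    return float(f"{step:.2g}")


def lorentzian(delta_ppm, fwhm_ppm):
    """Unit-amplitude Lorentzian ``(G/2)^2 / ((G/2)^2 + d^2)`` with FWHM G."""
    g = fwhm_ppm / 2.0
    d = np.asarray(delta_ppm, dtype=float)
    return g * g / (g * g + d * d)


@dataclass(frozen=True)
class LorentzianPool:
    """One saturation pool of the Z-spectrum model.

    amplitude is the peak fractional saturation (of S0), fwhm_ppm the full
    width at half maximum, center_ppm the pool resonance relative to water.
    """

    amplitude: float
    fwhm_ppm: float
    center_ppm: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.fwhm_ppm) or self.fwhm_ppm <= 0:
            raise ValueError(f"pool width must be > 0, got {self.fwhm_ppm}")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError(
                f"pool amplitude must be in [0, 1], got {self.amplitude}")

    def __call__(self, offsets_ppm, b0_shift_ppm: float = 0.0):
        return self.amplitude * lorentzian(
            np.asarray(offsets_ppm, dtype=float) - self.center_ppm
            - b0_shift_ppm, self.fwhm_ppm)


@dataclass
class OffsetSchedule:
    """Ordered saturation offsets with reference-image entries.

    entries is a list of ``(offset_ppm, is_reference)`` in acquisition order.
    The last reference entry is the designated S0 image.
    """

    entries: list
    per_image_duration_s: float = 7.2

    def __post_init__(self):
        self.entries = [(float(o), bool(r)) for o, r in self.entries]
        offs = np.array([o for o, _ in self.entries])
        if not np.all(np.isfinite(offs)):
            raise ValueError("schedule offsets must be finite")
        if not any(r for _, r in self.entries):
            raise ValueError("schedule needs at least one reference entry")

    def __len__(self):
        return len(self.entries)

    @property
    def is_reference(self) -> np.ndarray:
        return np.array([r for _, r in self.entries], dtype=bool)

    @property
    def offsets_ppm(self) -> np.ndarray:
        """Saturation (non-reference) offsets, in acquisition order."""
        return np.array([o for o, r in self.entries if not r])

    @property
    def s0_index(self) -> int:
        """Frame index of the S0 image (the last reference entry)."""
        return int(np.nonzero(self.is_reference)[0][-1])

    @property
    def n_saturation(self) -> int:
        return int((~self.is_reference).sum())

    @classmethod
    def volunteer_static(cls, per_image_duration_s: float = 7.2
                         ) -> "OffsetSchedule":
        """Default full-Z-spectrum protocol: 4 leading reference images at
        300 ppm followed by 35 saturation offsets from +100 to -100 ppm."""
        entries = [(REFERENCE_OFFSET_PPM, True)] * 4
        pos = list(_STATIC_POSITIVE_OFFSETS)
        offsets = pos + [0.0] + [-o for o in reversed(pos)]
        entries += [(o, False) for o in sorted(offsets, reverse=True)]
        return cls(entries, per_image_duration_s)

    def to_dict(self) -> dict:
        return {
            "offsets_ppm": [o for o, _ in self.entries],
            "is_reference": [bool(r) for _, r in self.entries],
            "per_image_duration_s": self.per_image_duration_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OffsetSchedule":
        return cls(list(zip(d["offsets_ppm"], d["is_reference"])),
                   d.get("per_image_duration_s", 7.2))


@dataclass
class ZSpectrumVolume:
    """Per-voxel Z-spectrum over the saturation offsets.

    z has shape ``spatial + (n_offsets,)``; offsets_ppm matches the last
    axis in schedule order; s0 is the reference image the series was
    normalized by.
    """

    z: np.ndarray
    offsets_ppm: np.ndarray
    s0: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        if self.z.shape[-1] != self.offsets_ppm.size:
            raise ValueError("z last axis must match number of offsets")
        if self.z.shape[:-1] != self.s0.shape:
            raise ValueError("z spatial shape must match s0")

    @property
    def spatial_shape(self):
        return self.s0.shape

    def at_offset(self, offset_ppm: float) -> np.ndarray:
        """Z map at one nominal offset; raises naming the available offsets."""
        idx = np.nonzero(np.isclose(self.offsets_ppm, offset_ppm))[0]
        if idx.size == 0:
            raise ValueError(
                f"offset {offset_ppm} ppm not in schedule; available: "
                f"{sorted(set(self.offsets_ppm.tolist()))}")
        return self.z[..., idx[0]]


@dataclass
class B0Map:
    """Per-voxel water-frequency shift (ppm) with the search settings used.

    converged marks voxels whose Lorentzian fit succeeded; failed voxels
    carry shift 0.
    """

    shift_ppm: np.ndarray
    grid_resolution_ppm: float = 0.0078
    search_window_ppm: float = 1.0
    converged: np.ndarray | None = None

    def __post_init__(self):
        self.shift_ppm = np.asarray(self.shift_ppm, dtype=float)
        if self.converged is None:
            self.converged = np.ones(self.shift_ppm.shape, dtype=bool)


def normalize(series: np.ndarray, schedule: OffsetSchedule) -> ZSpectrumVolume:
    """Normalize a static series by its S0 frame.

    series has shape ``spatial + (n_frames,)`` in schedule order.  Reference
    frames are dropped from the output; voxels with non-positive S0 are set
    to NaN, counted and logged.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] != len(schedule):
        raise ValueError(
            f"series has {series.shape[-1]} frames but schedule has "
            f"{len(schedule)} entries")
    s0 = series[..., schedule.s0_index]
    bad = ~(s0 > 0)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("normalize: %d voxels with non-positive S0 set to NaN",
                       n_bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = series[..., ~schedule.is_reference] / s0[..., None]
    z[bad] = np.nan
    return ZSpectrumVolume(z, schedule.offsets_ppm, s0)


def _fit_subset(offsets_ppm: np.ndarray, inner_ppm: float = 1.0,
                outer_ppm: float = 10.0) -> np.ndarray:
    """Boolean mask of the offsets used for the B0 / two-pool fits:
    the closed interval ``[-inner, inner]`` plus the wings ``|w| > outer``."""
    a = np.abs(offsets_ppm)
    return (a <= inner_ppm) | (a > outer_ppm)


#: Hydroxyl (glucose) pool defaults used by the multi-pool B0 fit: resonance
#: offset from water and FWHM, ppm.
HYDROXYL_OFFSET_PPM = 1.2
HYDROXYL_FWHM_PPM = 1.6


def _b0_model_jac(p, om, n_par):
    """Model value and analytic Jacobian of the multi-pool B0-fit model.

    Parameters are (A_ds, w_ds, c_ds, A_mt, w_mt[, A_oh]); the MT pool is
    fixed at 0 ppm and the hydroxyl pool rides at c_ds + 1.2 ppm with fixed
    width.
    """
    a1, w1, c1, a2, w2 = p[:5]
    J = np.empty((om.size, n_par))
    g1 = w1 / 2.0
    d1 = om - c1
    q1 = g1 * g1 + d1 * d1
    J[:, 0] = -(g1 * g1) / q1
    J[:, 1] = -a1 * (g1 * d1 * d1) / (q1 * q1)
    J[:, 2] = -a1 * (2 * g1 * g1 * d1) / (q1 * q1)
    g2 = w2 / 2.0
    q2 = g2 * g2 + om * om
    J[:, 3] = -(g2 * g2) / q2
    J[:, 4] = -a2 * (g2 * om * om) / (q2 * q2)
    val = 1.0 - a1 * (g1 * g1) / q1 - a2 * (g2 * g2) / q2
    if n_par == 6:
        a3 = p[5]
        g3 = HYDROXYL_FWHM_PPM / 2.0
        d3 = om - c1 - HYDROXYL_OFFSET_PPM
        q3 = g3 * g3 + d3 * d3
        J[:, 5] = -(g3 * g3) / q3
        J[:, 2] += -a3 * (2 * g3 * g3 * d3) / (q3 * q3)
        val = val - a3 * (g3 * g3) / q3
    return val, J


def fit_b0_map(zvol: ZSpectrumVolume,
               search_window_ppm: float = 1.0,
               grid_resolution_ppm: float | None = None,
               solute_pool: bool = True,
               mask: np.ndarray | None = None) -> B0Map:
    """Per-voxel B0 shift by multi-pool Lorentzian fitting.

    A direct-saturation pool (free amplitude, width and center) plus a
    broad magnetization-transfer pool (fixed at 0 ppm) are fitted by bounded
    trust-region least squares to the offsets in ``[-1, 1]`` ppm and the
    ``|w| > 10`` ppm wings.  With ``solute_pool`` (default) a hydroxyl pool
    riding 1.2 ppm above the water center (fixed 1.6-ppm width, free
    amplitude) is included so that dissolved-glucose signal leaking into the
    fitting window does not bias the water-line estimate.  The fitted
    water + MT curve is evaluated on a uniform grid (default step
    0.0078 ppm, i.e. 1 Hz at 3 T) over ``+-search_window_ppm`` and the grid
    argmin is the voxel's B0 shift; ties resolve to the smallest absolute
    shift.

    Fit failures get shift 0 and ``converged=False``; a warning is issued if
    more than 5% of fitted voxels fail.
    """
    if grid_resolution_ppm is None:
        grid_resolution_ppm = b0_grid_step_ppm()
    sel = _fit_subset(zvol.offsets_ppm)
    if sel.sum() < 5:
        raise ValueError(
            f"need >= 5 offsets inside the fitting subset, got {sel.sum()}")
    om = zvol.offsets_ppm[sel]
    order = np.argsort(om)
    om = om[order]
    inner = np.abs(om) <= search_window_ppm

    n_par = 6 if solute_pool else 5
    lb = np.array([0.0, 0.3, -search_window_ppm, 0.0, 5.0, 0.0][:n_par])
    ub = np.array([1.0, 10.0, search_window_ppm, 1.0, 100.0, 0.2][:n_par])

    n_grid = int(np.floor(search_window_ppm / grid_resolution_ppm))
    grid = grid_resolution_ppm * np.arange(-n_grid, n_grid + 1)

    spatial = zvol.spatial_shape
    zflat = zvol.z.reshape(-1, zvol.z.shape[-1])[:, sel][:, order]
    if mask is None:
        vox = np.nonzero(np.isfinite(zflat).all(axis=1))[0]
    else:
        vox = np.nonzero(np.asarray(mask, bool).ravel()
                         & np.isfinite(zflat).all(axis=1))[0]

    shifts = np.zeros(zflat.shape[0])
    ok = np.ones(zflat.shape[0], dtype=bool)
    n_fail = 0
    for i in vox:
        zi = zflat[i]
        c0 = om[inner][np.argmin(zi[inner])] if inner.any() else 0.0
        p0 = np.array([0.9, 2.0, c0, 0.1, 25.0, 0.0][:n_par])
        p0 = np.clip(p0, lb, ub)
        try:
            res = least_squares(
                lambda p: _b0_model_jac(p, om, n_par)[0] - zi, p0,
                jac=lambda p: _b0_model_jac(p, om, n_par)[1],
                bounds=(lb, ub))
            if not res.success or not np.all(np.isfinite(res.x)):
                raise RuntimeError("fit did not converge")
        except Exception:
            n_fail += 1
            ok[i] = False
            continue
        a1, w1, c1, a2, w2 = res.x[:5]
        curve = (1.0 - a1 * lorentzian(grid - c1, w1)
                 - a2 * lorentzian(grid, w2))
        m = curve.min()
        cand = np.nonzero(curve == m)[0]
        shifts[i] = grid[cand[np.argmin(np.abs(grid[cand]))]]
    if vox.size and n_fail / vox.size > 0.05:
        logger.warning("fit_b0_map: %d/%d voxel fits failed", n_fail,
                       vox.size)
    return B0Map(shifts.reshape(spatial), grid_resolution_ppm,
                 search_window_ppm, ok.reshape(spatial))


def correct_zspectrum_b0(zvol: ZSpectrumVolume, b0: B0Map) -> ZSpectrumVolume:
    """Reference each voxel's spectrum to its true water frequency.

    The measured spectrum, piecewise-linear in offset, is resampled at the
    nominal offsets shifted by the voxel's B0 shift, so that the corrected
    value at nominal offset ``w`` is the measurement the voxel would have
    produced with zero shift.  Shifted sample positions falling outside the
    measured offset range are left unchanged (and counted in the log).
    """
    if b0.shift_ppm.shape != zvol.spatial_shape:
        raise ValueError("B0 map shape does not match spectrum volume")
    offs = zvol.offsets_ppm
    order = np.argsort(offs)
    so = offs[order]
    zflat = zvol.z.reshape(-1, offs.size)
    out = zflat.copy()
    shifts = b0.shift_ppm.ravel()
    n_out_of_range = 0
    # shifts live on the evaluation grid, so group voxels by unique shift
    # and resample each group with one vectorized interpolation.
    for s in np.unique(shifts):
        rows = np.nonzero(shifts == s)[0]
        if s == 0.0:
            continue
        x = offs + s
        in_range = (x >= so[0]) & (x <= so[-1])
        n_out_of_range += int((~in_range).sum()) * rows.size
        j = np.clip(np.searchsorted(so, x[in_range]) - 1, 0, so.size - 2)
        x0 = so[j]
        w = (x[in_range] - x0) / (so[j + 1] - x0)
        zs = zflat[np.ix_(rows, order)]
        out[np.ix_(rows, np.nonzero(in_range)[0])] = (
            (1.0 - w) * zs[:, j] + w * zs[:, j + 1])
    if n_out_of_range:
        logger.info("correct_zspectrum_b0: %d shifted samples outside the "
                    "measured range left unchanged", n_out_of_range)
    return ZSpectrumVolume(out.reshape(zvol.z.shape), offs, zvol.s0)


def fit_two_pool(zvol: ZSpectrumVolume,
                 mask: np.ndarray | None = None) -> dict:
    """Two-pool (direct saturation + MT) amplitude/width maps.

    Expects a B0-corrected input: both pool centers are held fixed (water at
    0 ppm, MT at 0 ppm) and only amplitudes and widths are fitted, on the
    same offset subset as the B0 fit.  Returns a dict of maps
    ``ds_amplitude, ds_fwhm, mt_amplitude, mt_fwhm, converged``.
    """
    sel = _fit_subset(zvol.offsets_ppm)
    om = zvol.offsets_ppm[sel]
    lb = np.array([0.0, 0.3, 0.0, 5.0])
    ub = np.array([1.0, 10.0, 1.0, 100.0])

    def model(p):
        return 1.0 - p[0] * lorentzian(om, p[1]) - p[2] * lorentzian(om, p[3])

    def jac(p):
        J = np.empty((om.size, 4))
        for k, (a, w) in enumerate(((p[0], p[1]), (p[2], p[3]))):
            g = w / 2.0
            q = g * g + om * om
            J[:, 2 * k] = -(g * g) / q
            J[:, 2 * k + 1] = -a * (g * om * om) / (q * q)
        return J

    spatial = zvol.spatial_shape
    zflat = zvol.z.reshape(-1, zvol.z.shape[-1])[:, sel]
    if mask is None:
        vox = np.nonzero(np.isfinite(zflat).all(axis=1))[0]
    else:
        vox = np.nonzero(np.asarray(mask, bool).ravel()
                         & np.isfinite(zflat).all(axis=1))[0]
    out = {k: np.zeros(zflat.shape[0]) for k in
           ("ds_amplitude", "ds_fwhm", "mt_amplitude", "mt_fwhm")}
    ok = np.ones(zflat.shape[0], dtype=bool)
    for i in vox:
        zi = zflat[i]
        try:
            res = least_squares(lambda p: model(p) - zi, [0.9, 2.0, 0.1, 25.0],
                                jac=lambda p: jac(p), bounds=(lb, ub))
            if not res.success:
                raise RuntimeError
        except Exception:
            ok[i] = False
            continue
        (out["ds_amplitude"][i], out["ds_fwhm"][i],
         out["mt_amplitude"][i], out["mt_fwhm"][i]) = res.x
    maps = {k: v.reshape(spatial) for k, v in out.items()}
    maps["converged"] = ok.reshape(spatial)
    return maps


def compute_glucocest(z_baseline: ZSpectrumVolume, z_post: ZSpectrumVolume,
                      offset_ppm: float) -> np.ndarray:
    """Static glucose-enhanced contrast: ``Z_baseline - Z_post`` at one
    offset (typically 1.2 or 2 ppm), as a fraction of S0.

    Both inputs should be B0-corrected and spatially aligned.
    """
    return z_baseline.at_offset(offset_ppm) - z_post.at_offset(offset_ppm)
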