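"""Synthetic glucoCEST/DGE phantom and acquisition simulator.

Generates static full-Z-spectrum scans and interleaved two-offset dynamic
scans of a small digital head phantom with known ground truth: multi-pool
Lorentzian Z-spectra per tissue class, a calibrated glucose pool, a venous
glucose bolus time course, a smooth spatial B0 field with optional linear
temporal drift, additive Gaussian noise on the normalized signal, and
optional per-frame rigid translation.

The glucose pool is a Lorentzian at +1.2 ppm (hydroxyl regime) with a
1.6-ppm width whose amplitude is linear in concentration; the per-mM
amplitude is calibrated numerically so that a 10-mM increase reduces Z at
2 ppm by exactly 2% (the phantom-study effect size the simulator is scaled
to).  Ground-truth contrast is therefore exactly linear in concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import shift as _ndshift
from scipy.optimize import brentq

from .dynamic import DYNAMIC_OFFSETS_PPM, DynamicSeries
from .zspec import (HYDROXYL_FWHM_PPM, HYDROXYL_OFFSET_PPM, LorentzianPool,
                    OffsetSchedule, lorentzian)

# Tissue labels of the phantom label map.
BACKGROUND, WM, GM, CSF, SS, TUMOR = 0, 1, 2, 3, 4, 5
LABEL_NAMES = {WM: "WM", GM: "GM", CSF: "CSF", SS: "SS", TUMOR: "tumor"}

#: Phantom-study calibration anchor: Z reduction at 2 ppm per 10 mM glucose.
CALIBRATION_EFFECT = 0.02
CALIBRATION_MM = 10.0
CALIBRATION_OFFSET_PPM = 2.0


def calibrate_glucose_amplitude_per_mm() -> float:
    """Glucose-pool amplitude per mM such that ``CALIBRATION_MM`` mM reduces
    Z at 2 ppm by ``CALIBRATION_EFFECT`` (solved numerically)."""
    shape = lorentzian(CALIBRATION_OFFSET_PPM - HYDROXYL_OFFSET_PPM,
                       HYDROXYL_FWHM_PPM)

    def f(k):
        return CALIBRATION_MM * k * shape - CALIBRATION_EFFECT

    return brentq(f, 0.0, 1.0, xtol=1e-14)


def glucose_sensitivity_at(offset_ppm: float,
                           amplitude_per_mm: float | None = None) -> float:
    """Ground-truth Z reduction per mM at a given offset (fraction of S0)."""
    if amplitude_per_mm is None:
        amplitude_per_mm = calibrate_glucose_amplitude_per_mm()
    return amplitude_per_mm * lorentzian(offset_ppm - HYDROXYL_OFFSET_PPM,
                                         HYDROXYL_FWHM_PPM)


@dataclass
class GlucoseKinetics:
    """Venous glucose bolus model.

    A piecewise-linear rise from the start of the infusion (duration 200 s =
    50 mL at 0.25 mL/s) plus a circulation/mixing lag, peaking
    ``infusion_duration_s + rise_lag_s`` after infusion start (default
    300 s, matching the observed venous peak near 5 min), then exponential
    clearance.  Tissue curves are delayed, scaled copies of the venous
    curve.
    """

    infusion_start_s: float = 180.0
    infusion_duration_s: float = 200.0
    bolus_mM: float = 8.0
    rise_lag_s: float = 100.0
    decay_halflife_s: float = 900.0
    tissue_scale: dict = field(default_factory=lambda: {
        WM: 0.08, GM: 0.15, CSF: 0.20, SS: 1.0, TUMOR: 0.5})
    tissue_delay_s: dict = field(default_factory=lambda: {
        WM: 30.0, GM: 25.0, CSF: 40.0, SS: 0.0, TUMOR: 20.0})


def glucose_timecourse(t_s, kinetics: GlucoseKinetics) -> np.ndarray:
    """Venous concentration increase (mM) at time ``t_s`` (scan clock).

    Deterministic and continuous; identically 0 before the infusion starts
    and decaying to 0 as t -> infinity.
    """
    t = np.asarray(t_s, dtype=float)
    tau = t - kinetics.infusion_start_s
    rise = kinetics.infusion_duration_s + kinetics.rise_lag_s
    c = np.where(
        tau <= 0.0, 0.0,
        np.where(
            tau <= rise,
            kinetics.bolus_mM * tau / rise,
            kinetics.bolus_mM * np.exp(
                -np.log(2.0) * (tau - rise) / kinetics.decay_halflife_s)))
    return c if c.ndim else float(c)


def tissue_concentration(kinetics: GlucoseKinetics, label: int,
                         t_s) -> np.ndarray:
    """Concentration increase (mM) in one tissue class at time ``t_s``."""
    scale = kinetics.tissue_scale.get(label, 0.0)
    delay = kinetics.tissue_delay_s.get(label, 0.0)
    return scale * glucose_timecourse(np.asarray(t_s, float) - delay,
                                      kinetics)


@dataclass
class PhantomTruth:
    """Complete ground truth of one synthetic head.

    pool_params maps tissue label -> (water direct-saturation pool, optional
    MT pool); glucose_sensitivity maps label -> Z reduction per mM at 2 ppm;
    b0_field is the shift map at t=0 and b0_drift_rate its uniform linear
    drift (ppm/s); s0_per_label sets raw reference intensities.
    motion_trace, if set, holds one rigid translation (voxels) per frame.
    """

    label_map: np.ndarray
    pool_params: dict
    glucose_sensitivity: dict
    b0_field: np.ndarray
    b0_drift_rate: float = 0.0
    kinetics: GlucoseKinetics = field(default_factory=GlucoseKinetics)
    noise_sigma: float = 0.0
    motion_trace: np.ndarray | None = None
    seed: int = 0
    s0_per_label: dict = field(default_factory=lambda: {
        WM: 900.0, GM: 1000.0, CSF: 1100.0, SS: 950.0, TUMOR: 1000.0})
    max_concentration_mM: float = 12.0

    def __post_init__(self):
        self.label_map = np.asarray(self.label_map)
        self.b0_field = np.asarray(self.b0_field, dtype=float)
        if self.label_map.shape != self.b0_field.shape:
            raise ValueError("label map and B0 field must share one grid")
        for lab, pools in self.pool_params.items():
            amp = sum(p.amplitude for p in pools)
            k = self.glucose_amplitude_per_mm(lab)
            if amp + k * self.max_concentration_mM > 1.0 + 1e-12:
                raise ValueError(
                    f"label {lab}: pool amplitudes + max glucose "
                    "contribution exceed 1")

    @property
    def shape(self):
        return self.label_map.shape

    @property
    def labels(self) -> list[int]:
        return sorted(self.pool_params)

    def mask(self, label: int | None = None) -> np.ndarray:
        """Boolean mask of one label, or of all tissue (label > 0)."""
        if label is None:
            return self.label_map > 0
        return self.label_map == label

    @property
    def s0_map(self) -> np.ndarray:
        s0 = np.zeros(self.shape)
        for lab, v in self.s0_per_label.items():
            s0[self.label_map == lab] = v
        return s0

    def glucose_amplitude_per_mm(self, label: int) -> float:
        """Glucose-pool amplitude per mM for one label (its sensitivity at
        2 ppm divided by the Lorentzian shape factor at 2 ppm)."""
        shape = lorentzian(CALIBRATION_OFFSET_PPM - HYDROXYL_OFFSET_PPM,
                           HYDROXYL_FWHM_PPM)
        return self.glucose_sensitivity.get(label, 0.0) / shape

    def b0_at(self, t_s: float) -> np.ndarray:
        return self.b0_field + self.b0_drift_rate * t_s

    def concentration(self, label: int, t_s) -> np.ndarray:
        return tissue_concentration(self.kinetics, label, t_s)

    def true_dge(self, label: int, offset_ppm: float, t_s) -> np.ndarray:
        """Ground-truth DGE (Z reduction) of one tissue at one offset."""
        shape2 = lorentzian(CALIBRATION_OFFSET_PPM - HYDROXYL_OFFSET_PPM,
                            HYDROXYL_FWHM_PPM)
        shape = lorentzian(offset_ppm - HYDROXYL_OFFSET_PPM,
                           HYDROXYL_FWHM_PPM)
        sens = self.glucose_sensitivity.get(label, 0.0) * shape / shape2
        return sens * self.concentration(label, t_s)


#: Default tissue pools: (direct water saturation, magnetization transfer).
_DEFAULT_POOLS = {
    WM: (LorentzianPool(0.85, 3.2, 0.0), LorentzianPool(0.09, 25.0, 0.0)),
    GM: (LorentzianPool(0.87, 3.0, 0.0), LorentzianPool(0.05, 25.0, 0.0)),
    CSF: (LorentzianPool(0.94, 2.0, 0.0),),
    SS: (LorentzianPool(0.90, 2.8, 0.0), LorentzianPool(0.02, 25.0, 0.0)),
    TUMOR: (LorentzianPool(0.88, 2.6, 0.0), LorentzianPool(0.03, 25.0, 0.0)),
}


def _polynomial_b0_field(shape, amplitude_ppm: float) -> np.ndarray:
    """Smooth second-order polynomial shift field scaled to
    ``max |field| = amplitude_ppm``."""
    nx, ny, nz = shape
    x, y, z = np.meshgrid(np.linspace(-1, 1, nx), np.linspace(-1, 1, ny),
                          np.linspace(-1, 1, nz), indexing="ij")
    f = (0.9 * x + 0.5 * y - 0.3 * z + 0.7 * x * x - 0.5 * y * y
         + 0.4 * x * y - 0.2 * z * z + 0.1)
    if amplitude_ppm == 0:
        return np.zeros(shape)
    return f / np.abs(f).max() * amplitude_ppm


def default_phantom(shape=(32, 32, 8), b0_amplitude_ppm: float = 0.2,
                    b0_drift_rate: float = 0.0, noise_sigma: float = 0.0,
                    kinetics: GlucoseKinetics | None = None,
                    motion_trace: np.ndarray | None = None,
                    with_tumor: bool = False, seed: int = 0) -> PhantomTruth:
    """Default digital head: WM core, GM shell, a central CSF compartment
    and a small sagittal-sinus cylinder, on a 32 x 32 x 8 grid."""
    nx, ny, nz = shape
    x, y, z = np.meshgrid(np.linspace(-1, 1, nx), np.linspace(-1, 1, ny),
                          np.linspace(-1, 1, nz), indexing="ij")
    labels = np.zeros(shape, dtype=np.int16)
    brain = (x / 0.92) ** 2 + (y / 0.92) ** 2 + (z / 0.95) ** 2 <= 1.0
    inner = (x / 0.70) ** 2 + (y / 0.70) ** 2 + (z / 0.80) ** 2 <= 1.0
    labels[brain] = GM
    labels[brain & inner] = WM
    ventricle = (x / 0.22) ** 2 + (y / 0.30) ** 2 + (z / 0.55) ** 2 <= 1.0
    labels[brain & ventricle] = CSF
    sinus = (x ** 2 + (y - 0.72) ** 2 <= 0.12 ** 2) & (np.abs(z) <= 0.5)
    labels[brain & sinus] = SS
    if with_tumor:
        tumor = ((x + 0.42) ** 2 + (y + 0.30) ** 2
                 + (z / 1.4) ** 2 <= 0.22 ** 2)
        labels[brain & tumor] = TUMOR

    k = calibrate_glucose_amplitude_per_mm()
    shape2 = lorentzian(CALIBRATION_OFFSET_PPM - HYDROXYL_OFFSET_PPM,
                        HYDROXYL_FWHM_PPM)
    sens = {lab: k * shape2 for lab in _DEFAULT_POOLS}
    pools = {lab: _DEFAULT_POOLS[lab]
             for lab in _DEFAULT_POOLS if with_tumor or lab != TUMOR}
    return PhantomTruth(
        label_map=labels, pool_params=pools,
        glucose_sensitivity={lab: sens[lab] for lab in pools},
        b0_field=_polynomial_b0_field(shape, b0_amplitude_ppm),
        b0_drift_rate=b0_drift_rate,
        kinetics=kinetics or GlucoseKinetics(),
        noise_sigma=noise_sigma, motion_trace=motion_trace, seed=seed)


def zspectrum_forward(pools, offsets_ppm, b0_shift_ppm: float = 0.0
                      ) -> np.ndarray:
    """Forward Z-spectrum model: ``Z = 1 - sum_i A_i L(w - c_i - b0)``.

    With pool amplitudes summing to at most 1 the result lies in [0, 1].
    """
    offsets = np.asarray(offsets_ppm, dtype=float)
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    z = np.ones_like(offsets, dtype=float)
    for p in pools:
        z = z - p(offsets, b0_shift_ppm)
    return z


def apply_motion(volume: np.ndarray, translation_voxels) -> np.ndarray:
    """Rigid translation of a volume by linear interpolation, zero-filled
    outside the field of view."""
    t = np.asarray(translation_voxels, dtype=float)
    if np.all(t == 0):
        return np.asarray(volume, dtype=float).copy()
    return _ndshift(np.asarray(volume, dtype=float), t, order=1, cval=0.0,
                    mode="constant")


def _label_zspectra(truth: PhantomTruth, offsets: np.ndarray,
                    concentrations: dict, t_s: float) -> np.ndarray:
    """Noise-free Z for every voxel at the given offsets: shape
    ``spatial + (n_offsets,)``.  Vectorized per tissue label over the
    voxel-wise B0 field at time ``t_s``."""
    b0 = truth.b0_at(t_s)
    out = np.ones(truth.shape + (offsets.size,))
    for lab in truth.labels:
        m = truth.label_map == lab
        if not m.any():
            continue
        d = offsets[None, :] - b0[m][:, None]
        z = np.ones_like(d)
        for p in truth.pool_params[lab]:
            z -= p.amplitude * lorentzian(d - p.center_ppm, p.fwhm_ppm)
        c = concentrations.get(lab, 0.0)
        if c > 0:
            amp = truth.glucose_amplitude_per_mm(lab) * c
            z -= amp * lorentzian(d - HYDROXYL_OFFSET_PPM, HYDROXYL_FWHM_PPM)
        out[m] = z
    out[truth.label_map == BACKGROUND] = 0.0
    return out


def simulate_static_scan(truth: PhantomTruth,
                         schedule: OffsetSchedule | None = None,
                         state: str = "baseline",
                         seed: int | None = None,
                         concentration_mM: float | None = None,
                         scan_time_s: float | None = None
                         ) -> tuple[np.ndarray, dict]:
    """One static full-Z-spectrum acquisition (raw, unnormalized).

    ``state='baseline'`` images the phantom at t=0 with no glucose;
    ``state='postinfusion'`` at the configured post-scan time (default
    13 min after infusion start) with tissue concentrations from the
    kinetics, or a uniform ``concentration_mM`` override (the phantom-study
    condition).  Reference entries are simulated at Z ~ 1.  Returns the 4D
    frame array (schedule order) and an acquisition-metadata dict.
    """
    if schedule is None:
        schedule = OffsetSchedule.volunteer_static()
    if len(schedule) == 0:
        raise ValueError("empty schedule")
    if state not in ("baseline", "postinfusion"):
        raise ValueError(f"unknown state {state!r}")
    if state == "baseline":
        t = 0.0
        conc = {lab: 0.0 for lab in truth.labels}
    else:
        t = (truth.kinetics.infusion_start_s + 780.0
             if scan_time_s is None else float(scan_time_s))
        if concentration_mM is not None:
            conc = {lab: float(concentration_mM) for lab in truth.labels}
        else:
            conc = {lab: float(truth.concentration(lab, t))
                    for lab in truth.labels}

    offsets = schedule.offsets_ppm
    z_sat = _label_zspectra(truth, offsets, conc, t)
    s0 = truth.s0_map
    n = len(schedule)
    frames = np.empty(truth.shape + (n,))
    isref = schedule.is_reference
    zref = np.where(s0 > 0, 1.0, 0.0)
    frames[..., isref] = zref[..., None]
    frames[..., ~isref] = z_sat
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    if truth.noise_sigma > 0:
        frames = frames + rng.normal(0.0, truth.noise_sigma,
                                     size=frames.shape)
    frames *= s0[..., None]
    if truth.motion_trace is not None:
        trace = np.asarray(truth.motion_trace, dtype=float)
        for i in range(min(n, len(trace))):
            frames[..., i] = apply_motion(frames[..., i], trace[i])
    meta = {
        "kind": "static", "state": state, "scan_time_s": t,
        "schedule": schedule.to_dict(),
        "concentration_mM": {int(k): v for k, v in conc.items()},
        "infusion_start_s": truth.kinetics.infusion_start_s,
        "seed": int(truth.seed if seed is None else seed),
    }
    return frames, meta


def simulate_dynamic_scan(truth: PhantomTruth, n_timepoints: int = 128,
                          offsets=DYNAMIC_OFFSETS_PPM,
                          seed: int | None = None,
                          per_image_duration_s: float = 7.2,
                          n_reference: int = 4
                          ) -> tuple[DynamicSeries, np.ndarray]:
    """Interleaved two-offset dynamic acquisition (raw, unnormalized).

    Saturation frames alternate between the two offsets; frame ``i`` is
    acquired at ``i * per_image_duration_s`` (the leading reference images
    precede t=0).  The glucose pool follows the bolus kinetics, the B0
    field drifts linearly, and the optional motion trace displaces each
    saturation frame.  Returns the series plus the leading reference
    images; the last reference is the series' S0.
    """
    if n_timepoints < 2:
        raise ValueError("need at least one interleaved pair")
    if n_timepoints % 2:
        raise ValueError("interleaved mode requires an even number of "
                         "time points")
    o1, o2 = offsets
    labels = np.where(np.arange(n_timepoints) % 2 == 0, o1, o2)
    times = np.arange(n_timepoints) * per_image_duration_s
    s0 = truth.s0_map
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    refs = np.repeat(np.where(s0 > 0, 1.0, 0.0)[..., None], n_reference,
                     axis=-1)
    if truth.noise_sigma > 0:
        refs = refs + rng.normal(0.0, truth.noise_sigma, size=refs.shape)
    refs *= s0[..., None]

    frames = np.empty(truth.shape + (n_timepoints,))
    for i in range(n_timepoints):
        conc = {lab: float(truth.concentration(lab, times[i]))
                for lab in truth.labels}
        z = _label_zspectra(truth, np.array([labels[i]]), conc,
                            times[i])[..., 0]
        frames[..., i] = z
    if truth.noise_sigma > 0:
        frames = frames + rng.normal(0.0, truth.noise_sigma,
                                     size=frames.shape)
    frames *= s0[..., None]
    if truth.motion_trace is not None:
        trace = np.asarray(truth.motion_trace, dtype=float)
        for i in range(min(n_timepoints, len(trace))):
            frames[..., i] = apply_motion(frames[..., i], trace[i])
    series = DynamicSeries(frames, labels, times, s0=refs[..., -1],
                           normalized=False)
    return series, refs
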