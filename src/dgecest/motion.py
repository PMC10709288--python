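"""Rigid-body motion correction of volumetric time series.

Frames are aligned to a designated reference frame by maximizing normalized
cross-correlation with a derivative-free simplex search started from several
translations.  The similarity metric is chosen to be insensitive to the
global intensity drop during saturation; resampling is trilinear with zero
fill outside the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform
from scipy.ndimage import shift as _ndshift
from scipy.optimize import minimize


@dataclass
class RigidTransform:
    """Rigid transform: translation in voxels, rotation as Euler angles
    (degrees, applied about the volume center in x-y-z order)."""

    translation: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        wrapped = (self.rotation + 180.0) % 360.0 - 180.0
        self.rotation = np.where(wrapped == -180.0, 180.0, wrapped)

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.translation == 0)
                    and np.all(self.rotation == 0))


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def resample(volume: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Apply a rigid transform to a volume (content displaced by
    ``transform``), trilinear interpolation, zero fill."""
    vol = np.asarray(volume, dtype=float)
    if transform.is_identity:
        return vol.copy()
    if np.all(transform.rotation == 0):
        return _ndshift(vol, transform.translation, order=1, cval=0.0,
                        mode="constant")
    R = _rotation_matrix(transform.rotation)
    center = (np.array(vol.shape) - 1) / 2.0
    # affine_transform maps output coords to input: x_in = M x_out + off
    M = np.linalg.inv(R)
    off = center - M @ (center + transform.translation)
    return affine_transform(vol, M, offset=off, order=1, cval=0.0,
                            mode="constant")


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


_TRANSLATION_STARTS = (
    (0.0, 0.0, 0.0),
    (1.5, 1.5, 0.75),
    (-1.5, -1.5, -0.75),
)


def register_rigid(moving: np.ndarray, reference: np.ndarray,
                   mode: str = "translation",
                   max_translation: float = 5.0,
                   max_rotation_deg: float = 10.0) -> RigidTransform:
    """Estimate the rigid transform displacing ``moving`` relative to
    ``reference``.

    Maximizes normalized cross-correlation between the back-shifted moving
    volume and the reference with a Nelder-Mead simplex from three
    translation starts; ``mode='rigid'`` adds the three Euler angles.
    The returned transform is the estimated displacement of the moving
    frame's content; apply its inverse (``resample`` with the negated
    parameters) to align it to the reference.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError("moving and reference must share a grid")
    if reference.std() == 0:
        raise ValueError("flat reference image: registration undefined")
    if mode not in ("translation", "rigid"):
        raise ValueError(f"unknown mode {mode!r}")
    n_par = 3 if mode == "translation" else 6
    bound = np.array([max_translation] * 3 + [max_rotation_deg] * 3)[:n_par]

    def cost(p):
        if np.any(np.abs(p) > bound):
            return 1.0 + float(np.sum(np.abs(p) - bound, where=np.abs(p)
                                      > bound, initial=0.0))
        tr = RigidTransform(-p[:3], -p[3:6] if n_par == 6 else (0, 0, 0))
        return -_ncc(resample(moving, tr), reference)

    best = None
    for start in _TRANSLATION_STARTS:
        p0 = np.zeros(n_par)
        p0[:3] = start
        res = minimize(cost, p0, method="Nelder-Mead",
                       options={"xatol": 0.01, "fatol": 1e-8,
                                "maxiter": 400 * n_par})
        if best is None or res.fun < best.fun:
            best = res
    p = np.clip(best.x, -bound, bound)
    return RigidTransform(p[:3], p[3:6] if n_par == 6 else np.zeros(3))


def mocorr_series(frames: np.ndarray, reference_index: int,
                  mode: str = "translation"
                  ) -> tuple[np.ndarray, pd.DataFrame]:
    """Align every frame of a 4D series to one reference frame.

    Returns the corrected series (same frame count and order) and a
    per-frame transform log with columns
    ``frame, tx, ty, tz, rx, ry, rz, ok``.  The reference frame maps to
    itself exactly; frames whose registration fails are left unaligned and
    flagged ``ok=False``.
    """
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[-1]
    if not 0 <= reference_index < n:
        raise ValueError(f"reference index {reference_index} out of range")
    ref = frames[..., reference_index]
    out = frames.copy()
    rows = []
    for i in range(n):
        if i == reference_index:
            rows.append((i, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, True))
            continue
        try:
            tr = register_rigid(frames[..., i], ref, mode=mode)
            inv = RigidTransform(-tr.translation, -tr.rotation)
            if not inv.is_identity:
                out[..., i] = resample(frames[..., i], inv)
            ok = True
        except Exception:
            tr = RigidTransform()
            ok = False
        rows.append((i, *tr.translation, *tr.rotation, ok))
    log = pd.DataFrame(rows, columns=["frame", "tx", "ty", "tz",
                                      "rx", "ry", "rz", "ok"])
    return out, log
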