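"""Forward kinetic models and Patlak graphical analysis.

The forward chain is: a parametric arterial input function Cp(t) (Feng
model 2: a linear upslope times a fast exponential plus two slower
exponentials), an irreversible two-tissue compartment model driven by Cp,
and duration-weighted frame averaging onto a :class:`FrameSchedule`.

Patlak analysis linearizes the irreversible model after a steady-state time
t*: plotting Ct/Cp against the normalized running integral of Cp gives a
line whose slope is the net influx rate constant Ki = K1*k3/(k2+k3) and
whose intercept approximates the reversible distribution volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .imaging_core import DynamicImage, FrameSchedule, TimeActivityCurve, ValidationError

__all__ = [
    "FengAifParams",
    "KineticParams",
    "PatlakResult",
    "feng_aif",
    "tissue_2tc_irreversible",
    "frame_average",
    "patlak_fit",
    "patlak_voxelwise",
]

#: internal simulation grid step for convolutions [min]
SIM_DT_MIN = 0.01


@dataclass(frozen=True)
class FengAifParams:
    """Parameters of the three-exponential bolus input function.

    Cp(t') = (A1*t' - A2 - A3) e^{lam1 t'} + A2 e^{lam2 t'} + A3 e^{lam3 t'}
    with t' = t - delay (Cp = 0 before the delay).  A1 is in SUV/min, A2 and
    A3 in SUV, the eigenvalues lam1 <= lam2 <= lam3 < 0 in 1/min.
    """

    A1: float
    A2: float
    A3: float
    lam1: float
    lam2: float
    lam3: float
    delay_min: float = 0.0

    def __post_init__(self) -> None:
        if not (self.lam1 <= self.lam2 <= self.lam3 < 0):
            raise ValidationError("eigenvalues must satisfy lam1 <= lam2 <= lam3 < 0")

    def __call__(self, t_min: np.ndarray) -> np.ndarray:
        return feng_aif(self, t_min)


def feng_aif(p: FengAifParams, t_min: np.ndarray) -> np.ndarray:
    """Evaluate the bolus input function at times ``t_min`` [min].

    Raises a validation error if the parameters produce a negative
    concentration anywhere on the requested grid.
    """
    t = np.asarray(t_min, dtype=float)
    tp = t - p.delay_min
    cp = np.where(
        tp < 0,
        0.0,
        (p.A1 * tp - p.A2 - p.A3) * np.exp(p.lam1 * np.where(tp < 0, 0, tp))
        + p.A2 * np.exp(p.lam2 * np.where(tp < 0, 0, tp))
        + p.A3 * np.exp(p.lam3 * np.where(tp < 0, 0, tp)),
    )
    if np.any(cp < -1e-9 * max(1.0, abs(p.A2) + abs(p.A3))):
        raise ValidationError("input-function parameters produce negative Cp")
    return np.clip(cp, 0.0, None)


@dataclass(frozen=True)
class KineticParams:
    """Irreversible two-tissue compartment rate constants.

    K1 [ml/g/min] is plasma-to-tissue delivery, k2 and k3 [1/min] are efflux
    and trapping, vB is the fractional blood volume.  The implied net influx
    rate is ``Ki = K1*k3/(k2+k3)``.
    """

    K1: float
    k2: float
    k3: float
    vB: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3, self.vB) < 0:
            raise ValidationError("rate constants and vB must be >= 0")
        if self.vB > 1:
            raise ValidationError("vB must be <= 1")
        if self.k3 > 0 and self.k2 + self.k3 <= 0:
            raise ValidationError("k2 + k3 must be > 0 when k3 > 0")

    @property
    def Ki(self) -> float:
        if self.k2 + self.k3 == 0:
            return self.K1
        return self.K1 * self.k3 / (self.k2 + self.k3)


def tissue_2tc_irreversible(
    kp: KineticParams,
    cp_fn: Callable[[np.ndarray], np.ndarray],
    t_min: np.ndarray,
    dt_min: float = SIM_DT_MIN,
) -> np.ndarray:
    """Tissue concentration of the irreversible two-tissue model at ``t_min``.

    Ct(t) = (1-vB) * h(t) (*) Cp(t) + vB * Cp(t), with impulse response
    h(t) = K1/(k2+k3) * [k3 + k2 * e^{-(k2+k3)t}] (h = K1 when k2+k3 = 0,
    the pure-accumulation limit).  The convolution is evaluated on a uniform
    internal grid of step ``dt_min`` and linearly interpolated onto ``t_min``.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    t_max = float(t.max()) if t.size else 0.0
    grid = np.arange(0.0, t_max + dt_min, dt_min)
    cp = np.asarray(cp_fn(grid), dtype=float)
    beta = kp.k2 + kp.k3
    if beta == 0:
        h = np.full_like(grid, kp.K1)
    else:
        h = kp.K1 / beta * (kp.k3 + kp.k2 * np.exp(-beta * grid))
    # trapezoid-corrected discrete convolution (exact for constant inputs)
    conv = (np.convolve(cp, h)[: len(grid)] - 0.5 * (cp[0] * h + cp * h[0])) * dt_min
    # the blood term is analytic; only the convolution needs the grid
    return (1.0 - kp.vB) * np.interp(t, grid, conv) + kp.vB * np.asarray(
        cp_fn(t), dtype=float
    )


def frame_average(
    curve_fn: Callable[[np.ndarray], np.ndarray],
    schedule: FrameSchedule,
    kind: str = "tissue",
    n_sub: int = 64,
) -> TimeActivityCurve:
    """Duration-weighted mean of ``curve_fn`` (argument in minutes) per frame.

    Each frame's value is (1/dur) * integral of the curve over the frame,
    computed by an ``n_sub``-point trapezoid rule, and attached to the frame
    midpoint.
    """
    values = np.empty(len(schedule))
    for i, (t0, dur) in enumerate(zip(schedule.start_s, schedule.duration_s)):
        ts = np.linspace(t0, t0 + dur, n_sub + 1) / 60.0
        values[i] = np.trapezoid(curve_fn(ts), ts) / (dur / 60.0)
    return TimeActivityCurve(schedule.midpoint_s, values, kind=kind)


@dataclass(frozen=True)
class PatlakResult:
    """Patlak line fit: slope Ki [ml/g/min], intercept V [ml/g]."""

    Ki: float
    intercept_V: float
    t_star_min: float
    n_points_used: int
    r_value: float


class FitError(ValueError):
    """Raised when a regression has too few usable points."""


def _patlak_coordinates(
    ct: np.ndarray,
    cp: np.ndarray,
    t_min: np.ndarray,
    t_star_min: float,
    cp_floor_frac: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transformed Patlak coordinates and the retained-frame mask.

    x = int_0^t Cp dτ / Cp(t) and y = Ct/Cp on frames with midpoint >= t*
    and Cp above ``cp_floor_frac`` of its peak.  The running integral is a
    midpoint trapezoid with an initial triangle from (0, 0) to the first
    midpoint.
    """
    t_ext = np.concatenate(([0.0], t_min))
    cp_ext = np.concatenate(([0.0], cp))
    icp = np.cumsum(np.diff(t_ext) * (cp_ext[1:] + cp_ext[:-1]) / 2.0)
    floor = cp_floor_frac * float(np.max(cp)) if np.max(cp) > 0 else np.inf
    keep = (t_min >= t_star_min) & (cp > floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(cp > 0, icp / cp, np.nan)
        y = ct / (cp if ct.ndim == 1 else cp[:, None])
    return x, y, keep


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares line fit; y may be (n,) or (n, m) sharing the same x."""
    xm = x.mean()
    ym = y.mean(axis=0)
    dx = x - xm
    sxx = float(np.dot(dx, dx))
    sxy = dx @ (y - ym)
    slope = sxy / sxx
    intercept = ym - slope * xm
    syy = ((y - ym) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    return slope, intercept, r


def patlak_fit(
    ct: TimeActivityCurve,
    cp: TimeActivityCurve,
    t_star_min: float = 10.0,
    cp_floor_frac: float = 0.01,
) -> PatlakResult:
    """Patlak graphical fit of a tissue curve against an input function.

    Ordinary least squares of y = Ct/Cp on x = (running integral of Cp)/Cp
    over frames with midpoint >= ``t_star_min`` [min]; frames where Cp is
    below ``cp_floor_frac`` of its peak are dropped.
    """
    if len(ct) != len(cp) or not np.allclose(ct.t_s, cp.t_s):
        raise ValidationError("tissue and input curves must share the time grid")
    t_min = cp.t_min
    x, y, keep = _patlak_coordinates(
        ct.value_suv, cp.value_suv, t_min, t_star_min, cp_floor_frac
    )
    keep = keep & np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 2:
        raise FitError("fewer than 2 usable Patlak points")
    slope, intercept, r = _ols(x[keep], y[keep])
    return PatlakResult(
        Ki=float(slope),
        intercept_V=float(intercept),
        t_star_min=t_star_min,
        n_points_used=int(keep.sum()),
        r_value=float(r),
    )


def patlak_voxelwise(
    img: DynamicImage,
    cp: TimeActivityCurve,
    t_star_min: float = 10.0,
    mask: np.ndarray | None = None,
    cp_floor_frac: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel Patlak fit; returns 3-D Ki and intercept maps (NaN outside).

    Uses the same transformed-coordinate least-squares routine as
    :func:`patlak_fit`.  Voxels outside ``mask`` or with no signal over the
    retained frames are NaN.
    """
    if img.n_frames != len(cp):
        raise ValidationError("image frames and input function length differ")
    spatial = img.spatial_shape
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ValidationError("mask shape must match spatial dims")
    if not mask.any():
        raise ValidationError("empty mask")

    t_min = cp.t_min
    ct = img.voxels.reshape(img.n_frames, -1)[:, mask.ravel()]
    x, y, keep = _patlak_coordinates(
        ct, cp.value_suv, t_min, t_star_min, cp_floor_frac
    )
    keep = keep & np.isfinite(x)
    if keep.sum() < 2:
        raise FitError("fewer than 2 usable Patlak points")
    yk = y[keep]
    slope, intercept, _ = _ols(x[keep], yk)
    # voxels with no late-frame signal are unidentifiable -> NaN
    dead = ct[keep].max(axis=0) <= 0
    slope = np.where(dead, np.nan, slope)
    intercept = np.where(dead, np.nan, intercept)

    ki_map = np.full(spatial, np.nan)
    v_map = np.full(spatial, np.nan)
    ki_map[mask] = slope
    v_map[mask] = intercept
    return ki_map, v_map
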