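"""Digital mouse phantom: ellipsoidal organs, shared arterial input,
organ-specific FDG kinetics, partial-volume blur and frame-dependent noise.

The phantom stands in for dynamic FDG mouse acquisitions: a 64x48x48 grid
at 0.5 mm isotropic spacing, a bolus input function shared by all organs,
tissue curves from the irreversible two-tissue model, per-frame Gaussian
smoothing emulating scanner resolution (partial-volume effect), and additive
Gaussian noise whose variance scales with value / frame duration, so the
early 5-s frames are visibly noisier than the late 300-s frames.

Every stochastic step draws from an explicit seed: identical spec + seed
gives bit-identical output.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .imaging_core import (
    DynamicImage,
    FrameSchedule,
    ScanMeta,
    TimeActivityCurve,
    ValidationError,
    build_frame_schedule,
    truncate_schedule,
)
from .kinetics import (
    FengAifParams,
    KineticParams,
    feng_aif,
    frame_average,
    tissue_2tc_irreversible,
)

__all__ = [
    "OrganSpec",
    "PhantomSpec",
    "SimulatedScan",
    "PopulationVariation",
    "default_aif",
    "default_organs",
    "default_phantom",
    "scaled_phantom",
    "default_schedule",
    "rasterize_organs",
    "simulate_scan",
    "sample_population",
    "blood_withdrawal_volume",
]

ORGAN_NAMES = (
    "blood_pool",
    "vena_cava",
    "myocardium",
    "brain",
    "liver",
    "muscle",
    "bladder",
    "background",
    "body",
)

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class OrganSpec:
    """An ellipsoidal organ: geometry plus kinetics (or a blood-pool flag)."""

    name: str
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    kinetics: KineticParams | None = None
    blood: bool = False

    def __post_init__(self) -> None:
        if self.name not in ORGAN_NAMES:
            raise ValidationError(f"unknown organ name {self.name!r}")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValidationError("semi-axes must be > 0")
        if self.blood and self.kinetics is not None:
            raise ValidationError("blood organs carry no kinetic parameters")
        if not self.blood and self.kinetics is None:
            raise ValidationError(f"organ {self.name!r} needs kinetics or blood flag")


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to simulate one phantom scan deterministically."""

    organs: tuple[OrganSpec, ...]
    aif: FengAifParams
    shape: tuple[int, int, int] = (64, 48, 48)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    psf_fwhm_mm: float = 1.2
    noise_scale: float = 0.15
    seed: int = 0
    meta: ScanMeta = field(
        default_factory=lambda: ScanMeta(10.5, 33.0, scan_id="phantom")
    )

    def __post_init__(self) -> None:
        if not self.organs:
            raise ValidationError("organ list must be non-empty")
        for o in self.organs:
            c_vox = [c / s for c, s in zip(o.center_mm, self.spacing_mm)]
            if any(c < 0 or c > n for c, n in zip(c_vox, self.shape)):
                raise ValidationError(f"organ {o.name!r} center outside grid")


def default_aif() -> FengAifParams:
    """Bolus input with ~21 SUV peak near 30 s and a slowly clearing tail."""
    return FengAifParams(
        A1=200.0, A2=3.0, A3=1.2, lam1=-4.0, lam2=-0.25, lam3=-0.015, delay_min=0.25
    )


def _load_kinetics_table() -> dict[str, KineticParams]:
    text = (
        importlib.resources.files("dlifkit") / "data" / "organ_kinetics.yaml"
    ).read_text()
    raw = yaml.safe_load(text)
    return {name: KineticParams(**params) for name, params in raw.items()}


def default_organs(uds_mode: bool = False) -> tuple[OrganSpec, ...]:
    """Mouse-like organ layout on the default 32 x 24 x 24 mm grid.

    Later organs overwrite earlier ones where they overlap, so the solid
    myocardium ellipsoid listed before the blood pool becomes a shell with a
    blood cavity.  ``uds_mode`` emulates an unfasted cohort by scaling
    myocardial K1 up.
    """
    kin = _load_kinetics_table()
    myo = kin["myocardium"]
    if uds_mode:
        myo = replace(myo, K1=myo.K1 * 1.5)
    return (
        OrganSpec("body", (16.0, 12.0, 12.0), (14.5, 9.0, 9.0), kin["body"]),
        OrganSpec("liver", (18.0, 13.0, 12.0), (5.0, 5.5, 6.0), kin["liver"]),
        OrganSpec("myocardium", (10.5, 12.0, 12.0), (4.2, 3.8, 3.8), myo),
        OrganSpec("blood_pool", (10.5, 12.0, 12.0), (2.4, 2.2, 2.2), blood=True),
        OrganSpec("vena_cava", (21.0, 9.0, 11.0), (4.5, 1.25, 1.25), blood=True),
        OrganSpec("brain", (4.5, 12.0, 12.0), (3.2, 2.8, 2.8), kin["brain"]),
        OrganSpec("bladder", (27.5, 12.0, 12.0), (2.0, 2.0, 2.0), kin["bladder"]),
    )


def default_phantom(seed: int = 0, uds_mode: bool = False, **overrides) -> PhantomSpec:
    return PhantomSpec(
        organs=default_organs(uds_mode=uds_mode),
        aif=default_aif(),
        seed=seed,
        **overrides,
    )


def scaled_phantom(seed: int = 0, **overrides) -> PhantomSpec:
    """A coarse 16x16x16 phantom (2 mm spacing) for fast experiments.

    Same organs, kinetics and input function as the full-resolution default;
    only the sampling grid is coarser, so whole-cohort simulation and
    network training run in minutes on one CPU.
    """
    overrides.setdefault("shape", (16, 16, 16))
    overrides.setdefault("spacing_mm", (2.0, 2.0, 2.0))
    return default_phantom(seed=seed, **overrides)


def default_schedule(t_max_s: float = 2700.0) -> FrameSchedule:
    """The 44-frame acquisition (24x5, 9x20, 11x300 s) truncated to 45 min."""
    return truncate_schedule(build_frame_schedule([(24, 5), (9, 20), (11, 300)]), t_max_s)


def _voxel_centers_mm(shape, spacing) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def rasterize_organs(spec: PhantomSpec) -> np.ndarray:
    """Integer label volume; background 0, organ i -> label i+1.

    Later organs overwrite earlier ones on overlap.  An organ that covers no
    voxel at all is a validation error.
    """
    xx, yy, zz = _voxel_centers_mm(spec.shape, spec.spacing_mm)
    labels = np.zeros(spec.shape, dtype=np.int16)
    for i, organ in enumerate(spec.organs):
        cx, cy, cz = organ.center_mm
        ax, ay, az = organ.semi_axes_mm
        inside = (
            ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2
        ) <= 1.0
        if not inside.any():
            raise ValidationError(f"organ {organ.name!r} rasterizes to zero voxels")
        labels[inside] = i + 1
    return labels


@dataclass
class SimulatedScan:
    """One simulated acquisition with its ground truth."""

    image: DynamicImage
    cp: TimeActivityCurve  # ground-truth input function on the frame grid
    truth_ki: pd.DataFrame  # per-organ rate constants and implied Ki
    labels: np.ndarray  # organ label volume (pre-blur geometry)
    organ_tacs: dict[str, TimeActivityCurve]  # noiseless forward-model TACs
    spec: PhantomSpec


def simulate_scan(spec: PhantomSpec, schedule: FrameSchedule | None = None) -> SimulatedScan:
    """Simulate a dynamic scan: forward model, then PSF blur, then noise.

    Per organ the time course is the frame-averaged two-tissue forward model
    (blood organs get the frame-averaged input function); voxels take their
    organ's value, each frame is smoothed with a Gaussian of FWHM
    ``psf_fwhm_mm``, and zero-mean Gaussian noise with standard deviation
    ``noise_scale * sqrt(value / duration_s)`` is added and clipped at 0.
    """
    if schedule is None:
        schedule = default_schedule()
    labels = rasterize_organs(spec)
    t_end_min = schedule.total_s / 60.0
    grid = np.arange(0.0, t_end_min + 0.01, 0.01)
    cp_fn = lambda t: feng_aif(spec.aif, t)  # noqa: E731

    organ_tacs: dict[str, TimeActivityCurve] = {}
    lookup = np.zeros((len(spec.organs) + 1, len(schedule)))
    truth_rows = []
    for i, organ in enumerate(spec.organs):
        if organ.blood:
            tac = frame_average(cp_fn, schedule, kind="blood")
        else:
            ct_grid = tissue_2tc_irreversible(organ.kinetics, cp_fn, grid)
            tac = frame_average(
                lambda ts: np.interp(ts, grid, ct_grid), schedule, kind="tissue"
            )
            kp = organ.kinetics
            truth_rows.append(
                {
                    "organ": organ.name,
                    "K1": kp.K1,
                    "k2": kp.k2,
                    "k3": kp.k3,
                    "vB": kp.vB,
                    "Ki": kp.Ki,
                }
            )
        organ_tacs[organ.name] = tac
        lookup[i + 1] = tac.value_suv

    voxels = lookup[labels]  # (X, Y, Z, T)
    voxels = np.moveaxis(voxels, -1, 0)

    if spec.psf_fwhm_mm > 0:
        sigma_vox = [
            spec.psf_fwhm_mm / _FWHM_TO_SIGMA / s for s in spec.spacing_mm
        ]
        voxels = np.stack([gaussian_filter(f, sigma_vox) for f in voxels])

    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        dur = schedule.duration_s[:, None, None, None]
        sd = spec.noise_scale * np.sqrt(np.clip(voxels, 0, None) / dur)
        voxels = voxels + rng.standard_normal(voxels.shape) * sd

    voxels = np.clip(voxels, 0.0, None)
    image = DynamicImage(voxels, spec.spacing_mm, schedule, spec.meta)
    cp = frame_average(cp_fn, schedule, kind="blood")
    truth = pd.DataFrame(truth_rows)
    return SimulatedScan(image, cp, truth, labels, organ_tacs, spec)


@dataclass(frozen=True)
class PopulationVariation:
    """Fractional coefficients of variation for the per-animal jitter.

    AIF amplitudes and decay eigenvalues, plasma-to-tissue delivery (K1),
    and tissue rate constants (k2, k3, at half the kinetics CV since efflux
    and trapping rates vary less across animals than perfusion/delivery) are
    each scaled by independent lognormal multipliers with unit mean.
    """

    aif_amplitude_cv: float = 0.2
    aif_decay_cv: float = 0.1
    kinetics_cv: float = 0.2
    dose_cv: float = 0.17
    weight_cv: float = 0.15


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return np.ones(size) if size else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _jitter_spec(
    base: PhantomSpec, var: PopulationVariation, rng: np.random.Generator, scan_id: str
) -> PhantomSpec:
    a = base.aif
    amp = _lognormal_factor(rng, var.aif_amplitude_cv)
    dec = [_lognormal_factor(rng, var.aif_decay_cv) for _ in range(3)]
    aif = FengAifParams(
        A1=a.A1 * amp,
        A2=a.A2 * amp,
        A3=a.A3 * amp,
        lam1=a.lam1 * dec[0],
        lam2=a.lam2 * dec[1],
        lam3=a.lam3 * dec[2],
        delay_min=a.delay_min,
    )
    # re-sort in case jitter broke the eigenvalue ordering
    l1, l2, l3 = sorted((aif.lam1, aif.lam2, aif.lam3))
    aif = replace(aif, lam1=l1, lam2=l2, lam3=l3)

    organs = []
    for o in base.organs:
        if o.blood:
            organs.append(o)
            continue
        kp = o.kinetics
        kp = KineticParams(
            K1=kp.K1 * _lognormal_factor(rng, var.kinetics_cv),
            k2=kp.k2 * _lognormal_factor(rng, var.kinetics_cv / 2),
            k3=kp.k3 * _lognormal_factor(rng, var.kinetics_cv / 2),
            vB=kp.vB,
        )
        organs.append(replace(o, kinetics=kp))

    meta = ScanMeta(
        injected_dose_MBq=base.meta.injected_dose_MBq * _lognormal_factor(rng, var.dose_cv),
        body_weight_g=base.meta.body_weight_g * _lognormal_factor(rng, var.weight_cv),
        strain_label=base.meta.strain_label,
        scan_id=scan_id,
    )
    return replace(
        base,
        organs=tuple(organs),
        aif=aif,
        meta=meta,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def sample_population(
    n: int,
    base: PhantomSpec | None = None,
    variation: PopulationVariation | None = None,
    seed: int = 0,
    schedule: FrameSchedule | None = None,
) -> list[SimulatedScan]:
    """Simulate a cohort of ``n`` animals with per-animal parameter jitter."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if base is None:
        base = default_phantom()
    if variation is None:
        variation = PopulationVariation()
    rng = np.random.default_rng(seed)
    scans = []
    for i in range(n):
        spec_i = _jitter_spec(base, variation, rng, scan_id=f"phantom-{i:03d}")
        scans.append(simulate_scan(spec_i, schedule))
    return scans


def blood_withdrawal_volume(segments: Sequence[tuple[float, float]]) -> float:
    """Total withdrawn blood [µl] for piecewise-constant pump segments.

    Each segment is (rate_ul_per_min, duration_min); e.g. 15 µl/min for
    5 min followed by 7 µl/min for 36 min withdraws 327 µl.
    """
    total = 0.0
    for rate, duration in segments:
        if rate < 0 or duration < 0:
            raise ValidationError("rates and durations must be >= 0")
        total += rate * duration
    return total
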