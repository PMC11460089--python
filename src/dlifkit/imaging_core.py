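"""Core domain types for dynamic PET: frame schedules, SUV volumes, curves.

Conventions used throughout the package:

* time origin is the injection start (t = 0); frame starts are relative to it;
* after ingestion every voxel and curve value is in SUV [g/ml]; raw activity
  concentrations in kBq/ml are accepted only at the :func:`suv_normalize`
  boundary;
* in memory a dynamic image is ``(T, X, Y, Z)``; on disk (NIfTI) it is stored
  in the conventional ``(X, Y, Z, T)`` order;
* voxel indices are 0-based, world coordinates come from the NIfTI affine.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "ScanMeta",
    "DynamicImage",
    "TimeActivityCurve",
    "build_frame_schedule",
    "truncate_schedule",
    "suv_normalize",
    "read_dynamic_nifti",
    "write_dynamic_nifti",
    "crop_center",
]


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class SchemaError(ValidationError):
    """Raised when file contents do not match the expected layout."""


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous time frames defining the temporal sampling grid.

    Parameters
    ----------
    start_s, duration_s
        Per-frame start times and durations in seconds.  Frames must be
        contiguous (each frame starts where the previous one ends) and
        non-overlapping, with strictly positive durations.
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        if start.ndim != 1 or dur.ndim != 1 or start.shape != dur.shape:
            raise ValidationError("start_s and duration_s must be 1-D and equal length")
        if np.any(dur <= 0):
            raise ValidationError("frame durations must be > 0")
        if len(start) and not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ValidationError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)

    def __len__(self) -> int:
        return len(self.start_s)

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def midpoint_s(self) -> np.ndarray:
        return self.start_s + self.duration_s / 2.0

    @property
    def midpoint_min(self) -> np.ndarray:
        return self.midpoint_s / 60.0

    @property
    def total_s(self) -> float:
        return float(self.end_s[-1]) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(len(self)),
                "start_s": self.start_s,
                "duration_s": self.duration_s,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrameSchedule":
        df = pd.read_csv(path)
        missing = {"start_s", "duration_s"} - set(df.columns)
        if missing:
            raise SchemaError(f"schedule CSV missing columns: {sorted(missing)}")
        return cls(df["start_s"].to_numpy(float), df["duration_s"].to_numpy(float))


def build_frame_schedule(spec: Sequence[tuple[int, float]]) -> FrameSchedule:
    """Build a contiguous schedule from ``[(count, duration_s), ...]`` blocks.

    ``[(24, 5), (9, 20), (11, 300)]`` yields the 44-frame, 60-min protocol
    commonly used for dynamic FDG mouse scans.
    """
    durations: list[float] = []
    for count, dur in spec:
        if count < 0:
            raise ValidationError(f"frame count must be >= 0, got {count}")
        if dur <= 0:
            raise ValidationError(f"frame duration must be > 0, got {dur}")
        durations.extend([float(dur)] * int(count))
    dur_arr = np.asarray(durations, dtype=float)
    starts = np.concatenate(([0.0], np.cumsum(dur_arr)[:-1])) if len(dur_arr) else np.empty(0)
    return FrameSchedule(starts, dur_arr)


def truncate_schedule(schedule: FrameSchedule, t_max_s: float) -> FrameSchedule:
    """Keep exactly the frames whose end time is <= ``t_max_s``.

    Truncating the 44-frame protocol at 45 min (2700 s) drops the last three
    300-s frames and leaves 41 frames.
    """
    if t_max_s <= 0:
        raise ValidationError("t_max_s must be > 0")
    keep = schedule.end_s <= t_max_s + 1e-9
    return FrameSchedule(schedule.start_s[keep], schedule.duration_s[keep])


@dataclass(frozen=True)
class ScanMeta:
    """Per-scan metadata needed for SUV normalization and bookkeeping."""

    injected_dose_MBq: float
    body_weight_g: float
    injection_start_s: float = 0.0
    strain_label: str = ""
    scan_id: str = ""

    def __post_init__(self) -> None:
        if self.injected_dose_MBq <= 0:
            raise ValidationError("injected dose must be > 0")
        if self.body_weight_g <= 0:
            raise ValidationError("body weight must be > 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanMeta":
        return cls(**json.loads(Path(path).read_text()))


def suv_normalize(activity_kBq_per_ml: np.ndarray, meta: ScanMeta) -> np.ndarray:
    """Convert an activity concentration [kBq/ml] to SUV [g/ml].

    SUV = concentration / (injected dose / body weight); with the dose in MBq
    and weight in grams the normalizer is ``dose_MBq * 1000 / weight_g`` in
    kBq/g, so e.g. 500 kBq/ml at 10 MBq / 20 g gives SUV 1.0.
    """
    norm = meta.injected_dose_MBq * 1000.0 / meta.body_weight_g  # kBq/g
    return np.asarray(activity_kBq_per_ml, dtype=float) / norm


@dataclass(frozen=True)
class TimeActivityCurve:
    """An SUV-vs-time curve sampled at frame midpoints."""

    t_s: np.ndarray
    value_suv: np.ndarray
    kind: str = "tissue"  # blood | tissue | predicted

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        v = np.asarray(self.value_suv, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValidationError("t_s and value_suv must be 1-D and equal length")
        if not np.all(np.isfinite(v)):
            raise ValidationError("TAC values must be finite")
        if self.kind not in ("blood", "tissue", "predicted"):
            raise ValidationError(f"unknown TAC kind {self.kind!r}")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "value_suv", v)

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def t_min(self) -> np.ndarray:
        return self.t_s / 60.0

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t_s": self.t_s, "value_suv": self.value_suv}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "tissue") -> "TimeActivityCurve":
        df = pd.read_csv(path)
        missing = {"t_s", "value_suv"} - set(df.columns)
        if missing:
            raise SchemaError(f"TAC CSV missing columns: {sorted(missing)}")
        return cls(df["t_s"].to_numpy(float), df["value_suv"].to_numpy(float), kind=kind)


# An input function is just a blood TAC; keep the domain name available.
InputFunction = TimeActivityCurve


@dataclass
class DynamicImage:
    """A 4-D SUV volume sequence aligned to a :class:`FrameSchedule`.

    ``voxels`` is ``(T, X, Y, Z)`` with T equal to the number of frames.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    schedule: FrameSchedule
    meta: ScanMeta | None = None

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float32)
        if vox.ndim != 4:
            raise ValidationError("voxels must be 4-D (T, X, Y, Z)")
        if vox.shape[0] != len(self.schedule):
            raise ValidationError(
                f"number of frames {vox.shape[0]} != schedule length {len(self.schedule)}"
            )
        if not np.all(np.isfinite(vox)):
            raise ValidationError("voxel values must be finite")
        if np.any(vox < 0):
            raise ValidationError("voxel values must be >= 0")
        self.voxels = vox
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]


def write_dynamic_nifti(img: DynamicImage, path: str | Path) -> None:
    """Write a dynamic image as 4-D NIfTI, X-Y-Z-T on disk, float32."""
    data = np.moveaxis(img.voxels, 0, -1).astype(np.float32)
    affine = np.diag([*img.spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_dynamic_nifti(
    path: str | Path, schedule: FrameSchedule, meta: ScanMeta | None = None
) -> DynamicImage:
    """Read a 4-D NIfTI whose 4th dimension matches the schedule length."""
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise SchemaError(f"expected a 4-D image, got {data.ndim}-D")
    if data.shape[-1] != len(schedule):
        raise SchemaError(
            f"4th dimension {data.shape[-1]} != schedule length {len(schedule)}"
        )
    spacing = tuple(float(z) for z in nii.header.get_zooms()[:3])
    return DynamicImage(np.moveaxis(data, -1, 0), spacing, schedule, meta)


def crop_center(img: DynamicImage, shape: tuple[int, int, int]) -> DynamicImage:
    """Spatial center crop; offsets round down for odd margins (0-based)."""
    src = img.spatial_shape
    if any(t > s for t, s in zip(shape, src)):
        raise ValidationError(f"crop shape {shape} exceeds source shape {src}")
    off = [(s - t) // 2 for s, t in zip(src, shape)]
    sl = tuple(slice(o, o + t) for o, t in zip(off, shape))
    return DynamicImage(img.voxels[(slice(None), *sl)], img.spacing_mm, img.schedule, img.meta)
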