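"""Dynamic-acquisition time grids and time-activity curves.

A dynamic cardiac PET acquisition is reconstructed into a short sequence of
time frames ("framesets").  The clinical default used throughout this
package is a 1 s trigger delay followed by 12 x 10 s, 2 x 30 s, 2 x 60 s and
1 x 120 s frames (17 frames spanning 421 s); the coarse 10 s early frames
are exactly what makes transit-time estimation a discretization problem.

The module houses the frame schedule, the in-memory containers for dynamic
volumes / VOI masks, and SUV_mean time-activity-curve extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyVOIError, GeometryError, ParameterError, ScheduleError

__all__ = [
    "FrameSchedule",
    "DynamicPETImage",
    "VOIMask",
    "TimeActivityCurve",
    "make_frame_schedule",
    "extract_tac",
    "DEFAULT_FRAME_SPEC",
    "DEFAULT_DELAY_S",
]

#: Vendor-default dynamic frameset of the Rb-82 protocol: (count, duration s).
DEFAULT_FRAME_SPEC: tuple[tuple[int, float], ...] = ((12, 10.0), (2, 30.0), (2, 60.0), (1, 120.0))
#: Trigger delay before the first frame, seconds.
DEFAULT_DELAY_S: float = 1.0


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous time grid of a dynamic acquisition.

    Parameters
    ----------
    delay
        Seconds between scan start and the first frame.
    starts, durations
        Per-frame start times and lengths, seconds.  Frames must be
        contiguous: ``starts[k+1] == starts[k] + durations[k]`` and
        ``starts[0] == delay``.
    """

    delay: float
    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if self.delay < 0:
            raise ScheduleError(f"delay must be >= 0, got {self.delay}")
        if starts.ndim != 1 or starts.shape != durations.shape or starts.size == 0:
            raise ScheduleError("starts/durations must be matching non-empty 1-D arrays")
        if np.any(durations <= 0):
            raise ScheduleError("all frame durations must be > 0")
        if not np.isclose(starts[0], self.delay):
            raise ScheduleError("first frame must start at the delay")
        if not np.allclose(starts[1:], starts[:-1] + durations[:-1]):
            raise ScheduleError("frames must be contiguous")

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def midpoints(self) -> np.ndarray:
        """Frame midpoints, seconds."""
        return self.starts + self.durations / 2.0

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def span(self) -> tuple[float, float]:
        """(first frame start, last frame end) in seconds."""
        return float(self.starts[0]), float(self.ends[-1])

    def to_spec(self) -> list[tuple[int, float]]:
        """Run-length encode back to ``[(count, duration), ...]``."""
        spec: list[tuple[int, float]] = []
        for d in self.durations:
            if spec and np.isclose(spec[-1][1], d):
                spec[-1] = (spec[-1][0] + 1, spec[-1][1])
            else:
                spec.append((1, float(d)))
        return spec


def make_frame_schedule(
    spec: Sequence[tuple[int, float]] = DEFAULT_FRAME_SPEC,
    delay: float = DEFAULT_DELAY_S,
) -> FrameSchedule:
    """Build a contiguous :class:`FrameSchedule` from a run-length spec.

    ``spec`` is a list of ``(count, duration_s)`` pairs; the default is the
    clinical Rb-82 frameset (17 frames, ending at 421 s).
    """
    if delay < 0:
        raise ScheduleError(f"delay must be >= 0, got {delay}")
    durations: list[float] = []
    for count, dur in spec:
        if int(count) != count or count < 1:
            raise ScheduleError(f"frame count must be a positive integer, got {count}")
        if dur <= 0:
            raise ScheduleError(f"frame duration must be > 0, got {dur}")
        durations.extend([float(dur)] * int(count))
    if not durations:
        raise ScheduleError("empty frame specification")
    durations_arr = np.asarray(durations)
    starts = delay + np.concatenate([[0.0], np.cumsum(durations_arr[:-1])])
    return FrameSchedule(delay=float(delay), starts=starts, durations=durations_arr)


@dataclass
class DynamicPETImage:
    """4-D dynamic PET volume with the metadata needed for SUV scaling.

    ``voxels`` holds activity concentration in kBq/mL on an
    ``(x, y, z, frame)`` grid; ``voxel_size`` is in mm.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    schedule: FrameSchedule
    injected_dose_MBq: float
    patient_weight_kg: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise GeometryError(f"dynamic image must be 4-D, got {self.voxels.ndim}-D")
        if self.voxels.shape[3] != len(self.schedule):
            raise GeometryError(
                f"frame axis length {self.voxels.shape[3]} != schedule length {len(self.schedule)}"
            )
        if not np.all(np.isfinite(self.voxels)):
            raise ParameterError("voxel values must be finite")
        if self.injected_dose_MBq <= 0:
            raise ParameterError(f"injected dose must be > 0, got {self.injected_dose_MBq}")
        if self.patient_weight_kg <= 0:
            raise ParameterError(f"patient weight must be > 0, got {self.patient_weight_kg}")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def suv_factor(self) -> float:
        """Multiplier taking kBq/mL to body-weight SUV.

        SUV = conc[kBq/mL] * weight[kg] / dose[MBq] under the standard
        1 g/mL tissue-density convention (kBq/mL == kBq/g).
        """
        return self.patient_weight_kg / self.injected_dose_MBq



@dataclass
class VOIMask:
    """Binary volume of interest on the image grid.

    ``nominal_volume_cm3`` records the intended VOI size (the clinical
    protocol uses standardized 1 cm^3 cavity VOIs); the realized voxelized
    volume may differ slightly.
    """

    voxels: np.ndarray
    nominal_volume_cm3: float = 1.0

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise GeometryError(f"mask must be 3-D, got {vox.ndim}-D")
        if not np.isin(vox, (0, 1)).all():
            warnings.warn(
                "mask values outside {0,1}; binarizing with a 0.5 threshold",
                stacklevel=2,
            )
            vox = vox > 0.5
        self.voxels = vox.astype(bool)
        if not self.voxels.any():
            raise EmptyVOIError("mask contains no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class TimeActivityCurve:
    """SUV_mean per frame at the frame midpoints."""

    midpoints: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.midpoints = np.asarray(self.midpoints, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.midpoints.shape != self.values.shape or self.midpoints.ndim != 1:
            raise GeometryError("midpoints and values must be matching 1-D arrays")
        if np.any(np.diff(self.midpoints) <= 0):
            raise GeometryError("midpoints must be strictly increasing")
        if np.any(self.values < 0):
            raise GeometryError("SUV values must be >= 0")

    def __len__(self) -> int:
        return int(self.values.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"midpoint_s": self.midpoints, "suv_mean": self.values, "label": self.label}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeActivityCurve":
        df = pd.read_csv(path)
        label = str(df["label"].iloc[0]) if "label" in df and len(df) else ""
        return cls(df["midpoint_s"].to_numpy(), df["suv_mean"].to_numpy(), label=label)


def extract_tac(image: DynamicPETImage, mask: VOIMask, label: str = "") -> TimeActivityCurve:
    """Extract the SUV_mean time-activity curve of a VOI.

    For each frame the masked voxel concentrations are averaged and scaled
    to body-weight SUV.  The mask must live on the image's spatial grid;
    no resampling is performed.
    """
    if mask.voxels.shape != image.spatial_shape:
        raise GeometryError(
            f"mask grid {mask.voxels.shape} does not match image grid {image.spatial_shape}"
        )
    means = image.voxels[mask.voxels, :].mean(axis=0)
    return TimeActivityCurve(
        midpoints=image.schedule.midpoints,
        values=means * image.suv_factor,
        label=label,
    )
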