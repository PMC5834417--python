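"""Dynamic-image / TAC input-output and regional extraction.

This module owns the basic time containers of the package:

* :class:`FrameSchedule` — the acquisition frame grid, in minutes
  post-injection, half-open intervals ``[start, end)``.
* :class:`TimeActivityCurve` — one region's frame-averaged activity
  concentration (kBq/mL).
* :class:`RegionalTACSet` — all regional TACs of one subject/tracer with a
  designated reference region.

Volumes are exchanged as NIfTI-1 (via nibabel) or plain numpy arrays; TAC
tables as tidy CSV with one row per (subject, tracer, region, frame).
The package never re-registers images: dynamic image and atlas must share
one voxel grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FrameSchedule",
    "FineCurve",
    "TimeActivityCurve",
    "RegionalTACSet",
    "extract_tacs",
    "read_tac_table",
    "write_tac_table",
    "load_dynamic_image",
    "save_dynamic_image",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Frame start/end times in minutes post-injection.

    Frames are half-open intervals ``[start, end)``; they must be
    non-overlapping and in increasing order. Gaps are permitted (they occur
    after truncation or frame dropping) but the default schedules are
    contiguous.
    """

    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        ends = np.asarray(self.ends, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.ndim != 1 or starts.shape != ends.shape or starts.size == 0:
            raise ValueError("starts and ends must be equal-length 1-D arrays")
        if starts[0] < 0:
            raise ValueError(f"first frame starts before injection: {starts[0]} min")
        if not np.all(np.diff(starts) > 0):
            raise ValueError("frame starts must be strictly increasing")
        if not np.all(ends > starts):
            bad = int(np.argmax(~(ends > starts)))
            raise ValueError(
                f"frame {bad} has end {ends[bad]} <= start {starts[bad]}"
            )
        if np.any(starts[1:] < ends[:-1] - 1e-9):
            raise ValueError("frames overlap")

    @classmethod
    def from_durations(cls, durations_s: Sequence[float], start: float = 0.0) -> "FrameSchedule":
        """Build a contiguous schedule from frame durations in *seconds*."""
        d = np.asarray(durations_s, dtype=float) / 60.0
        edges = start + np.concatenate([[0.0], np.cumsum(d)])
        return cls(edges[:-1], edges[1:])

    @property
    def n_frames(self) -> int:
        return self.starts.size

    @property
    def durations(self) -> np.ndarray:
        """Frame durations in minutes."""
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def total_end(self) -> float:
        return float(self.ends[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return (
            self.starts.shape == other.starts.shape
            and np.allclose(self.starts, other.starts)
            and np.allclose(self.ends, other.ends)
        )

    def __hash__(self) -> int:
        return hash((self.starts.tobytes(), self.ends.tobytes()))

    def truncated(self, duration: float) -> "FrameSchedule":
        """Keep only frames fully contained in ``[0, duration]``.

        Frames straddling the cut are dropped, not clipped.
        """
        keep = self.ends <= duration + 1e-9
        if not np.any(keep):
            raise ValueError(f"no frame fully inside [0, {duration}] min")
        return FrameSchedule(self.starts[keep], self.ends[keep])


@dataclass(frozen=True)
class FineCurve:
    """Continuous-time curve sampled on a uniform fine grid (minutes).

    The simulator carries this alongside frame averages so downstream
    convolutions do not pay an interpolation penalty. ``times[0]`` is 0.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape:
            raise ValueError("times/values shape mismatch")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class TimeActivityCurve:
    """Frame-averaged activity concentration of one region.

    ``fine`` optionally holds the underlying continuous curve when the TAC
    came out of the simulator; model fitting uses it when present and falls
    back to interpolating the frame values otherwise.
    """

    schedule: FrameSchedule
    values: np.ndarray
    region: str = ""
    fine: FineCurve | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"expected {self.schedule.n_frames} frame values, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite activity values in region {self.region!r}")

    def truncated(self, duration: float) -> "TimeActivityCurve":
        sched = self.schedule.truncated(duration)
        return TimeActivityCurve(
            sched, self.values[: sched.n_frames], self.region, self.fine
        )

    def scaled(self, factor: float) -> "TimeActivityCurve":
        fine = None
        if self.fine is not None:
            fine = FineCurve(self.fine.times, self.fine.values * factor)
        return TimeActivityCurve(self.schedule, self.values * factor, self.region, fine)


@dataclass
class RegionalTACSet:
    """All regional TACs of one subject and tracer."""

    subject: str
    tracer: str
    tacs: dict[str, TimeActivityCurve]
    reference_region: str

    def __post_init__(self) -> None:
        if self.reference_region not in self.tacs:
            raise ValueError(
                f"reference region {self.reference_region!r} missing from TACs "
                f"(have {sorted(self.tacs)})"
            )
        schedules = {tac.schedule for tac in self.tacs.values()}
        if len(schedules) > 1:
            raise ValueError(
                f"subject {self.subject!r} tracer {self.tracer!r}: "
                "TACs do not share one frame schedule"
            )

    @property
    def schedule(self) -> FrameSchedule:
        return next(iter(self.tacs.values())).schedule

    @property
    def reference(self) -> TimeActivityCurve:
        return self.tacs[self.reference_region]

    @property
    def regions(self) -> list[str]:
        return sorted(self.tacs)

    def targets(self) -> dict[str, TimeActivityCurve]:
        return {r: t for r, t in self.tacs.items() if r != self.reference_region}

    def truncated(self, duration: float) -> "RegionalTACSet":
        return RegionalTACSet(
            self.subject,
            self.tracer,
            {r: t.truncated(duration) for r, t in self.tacs.items()},
            self.reference_region,
        )


def _as_array(img) -> np.ndarray:
    if isinstance(img, np.ndarray):
        return img
    return np.asanyarray(img.dataobj)


def extract_tacs(
    dynamic_image,
    schedule: FrameSchedule,
    atlas,
    region_names: Mapping[int, str],
    subject: str = "",
    tracer: str = "",
    reference_region: str | None = None,
) -> RegionalTACSet | dict[str, TimeActivityCurve]:
    """Extract regional TACs from a labelled 4-D dynamic image.

    Each region's TAC is the unweighted mean over the voxels carrying its
    label, per frame. ``dynamic_image`` and ``atlas`` may be numpy arrays or
    nibabel images on the same voxel grid. Labels present in ``region_names``
    but absent from the atlas are skipped with a warning. Label 0 is
    background and never extracted.

    Returns a :class:`RegionalTACSet` when ``reference_region`` is given,
    otherwise a plain region→TAC dict.
    """
    dyn = _as_array(dynamic_image)
    lab = _as_array(atlas).astype(int)
    if dyn.ndim != 4:
        raise ValueError(f"dynamic image must be 4-D, got shape {dyn.shape}")
    if lab.shape != dyn.shape[:3]:
        raise ValueError(
            f"atlas grid {lab.shape} does not match image grid {dyn.shape[:3]}"
        )
    if dyn.shape[3] != schedule.n_frames:
        raise ValueError(
            f"image has {dyn.shape[3]} frames but schedule has {schedule.n_frames}"
        )
    if not np.any(lab > 0):
        raise ValueError("atlas contains no non-zero labels")

    flat = dyn.reshape(-1, dyn.shape[3])
    lab_flat = lab.ravel()
    tacs: dict[str, TimeActivityCurve] = {}
    for label, name in region_names.items():
        mask = lab_flat == int(label)
        n_vox = int(mask.sum())
        if n_vox == 0:
            logger.warning("label %d (%s): no voxels in atlas, region omitted", label, name)
            continue
        tacs[name] = TimeActivityCurve(schedule, flat[mask].mean(axis=0), region=name)
    if reference_region is None:
        return tacs
    return RegionalTACSet(subject, tracer, tacs, reference_region)


_TAC_COLUMNS = [
    "subject",
    "tracer",
    "region",
    "frame_start",
    "frame_end",
    "activity",
    "reference_region",
]


def write_tac_table(tac_sets: Sequence[RegionalTACSet], path) -> pd.DataFrame:
    """Write TAC sets as tidy CSV (one row per subject/tracer/region/frame)."""
    rows = []
    for ts in tac_sets:
        for region in ts.regions:
            tac = ts.tacs[region]
            for s, e, v in zip(tac.schedule.starts, tac.schedule.ends, tac.values):
                rows.append((ts.subject, ts.tracer, region, s, e, v, ts.reference_region))
    df = pd.DataFrame(rows, columns=_TAC_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_tac_table(path) -> list[RegionalTACSet]:
    """Read the tidy TAC CSV back into :class:`RegionalTACSet` objects.

    Validates frame ordering, per-subject schedule consistency and reference
    region presence; raises descriptive errors on malformed tables.
    """
    df = pd.read_csv(path)
    missing = set(_TAC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TAC table missing columns: {sorted(missing)}")
    if np.any(df["frame_end"].to_numpy() <= df["frame_start"].to_numpy()):
        bad = df[df["frame_end"] <= df["frame_start"]].iloc[0]
        raise ValueError(
            f"frame with end {bad.frame_end} <= start {bad.frame_start} "
            f"(subject {bad.subject}, region {bad.region})"
        )
    out: list[RegionalTACSet] = []
    for (subject, tracer), grp in df.groupby(["subject", "tracer"], sort=True):
        refs = grp["reference_region"].unique()
        if len(refs) != 1:
            raise ValueError(
                f"subject {subject} tracer {tracer}: conflicting reference regions {refs}"
            )
        tacs: dict[str, TimeActivityCurve] = {}
        schedule: FrameSchedule | None = None
        for region, rg in grp.groupby("region", sort=True):
            rg = rg.sort_values("frame_start")
            sched = FrameSchedule(rg["frame_start"].to_numpy(), rg["frame_end"].to_numpy())
            if schedule is None:
                schedule = sched
            elif sched != schedule:
                raise ValueError(
                    f"subject {subject} tracer {tracer}: region {region} has a "
                    "different frame schedule than its siblings"
                )
            tacs[str(region)] = TimeActivityCurve(
                schedule, rg["activity"].to_numpy(), region=str(region)
            )
        out.append(RegionalTACSet(str(subject), str(tracer), tacs, str(refs[0])))
    return out


def save_dynamic_image(data: np.ndarray, path, schedule: FrameSchedule | None = None,
                       affine: np.ndarray | None = None) -> None:
    """Write a 3-D/4-D volume as NIfTI-1; optionally a frame-timing CSV beside it."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
    if schedule is not None:
        timing = pd.DataFrame(
            {"frame_start": schedule.starts, "frame_end": schedule.ends}
        )
        timing.to_csv(Path(path).with_suffix("").with_suffix(".timing.csv"), index=False)


def load_dynamic_image(path, timing_path=None):
    """Load a NIfTI volume; return ``(array, FrameSchedule | None)``."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    schedule = None
    if timing_path is None:
        cand = Path(path).with_suffix("").with_suffix(".timing.csv")
        timing_path = cand if cand.exists() else None
    if timing_path is not None:
        t = pd.read_csv(timing_path)
        schedule = FrameSchedule(t["frame_start"].to_numpy(), t["frame_end"].to_numpy())
    return data, schedule
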