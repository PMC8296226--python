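"""Staff movement data model, I/O, resampling, phase slicing and descriptive
speed statistics.

The core container is :class:`Trajectory`: the time-ordered planar (plus z)
positions of one tagged staff member within one surgical case, in millimetres
and seconds from case start.  Operating-room staff are one of four roles
(anesthetist, assistant nurse, scrub nurse, surgeon) and a case is annotated
with six ordered surgical phases.  All analytics downstream assume tracks have
been resampled to a uniform 1 Hz grid, at which the distance between two
consecutive samples is interpretable as speed (mm/s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four staff roles tracked in the operating room.
ROLES = ("anesthetist", "assistant_nurse", "scrub_nurse", "surgeon")

#: The six surgical phases of an intraoperative-MRI neurosurgery.
PHASES = ("Preparation", "Craniotomy", "Close", "MRI", "TR", "End")

TRACK_COLUMNS = ["case_id", "role", "tag_id", "t", "x", "y", "z"]
PHASE_COLUMNS = ["case_id", "phase", "t_start", "t_end"]


class FormatError(ValueError):
    """Raised when an input file does not have the expected columns."""


class ValidationError(ValueError):
    """Raised when file contents violate the data model."""


@dataclass(frozen=True)
class PhaseInterval:
    """A labeled, half-open time window ``[t_start, t_end)`` of one phase."""

    case_id: str
    phase: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if not self.t_start < self.t_end:
            raise ValidationError(
                f"phase interval must satisfy t_start < t_end, got [{self.t_start}, {self.t_end})"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def contains(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


@dataclass
class Trajectory:
    """Time-ordered positions of one staff member in one case.

    Timestamps are seconds from case start (strictly increasing); coordinates
    are millimetres.  ``z`` is carried through I/O but ignored by the planar
    analytics.
    """

    case_id: str
    role: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray = None  # type: ignore[assignment]
    tag_id: str = "0"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.z is None:
            self.z = np.zeros_like(self.x)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValidationError("t, x, y, z must have equal length")
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if n:
            if np.any(self.t < 0):
                raise ValidationError("timestamps must be non-negative")
            if np.any(np.diff(self.t) <= 0):
                i = int(np.flatnonzero(np.diff(self.t) <= 0)[0])
                raise ValidationError(
                    f"timestamps must be strictly increasing; violation at sample {i + 1} "
                    f"(t={self.t[i + 1]!r} after t={self.t[i]!r}) for "
                    f"case={self.case_id!r} role={self.role!r} tag={self.tag_id!r}"
                )
            for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
                if not np.all(np.isfinite(arr)):
                    raise ValidationError(f"non-finite {name} coordinate in trajectory")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) planar coordinates."""
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": self.case_id,
                "role": self.role,
                "tag_id": self.tag_id,
                "t": self.t,
                "x": self.x,
                "y": self.y,
                "z": self.z,
            }
        )


# ---------------------------------------------------------------------------
# File I/O.  Track file: CSV with columns case_id,role,tag_id,t,x,y,z
# (seconds / millimetres).  Phase file: CSV with case_id,phase,t_start,t_end.
# ---------------------------------------------------------------------------

def read_tracks(path) -> list[Trajectory]:
    """Read a track CSV into trajectories grouped by (case, role, tag).

    Rows are sorted by time within each group; unknown role strings and
    non-increasing duplicate timestamps raise errors naming the offender.
    """
    df = pd.read_csv(
        path,
        dtype={"case_id": str, "role": str, "tag_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"track file {path} is missing columns {missing}")
    bad = sorted(set(df["role"]) - set(ROLES))
    if bad:
        raise ValidationError(f"track file {path} contains unknown roles {bad}")
    out: list[Trajectory] = []
    for (case_id, role, tag_id), grp in df.groupby(
        ["case_id", "role", "tag_id"], sort=True
    ):
        grp = grp.sort_values("t", kind="stable")
        out.append(
            Trajectory(
                case_id=case_id,
                role=role,
                tag_id=tag_id,
                t=grp["t"].to_numpy(),
                x=grp["x"].to_numpy(),
                y=grp["y"].to_numpy(),
                z=grp["z"].to_numpy(),
            )
        )
    return out


def write_tracks(trajectories, path) -> None:
    """Write trajectories to a track CSV (exact float round-trip).

    Rows are written in the canonical (case, role, tag) order used by
    :func:`read_tracks`, so write -> read -> write is bit-identical.
    """
    ordered = sorted(trajectories, key=lambda tr: (tr.case_id, tr.role, tr.tag_id))
    frames = [traj.to_frame() for traj in ordered]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRACK_COLUMNS)
    )
    df.to_csv(path, index=False)


def read_phases(path) -> list[PhaseInterval]:
    df = pd.read_csv(
        path, dtype={"case_id": str, "phase": str}, float_precision="round_trip"
    )
    missing = [c for c in PHASE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"phase file {path} is missing columns {missing}")
    return [
        PhaseInterval(row.case_id, row.phase, float(row.t_start), float(row.t_end))
        for row in df.itertuples()
    ]


def write_phases(intervals, path) -> None:
    df = pd.DataFrame(
        [
            {
                "case_id": iv.case_id,
                "phase": iv.phase,
                "t_start": iv.t_start,
                "t_end": iv.t_end,
            }
            for iv in intervals
        ],
        columns=PHASE_COLUMNS,
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Resampling and slicing
# ---------------------------------------------------------------------------

def split_on_gaps(traj: Trajectory, max_gap_s: float = 5.0) -> list[Trajectory]:
    """Split a trajectory wherever consecutive samples are more than
    ``max_gap_s`` apart (tag dropout).  Interpolating across such gaps would
    fabricate movement, so each contiguous run becomes its own trajectory."""
    if len(traj) < 2:
        return [traj]
    breaks = np.flatnonzero(np.diff(traj.t) > max_gap_s) + 1
    if breaks.size == 0:
        return [traj]
    pieces = []
    for lo, hi in zip(np.r_[0, breaks], np.r_[breaks, len(traj)]):
        pieces.append(
            replace(
                traj,
                t=traj.t[lo:hi],
                x=traj.x[lo:hi],
                y=traj.y[lo:hi],
                z=traj.z[lo:hi],
            )
        )
    return pieces


def resample(traj: Trajectory, interval_s: float = 1.0) -> Trajectory:
    """Resample to a uniform grid ``t0, t0+interval, ...`` by linear
    interpolation, never extrapolating beyond the observed time span."""
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    if len(traj) < 2:
        raise ValidationError("cannot resample a trajectory with fewer than 2 points")
    t0, t1 = traj.t[0], traj.t[-1]
    n = int(np.floor((t1 - t0) / interval_s + 1e-9)) + 1
    grid = t0 + interval_s * np.arange(n)
    return replace(
        traj,
        t=grid,
        x=np.interp(grid, traj.t, traj.x),
        y=np.interp(grid, traj.t, traj.y),
        z=np.interp(grid, traj.t, traj.z),
    )


def slice_by_phase(
    traj: Trajectory, intervals: list[PhaseInterval]
) -> dict[PhaseInterval, Trajectory]:
    """Partition a trajectory into per-phase segments.

    Each segment holds exactly the points with ``t_start <= t < t_end``
    (half-open, so a point at a boundary belongs to the following interval).
    A role absent during a phase yields an empty segment, preserved as such.
    """
    out: dict[PhaseInterval, Trajectory] = {}
    for iv in intervals:
        if iv.case_id != traj.case_id:
            raise ValidationError(
                f"interval case {iv.case_id!r} does not match trajectory case {traj.case_id!r}"
            )
        mask = (traj.t >= iv.t_start) & (traj.t < iv.t_end)
        out[iv] = replace(
            traj, t=traj.t[mask], x=traj.x[mask], y=traj.y[mask], z=traj.z[mask]
        )
    return out


def step_distances(traj: Trajectory) -> np.ndarray:
    """Planar (x, y) Euclidean distance between consecutive samples.

    On a 1 Hz grid this is speed in mm/s.  Fewer than 2 points gives an
    empty array.
    """
    if len(traj) < 2:
        return np.empty(0)
    return np.hypot(np.diff(traj.x), np.diff(traj.y))


# ---------------------------------------------------------------------------
# Speed distributions (descriptive statistics)
# ---------------------------------------------------------------------------

GROUPINGS = ("by_phase", "by_role", "by_phase_role")


@dataclass
class GroupDensity:
    """Normalized step-distance histogram for one group."""

    bin_edges: np.ndarray
    density: np.ndarray  # sums to 1 over bins
    mode: float  # centre of the highest-density bin (the distribution's peak)
    mean: float
    n: int


@dataclass
class SpeedDistribution:
    grouping: str
    groups: dict = field(default_factory=dict)


def speed_distribution(
    segments: dict[PhaseInterval, dict[str, Trajectory]] | list,
    grouping: str = "by_phase",
    n_bins: int = 40,
) -> SpeedDistribution:
    """Normalized step-distance (speed) histograms per group.

    ``segments`` is either a mapping interval -> {role: trajectory segment}
    or an iterable of ``(phase, role, trajectory)`` triples.  ``grouping`` is
    one of ``by_phase``, ``by_role``, ``by_phase_role``.  Both the histogram
    mode (the peak) and the mean are reported per group; empty groups are
    omitted with a warning.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    triples = []
    if isinstance(segments, dict):
        for iv, by_role in segments.items():
            for role, seg in by_role.items():
                triples.append((iv.phase, role, seg))
    else:
        triples = list(segments)

    pooled: dict = {}
    for phase, role, seg in triples:
        if grouping == "by_phase":
            key = phase
        elif grouping == "by_role":
            key = role
        else:
            key = (phase, role)
        pooled.setdefault(key, []).append(step_distances(seg))

    dist = SpeedDistribution(grouping=grouping)
    for key in sorted(pooled, key=str):
        d = np.concatenate(pooled[key]) if pooled[key] else np.empty(0)
        if d.size == 0:
            logger.warning("speed_distribution: empty group %r omitted", key)
            continue
        hi = float(d.max())
        edges = np.linspace(0.0, hi if hi > 0 else 1.0, n_bins + 1)
        counts, edges = np.histogram(d, bins=edges)
        density = counts / counts.sum()
        centres = 0.5 * (edges[:-1] + edges[1:])
        dist.groups[key] = GroupDensity(
            bin_edges=edges,
            density=density,
            mode=float(centres[int(np.argmax(density))]),
            mean=float(d.mean()),
            n=int(d.size),
        )
    return dist
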