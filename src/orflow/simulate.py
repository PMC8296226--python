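"""Synthetic operating-room movement generator.

Emulates ultrasonic indoor-tracking recordings of a four-role neurosurgical
team (anesthetist, assistant nurse, scrub nurse, surgeon) in a 5.8 x 4.8 m
room, with six ordered surgical phases, ~80 mm positional measurement noise
and 1 Hz analysis sampling.

The movement model is deliberately simple: while present, each role performs
a mean-reverting (AR(1) / discrete Ornstein-Uhlenbeck) walk around a
role-specific activity-zone anchor; pairwise *cooperation* is injected as
rendezvous events during which both members of a pair are steered to a shared
waypoint for a sampled dwell time.  Rendezvous frequency scales with the
configured cooperation intensity of the (pair, phase), which is what makes
trajectory similarity (LCSS) phase-dependent downstream.  The default
cooperation table encodes the qualitative structure of the study system:
surgeon-scrub-nurse cooperation high during Craniotomy and tumor resection
(TR), low during Preparation and End; scrub nurses rarely present during
Preparation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .movement import PhaseInterval, Trajectory, write_phases, write_tracks


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) key for an unordered role pair."""
    return tuple(sorted((a, b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class RoleZone:
    """Activity zone of one role: anchor point (mm) and stationary spread."""

    anchor: tuple[float, float]
    dispersion: float  # stationary s.d. of the mean-reverting walk, mm


@dataclass(frozen=True)
class PhaseTemplate:
    """One phase occurrence in the schedule: mean duration and spread."""

    phase: str
    mean_duration_s: float = 180.0
    cv: float = 0.25  # coefficient of variation of the gamma-distributed duration


def default_role_zones() -> dict[str, RoleZone]:
    # Surgeon and scrub nurse at the room centre (surgeon's activity space is
    # the largest, the scrub nurse's the smallest); assistant nurse works the
    # bottom of the room and the tool table; anesthetist sits upper-right.
    return {
        "surgeon": RoleZone((2900.0, 2400.0), 1100.0),
        "assistant_nurse": RoleZone((2900.0, 1100.0), 900.0),
        "scrub_nurse": RoleZone((2350.0, 2750.0), 300.0),
        "anesthetist": RoleZone((4900.0, 3900.0), 450.0),
    }


def default_schedule() -> list[PhaseTemplate]:
    # Preparation -> Craniotomy -> TR -> MRI -> TR -> Close -> End; an extra
    # MRI/TR imaging cycle may be inserted per case (see SimulationConfig).
    return [
        PhaseTemplate("Preparation", 600.0),
        PhaseTemplate("Craniotomy", 720.0),
        PhaseTemplate("TR", 840.0),
        PhaseTemplate("MRI", 600.0),
        PhaseTemplate("TR", 840.0),
        PhaseTemplate("Close", 660.0),
        PhaseTemplate("End", 480.0),
    ]


def default_cooperation() -> dict[tuple[tuple[str, str], str], float]:
    """Cooperation intensity in [0, 1] per (unordered pair, phase).

    Encodes the qualitative findings for the study system: frequent
    surgeon-scrub interaction in Craniotomy/TR, infrequent in End/Preparation;
    assistant nurses support the sterile team during Craniotomy/TR/Close;
    anesthetist-assistant contact peaks around imaging and turnover.
    """
    table = {
        # sterile operative work: surgeon-scrub separates the operative
        # phases (high in Craniotomy/TR, moderate around imaging and
        # closure, low in Preparation/End)
        ("scrub_nurse", "surgeon"): {
            "Preparation": 0.02, "Craniotomy": 0.90, "TR": 0.95,
            "MRI": 0.35, "Close": 0.40, "End": 0.05,
        },
        # circulating support of the surgeon: room setup and closure help,
        # some dressing work at the end, little during imaging
        ("assistant_nurse", "surgeon"): {
            "Preparation": 0.70, "Craniotomy": 0.05, "TR": 0.35,
            "MRI": 0.05, "Close": 0.70, "End": 0.35,
        },
        # patient positioning, imaging safety checks, emergence support
        ("anesthetist", "assistant_nurse"): {
            "Preparation": 0.05, "Craniotomy": 0.35, "TR": 0.05,
            "MRI": 0.70, "Close": 0.35, "End": 0.70,
        },
        # instrument supply during opening, final count and cleanup at the
        # end; tracks the sterile team's workload otherwise
        ("assistant_nurse", "scrub_nurse"): {
            "Preparation": 0.05, "Craniotomy": 0.80, "TR": 0.35,
            "MRI": 0.05, "Close": 0.35, "End": 0.80,
        },
        ("anesthetist", "surgeon"): {
            "Preparation": 0.05, "Craniotomy": 0.05, "TR": 0.05,
            "MRI": 0.30, "Close": 0.05, "End": 0.05,
        },
        ("anesthetist", "scrub_nurse"): {
            "Preparation": 0.02, "Craniotomy": 0.02, "TR": 0.02,
            "MRI": 0.02, "Close": 0.02, "End": 0.02,
        },
    }
    return {(pair, ph): v for pair, per in table.items() for ph, v in per.items()}


def default_presence() -> dict[tuple[str, str], float]:
    """Presence probability per (role, phase); unlisted pairs default to 1.

    Scrub nurses seldom appear during Preparation and leave early at End.
    """
    return {
        ("scrub_nurse", "Preparation"): 0.25,
        ("scrub_nurse", "End"): 0.85,
    }


def default_speed_scale() -> dict[str, float]:
    # Staff move slowest during Preparation and fastest around MRI transfers.
    return {
        "Preparation": 0.6, "Craniotomy": 1.1, "TR": 1.0,
        "MRI": 1.4, "Close": 1.0, "End": 0.9,
    }


@dataclass
class SimulationConfig:
    """All knobs of the synthetic OR.  Defaults encode the study conditions."""

    room_width: float = 5800.0  # x extent, mm
    room_depth: float = 4800.0  # y extent, mm
    landmarks: dict = field(
        default_factory=lambda: {"entrance": (4000.0, 0.0), "tool_table": (1000.0, 3000.0)}
    )
    role_zones: dict = field(default_factory=default_role_zones)
    phase_schedule: list = field(default_factory=default_schedule)
    #: probability that a case gets one extra MRI+TR imaging cycle, so that
    #: ten cases yield roughly 83 phase segments
    extra_imaging_cycle_prob: float = 0.65
    cooperation: dict = field(default_factory=default_cooperation)
    presence: dict = field(default_factory=default_presence)
    speed_scale: dict = field(default_factory=default_speed_scale)
    noise_sd: float = 80.0  # positional measurement noise s.d., mm
    sample_hz: float = 1.0
    # movement-model internals
    mean_reversion: float = 0.18  # per-step pull toward the goal
    rendezvous_rate_per_s: float = 0.18  # event hazard at intensity 1
    rendezvous_dwell_s: float = 5.0  # mean dwell at the shared waypoint
    rendezvous_dwell_min_s: float = 2.0
    rendezvous_reversion: float = 0.5  # stronger pull while steering to waypoint
    rendezvous_spread: float = 120.0  # s.d. of jitter around the waypoint, mm
    #: log-normal s.d. of a per-segment teamwork factor multiplying every
    #: pair's intensity: makes interaction levels co-vary within a segment
    team_coherence_sd: float = 0.0
    #: probability that the assistant nurse joins a surgeon-scrub rendezvous
    #: (tool transfer), coupling those interactions given the phase
    assistant_join_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.room_width <= 0 or self.room_depth <= 0:
            raise ConfigError("room dimensions must be positive")
        for role, zone in self.role_zones.items():
            ax, ay = zone.anchor
            if not (0 <= ax <= self.room_width and 0 <= ay <= self.room_depth):
                raise ConfigError(
                    f"anchor for {role!r} at {zone.anchor} lies outside the "
                    f"{self.room_width} x {self.room_depth} mm room"
                )
        for key, c in self.cooperation.items():
            if not 0.0 <= c <= 1.0:
                raise ConfigError(f"cooperation intensity {c} for {key} not in [0, 1]")
        for key, p in self.presence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"presence probability {p} for {key} not in [0, 1]")
        for tpl in self.phase_schedule:
            if tpl.mean_duration_s <= 0:
                raise ConfigError(f"non-positive duration for phase {tpl.phase!r}")

    def cooperation_for(self, a: str, b: str, phase: str) -> float:
        return self.cooperation.get((pair_key(a, b), phase), 0.0)

    def presence_for(self, role: str, phase: str) -> float:
        return self.presence.get((role, phase), 1.0)


@dataclass
class SyntheticCase:
    """One simulated operation: per-role tracks, phase annotation, ground truth."""

    case_id: str
    trajectories: dict[str, Trajectory]
    intervals: list[PhaseInterval]
    cooperation: dict  # (pair, phase) -> configured intensity
    seed: int


def _case_rng(master_seed: int, case_index: int) -> np.random.Generator:
    # counter-based derivation: stable under reordering/ subsetting of cases
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(case_index)]))


def generate_case(
    config: SimulationConfig, seed: int, case_id: str = "case01", _rng=None
) -> SyntheticCase:
    """Simulate one operation.  Pure function of (config, seed)."""
    config.validate()
    rng = _rng if _rng is not None else np.random.default_rng(int(seed))
    dt = 1.0 / config.sample_hz

    # --- schedule ------------------------------------------------------
    templates = list(config.phase_schedule)
    if config.extra_imaging_cycle_prob > 0 and rng.random() < config.extra_imaging_cycle_prob:
        # insert an extra imaging cycle before the last TR occurrence, if the
        # schedule has the canonical MRI/TR structure; otherwise append.
        extra = [PhaseTemplate("MRI", 160.0), PhaseTemplate("TR", 200.0)]
        tr_pos = [i for i, tpl in enumerate(templates) if tpl.phase == "TR"]
        at = tr_pos[-1] if tr_pos else len(templates)
        templates = templates[:at] + extra + templates[at:]

    intervals: list[PhaseInterval] = []
    seg_n: list[int] = []
    t_cursor = 0.0
    for tpl in templates:
        shape = 1.0 / (tpl.cv**2) if tpl.cv > 0 else None
        dur = (
            rng.gamma(shape, tpl.mean_duration_s / shape)
            if shape is not None
            else tpl.mean_duration_s
        )
        n = max(8, int(round(dur * config.sample_hz)))
        intervals.append(PhaseInterval(case_id, tpl.phase, t_cursor, t_cursor + n * dt))
        seg_n.append(n)
        t_cursor += n * dt
    n_total = sum(seg_n)
    seg_start = np.r_[0, np.cumsum(seg_n)][:-1]

    # --- presence ------------------------------------------------------
    roles = sorted(config.role_zones)
    present = {
        role: np.array(
            [rng.random() < config.presence_for(role, iv.phase) for iv in intervals]
        )
        for role in roles
    }

    # --- per-sample goals (zone anchor, overridden by rendezvous) ------
    goal = {}
    theta = {}
    sd = {}
    base_var = 1.0 - (1.0 - config.mean_reversion) ** 2
    for role in roles:
        zone = config.role_zones[role]
        goal[role] = np.tile(np.asarray(zone.anchor, dtype=float), (n_total, 1))
        theta[role] = np.empty(n_total)
        sd[role] = np.empty(n_total)
        for s, n, iv in zip(seg_start, seg_n, intervals):
            # scale step size (speed) per phase while keeping the stationary
            # spread of the walk equal to the zone dispersion: an AR(1) step
            # s.d. of dispersion*sqrt(f) with pull 1-sqrt(1-f) has stationary
            # s.d. = dispersion for any f in (0, 1].
            scale = config.speed_scale.get(iv.phase, 1.0)
            f = min(0.96, base_var * scale * scale)
            theta[role][s : s + n] = 1.0 - np.sqrt(1.0 - f)
            sd[role][s : s + n] = zone.dispersion * np.sqrt(f)

    busy = {role: np.zeros(n_total, dtype=bool) for role in roles}
    pairs = [(a, b) for i, a in enumerate(roles) for b in roles[i + 1 :]]
    for si, (s, n, iv) in enumerate(zip(seg_start, seg_n, intervals)):
        # per-segment teamwork coherence: one factor scales every pair's
        # intensity, so interaction levels co-vary within a segment
        team = (
            float(np.exp(rng.normal(0.0, config.team_coherence_sd)))
            if config.team_coherence_sd > 0
            else 1.0
        )
        # strongest cooperation gets first claim on the shared time budget
        ranked = sorted(
            pairs, key=lambda ab: (-config.cooperation_for(*ab, iv.phase), ab)
        )
        for a, b in ranked:
            c = min(1.0, config.cooperation_for(a, b, iv.phase) * team)
            if c <= 0 or not (present[a][si] and present[b][si]):
                continue
            anchor_a = np.asarray(config.role_zones[a].anchor)
            anchor_b = np.asarray(config.role_zones[b].anchor)
            k = 0
            while k < n:
                g = s + k
                if busy[a][g] or busy[b][g]:
                    k += 1
                    continue
                if rng.random() < config.rendezvous_rate_per_s * c * dt:
                    dwell = max(
                        config.rendezvous_dwell_min_s,
                        rng.exponential(config.rendezvous_dwell_s),
                    )
                    m = min(n - k, max(1, int(round(dwell * config.sample_hz))))
                    waypoint = 0.5 * (anchor_a + anchor_b) + rng.normal(
                        0.0, config.rendezvous_spread, size=2
                    )
                    waypoint = np.clip(
                        waypoint, [0.0, 0.0], [config.room_width, config.room_depth]
                    )
                    members = [a, b]
                    # assistant nurse may join surgeon-scrub cooperation
                    # (e.g. tool transfer), coupling those interactions
                    joiner = "assistant_nurse"
                    if (
                        {a, b} == {"scrub_nurse", "surgeon"}
                        and joiner in goal
                        and present.get(joiner, np.zeros(len(intervals), bool))[si]
                        and rng.random() < config.assistant_join_prob
                        and not busy[joiner][g : g + m].any()
                    ):
                        members.append(joiner)
                    for r in members:
                        goal[r][g : g + m] = waypoint
                        theta[r][g : g + m] = config.rendezvous_reversion
                        sd[r][g : g + m] = np.minimum(sd[r][g : g + m], 60.0)
                        busy[r][g : g + m] = True
                    k += m
                else:
                    k += 1

    # --- integrate the mean-reverting walk per role --------------------
    entrance = np.asarray(config.landmarks.get("entrance", (0.0, 0.0)), dtype=float)
    lo = np.array([0.0, 0.0])
    hi = np.array([config.room_width, config.room_depth])
    trajectories: dict[str, Trajectory] = {}
    for role in roles:
        ts: list[float] = []
        xs: list[np.ndarray] = []
        pos = np.asarray(config.role_zones[role].anchor, dtype=float).copy()
        started = False
        prev_present = False
        for si, (s, n, iv) in enumerate(zip(seg_start, seg_n, intervals)):
            if not present[role][si]:
                prev_present = False
                continue
            if started and not prev_present:
                pos = entrance.copy()  # mid-case re-entry through the door
            started = True
            steps = rng.normal(0.0, 1.0, size=(n, 2))
            for k in range(n):
                g = s + k
                pos = pos + theta[role][g] * (goal[role][g] - pos) + sd[role][g] * steps[k]
                pos = np.clip(pos, lo, hi)
                ts.append(iv.t_start + k * dt)
                xs.append(pos.copy())
            prev_present = True
        if not ts:
            continue
        arr = np.asarray(xs)
        if config.noise_sd > 0:
            arr = arr + rng.normal(0.0, config.noise_sd, size=arr.shape)
        arr = np.clip(arr, lo, hi)
        z = 1150.0 + rng.normal(0.0, 40.0, size=len(ts))  # tag worn at the back
        trajectories[role] = Trajectory(
            case_id=case_id, role=role, t=np.asarray(ts), x=arr[:, 0], y=arr[:, 1], z=z
        )

    cooperation = {
        (pair_key(a, b), iv.phase): config.cooperation_for(a, b, iv.phase)
        for a, b in pairs
        for iv in intervals
    }
    return SyntheticCase(case_id, trajectories, intervals, cooperation, int(seed))


def generate_dataset(
    config: SimulationConfig, n_cases: int = 10, seed: int | None = None
) -> list[SyntheticCase]:
    """Generate ``n_cases`` independent cases with per-case derived seeds."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    master = config.seed if seed is None else int(seed)
    cases = []
    for i in range(n_cases):
        rng = _case_rng(master, i)
        cases.append(
            generate_case(config, seed=master, case_id=f"case{i + 1:02d}", _rng=rng)
        )
    return cases


# ---------------------------------------------------------------------------
# Persistence: movement CSV formats + ground-truth JSON
# ---------------------------------------------------------------------------

def write_dataset(cases: list[SyntheticCase], out_dir: str) -> dict[str, str]:
    """Write tracks.csv, phases.csv and ground_truth.json under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    tracks_path = os.path.join(out_dir, "tracks.csv")
    phases_path = os.path.join(out_dir, "phases.csv")
    truth_path = os.path.join(out_dir, "ground_truth.json")
    all_trajs = [traj for case in cases for traj in case.trajectories.values()]
    write_tracks(all_trajs, tracks_path)
    write_phases([iv for case in cases for iv in case.intervals], phases_path)
    truth = {
        "cases": [
            {
                "case_id": case.case_id,
                "seed": case.seed,
                "cooperation": {
                    f"{a}|{b}|{phase}": v
                    for ((a, b), phase), v in sorted(case.cooperation.items())
                },
                "roles_present": sorted(case.trajectories),
            }
            for case in cases
        ]
    }
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {"tracks": tracks_path, "phases": phases_path, "ground_truth": truth_path}
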