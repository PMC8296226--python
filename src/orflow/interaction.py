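"""Pairwise staff interaction from trajectory similarity.

Interaction between two staff members during a phase segment is quantified by
the longest common subsequence (LCSS) of their 1 Hz trajectories: two samples
match when they are within ``eps`` millimetres in the x-y plane and within
``delta`` samples in time, and the LCSS is the longest order-preserving set of
such matches.  Normalized by the shorter trajectory's length it becomes a
similarity in [0, 1], read as the extent of interaction/cooperation of the
pair.  Unlike point-based geographic co-occurrence counting, the monotone
matching suppresses spurious ("fake") co-occurrences in a small closed room.

Continuous similarities are discretized into Low/Medium/High by per-column
tertiles (:class:`TertileDiscretizer`, an sklearn transformer so boundaries
can be fit on training rows only inside a validation split).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .movement import ROLES, PhaseInterval, Trajectory, resample, slice_by_phase

logger = logging.getLogger(__name__)

#: The four role pairs used as attribute nodes of the workflow classifier.
DEFAULT_PAIRS = (
    ("surgeon", "scrub_nurse"),
    ("assistant_nurse", "surgeon"),
    ("anesthetist", "assistant_nurse"),
    ("assistant_nurse", "scrub_nurse"),
)

LEVELS = ("Low", "Medium", "High")


@dataclass(frozen=True)
class LCSSParams:
    """LCSS matching thresholds.

    eps : spatial matching threshold in mm (~within-reach distance, well
        above the 80 mm tracking-noise floor).
    delta : temporal matching window in samples; ``None`` disables the
        window (any time alignment allowed).
    """

    eps: float = 500.0
    delta: int | None = 5

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.delta is not None and (self.delta < 0 or int(self.delta) != self.delta):
            raise ValueError("delta must be a non-negative integer or None")


def lcss_length(a: Trajectory, b: Trajectory, params: LCSSParams = LCSSParams()) -> int:
    """Length of the longest monotone matching between two trajectories.

    Standard LCSS dynamic programme; samples i of ``a`` and j of ``b`` match
    when their planar distance is <= eps and |i - j| <= delta.  Computed with
    a banded recursion (O(n * delta) when a window is set), which is exact
    because matches cannot occur outside the band.  Empty input gives 0.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0
    ax, ay, bx, by = a.x, a.y, b.x, b.y
    eps2 = params.eps * params.eps
    delta = params.delta if params.delta is not None else max(n, m)
    prev = np.zeros(m + 1, dtype=np.int64)
    cur = np.zeros(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        j_lo = max(1, i - delta)
        j_hi = min(m, i + delta)
        # left of the band no match at (i, j) is possible: cur == prev there
        cur[:j_lo] = prev[:j_lo]
        for j in range(j_lo, j_hi + 1):
            dx = ax[i - 1] - bx[j - 1]
            dy = ay[i - 1] - by[j - 1]
            if dx * dx + dy * dy <= eps2:
                cur[j] = prev[j - 1] + 1
            else:
                above, left = prev[j], cur[j - 1]
                cur[j] = above if above >= left else left
        if j_hi < m:
            # right of the band: cur[j] = max(prev[j], cur[j-1]) — a running max
            cur[j_hi + 1 :] = np.maximum.accumulate(
                np.maximum(prev[j_hi + 1 :], cur[j_hi])
            )
        prev, cur = cur, prev
    return int(prev[m])


def lcss_similarity(
    a: Trajectory, b: Trajectory, params: LCSSParams = LCSSParams()
) -> float:
    """LCSS length normalized by the shorter trajectory: similarity in [0, 1].

    Symmetric; 0 when either trajectory is empty (absent role).
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0.0
    return lcss_length(a, b, params) / min(n, m)


@dataclass
class InteractionRecord:
    """One measured interaction: an ordered role pair in one phase segment."""

    case_id: str
    phase: str
    t_start: float
    role_a: str
    role_b: str
    similarity: float
    missing: bool = False  # at least one role absent from the segment
    level: str | None = None  # assigned by discretization, if at all


def pairwise_interactions(
    segments: dict[str, Trajectory],
    case_id: str,
    phase: str,
    t_start: float = 0.0,
    params: LCSSParams = LCSSParams(),
) -> list[InteractionRecord]:
    """All 16 ordered role-pair interactions for one phase segment.

    ``segments`` maps role -> trajectory segment (roles may be missing or
    empty).  Self-pairs have similarity 1 when the role is present; a pair
    with an absent role gets similarity 0 with the missing flag set.
    """
    records = []
    cache: dict[tuple[str, str], float] = {}
    for ra in ROLES:
        for rb in ROLES:
            ta = segments.get(ra)
            tb = segments.get(rb)
            absent = ta is None or tb is None or len(ta) == 0 or len(tb) == 0
            if absent:
                sim = 0.0
            elif ra == rb:
                sim = 1.0
            else:
                key = (ra, rb) if ra < rb else (rb, ra)
                if key not in cache:
                    cache[key] = lcss_similarity(ta, tb, params)
                sim = cache[key]
            records.append(
                InteractionRecord(case_id, phase, t_start, ra, rb, sim, missing=absent)
            )
    return records


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

class TertileDiscretizer(TransformerMixin, BaseEstimator):
    """Per-column quantile binning of continuous similarities into levels.

    Boundaries are the (1/3, 2/3) quantiles of the *training* rows (``fit``)
    and are frozen for application to validation rows (``transform``), so a
    holdout split never leaks validation values into the bin edges.  Ties are
    broken toward the lower level: a value exactly on a boundary falls in the
    lower bin.  NaN marks an absent measurement and is passed through.

    Parameters
    ----------
    n_levels : number of levels (default 3: Low/Medium/High).
    """

    def __init__(self, n_levels: int = 3):
        self.n_levels = n_levels

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        qs = np.arange(1, self.n_levels) / self.n_levels
        self.columns_ = list(X.columns)
        self.boundaries_ = {}
        for col in self.columns_:
            v = X[col].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if np.unique(v).size < self.n_levels:
                logger.warning(
                    "discretize: column %r has fewer than %d distinct values; "
                    "using degenerate boundaries",
                    col,
                    self.n_levels,
                )
            self.boundaries_[col] = (
                np.quantile(v, qs) if v.size else np.zeros(self.n_levels - 1)
            )
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        out = {}
        levels = self._level_names()
        for col in self.columns_:
            v = X[col].to_numpy(dtype=float)
            b = self.boundaries_[col]
            idx = (v[:, None] > b[None, :]).sum(axis=1)  # ties -> lower level
            lab = np.array(levels, dtype=object)[idx]
            lab = np.where(np.isfinite(v), lab, None)
            out[col] = lab
        return pd.DataFrame(out, index=X.index)

    def _level_names(self) -> tuple[str, ...]:
        if self.n_levels == 3:
            return LEVELS
        return tuple(f"L{i}" for i in range(self.n_levels))


def discretize(values, n_levels: int = 3):
    """Fit-and-apply tertile binning; returns (levels frame, boundaries)."""
    disc = TertileDiscretizer(n_levels=n_levels).fit(values)
    return disc.transform(values), disc.boundaries_


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

def pair_column(pair: tuple[str, str]) -> str:
    return f"{pair[0]}__{pair[1]}"


def _check_pairs(selected_pairs) -> list[tuple[str, str]]:
    pairs = []
    for pair in selected_pairs:
        a, b = pair
        if a not in ROLES or b not in ROLES or a == b:
            raise ValueError(f"unknown role pair {pair!r}")
        pairs.append((a, b))
    return pairs


def build_similarity_table(
    cases,
    params: LCSSParams = LCSSParams(),
    selected_pairs=DEFAULT_PAIRS,
    resample_hz: float = 1.0,
) -> pd.DataFrame:
    """Continuous per-segment interaction table: one row per phase segment.

    Columns: ``case_id``, ``phase``, ``t_start`` plus one similarity column
    per selected pair (NaN when a member of the pair is absent).  Trajectories
    are resampled to the analysis grid before slicing.
    """
    pairs = _check_pairs(selected_pairs)
    rows = []
    for case in cases:
        sliced: dict[str, dict[PhaseInterval, Trajectory]] = {}
        for role, traj in case.trajectories.items():
            traj_rs = resample(traj, 1.0 / resample_hz) if len(traj) >= 2 else traj
            sliced[role] = slice_by_phase(traj_rs, case.intervals)
        for iv in case.intervals:
            segments = {
                role: by_iv[iv] for role, by_iv in sliced.items() if len(by_iv[iv])
            }
            records = pairwise_interactions(
                segments, case.case_id, iv.phase, iv.t_start, params
            )
            by_pair = {(r.role_a, r.role_b): r for r in records}
            row = {"case_id": case.case_id, "phase": iv.phase, "t_start": iv.t_start}
            for pair in pairs:
                rec = by_pair[pair]
                row[pair_column(pair)] = np.nan if rec.missing else rec.similarity
            rows.append(row)
    return pd.DataFrame(rows)


def build_feature_table(
    cases,
    params: LCSSParams = LCSSParams(),
    selected_pairs=DEFAULT_PAIRS,
    resample_hz: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Discrete feature table over *all* rows (tertiles fit on everything).

    Returns ``(table, boundaries)`` where the table has one row per phase
    segment with the selected pairs' Low/Medium/High levels plus the phase
    label.  For leakage-free validation use :func:`build_similarity_table`
    and fit the discretizer per training split instead.
    """
    sim = build_similarity_table(cases, params, selected_pairs, resample_hz)
    feat_cols = [c for c in sim.columns if c not in ("case_id", "phase", "t_start")]
    levels, boundaries = discretize(sim[feat_cols])
    table = pd.concat([sim[["case_id", "phase", "t_start"]], levels], axis=1)
    return table, boundaries
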