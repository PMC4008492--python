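"""The genomic duplications - element loss simulator.

A chromosome is modelled as a growing 1-D sequence of length L carrying
point markers (the conserved elements).  Five event types act on it:

i.   segmental duplication (SD): a region of length up to a fixed
     fraction of the current L is copied in tandem, duplicating the
     markers it contains;
ii.  elimination of a number of markers equal to a fraction ``fr`` of
     the just-duplicated ones, drawn by default from the duplicated
     markers themselves (either copy of a redundant pair may be lost);
iii. optional extra eliminations of markers after each SD;
iv.  insertions of neutral sequence (no markers created);
v.   deletions of marker-free sequence stretches.

Events i and ii alone suffice to turn an initially random marker
arrangement into one whose inter-marker spacer CCDF shows an extended
linear region in log-log scale; the extent of that region grows with
the number of SDs, with ``fr`` and with the extra-elimination rate.
Duplication both enables subsequent loss (redundant copies) and
stretches the sequence, building up the long spacers of the heavy tail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .powerlaw import (
    CumulativeDistribution,
    FitParams,
    LinearFit,
    _distinct_uniform,
    ccdf,
    fit_linear_region,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimState", "SimConfig", "SimRun", "init_state",
    "segmental_duplication", "eliminate_markers", "extra_eliminations",
    "insert_sequence", "delete_sequence", "run_model", "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round half away from zero (so fr=0.9 of 7 duplicated markers -> 6)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class SimState:
    """Simulated chromosome: length L and sorted point markers in [0, L)."""

    L: int
    markers: np.ndarray
    counters: dict[str, int] = field(default_factory=dict)
    # indices (into markers) of the originals+copies of the last SD event
    last_duplicated: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=np.int64)
        assert (np.diff(self.markers) > 0).all(), "markers must be sorted, distinct"
        if len(self.markers):
            assert 0 <= self.markers[0] and self.markers[-1] < self.L

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def spacers(self) -> np.ndarray:
        return np.diff(self.markers)

    def copy(self) -> "SimState":
        return SimState(self.L, self.markers.copy(), dict(self.counters))


@dataclass
class SimConfig:
    """Simulation settings.

    Defaults mirror the showcase conditions: 1000 markers on a 2 Mbp
    sequence, SD lengths uniform up to 5% of the current length, 90% of
    each SD's duplicated markers subsequently eliminated, snapshots
    every 50 SDs.
    """

    n0: int = 1000
    L0: int = 2_000_000
    n_sd: int = 150
    sd_max_frac: float = 0.05
    fr: float = 0.9
    extra_elims: int = 0
    elim_pool: str = "duplicated"     # "duplicated" or "all"
    insertion_rate: float = 0.0       # expected insertions per SD (Poisson)
    insertion_mean_len: int = 10_000
    deletion_rate: float = 0.0        # expected deletions per SD (Poisson)
    deletion_mean_len: int = 10_000
    snapshot_every: int = 50
    seed: int = 0
    fit_params: FitParams = field(default_factory=FitParams)

    def __post_init__(self) -> None:
        if not (0.0 <= self.fr <= 1.0):
            raise ValueError("fr must be in [0, 1]")
        if not (0.0 < self.sd_max_frac <= 1.0):
            raise ValueError("sd_max_frac must be in (0, 1]")
        if self.n0 < 2:
            raise ValueError("need at least two initial markers")
        if self.elim_pool not in ("duplicated", "all"):
            raise ValueError("elim_pool must be 'duplicated' or 'all'")


@dataclass
class Snapshot:
    events: int                    # SD events applied so far
    dist: CumulativeDistribution
    fit: LinearFit
    n_markers: int
    L: int


@dataclass
class SimRun:
    snapshots: list[Snapshot]
    final_state: SimState
    event_log: list[dict]
    completed: bool = True


# ---------------------------------------------------------------------------
# Events


def init_state(n0: int, L0: int, seed: int | np.random.Generator = 0) -> SimState:
    """Place ``n0`` distinct markers uniformly at random on [0, L0)."""
    if n0 >= L0:
        raise ValueError("more markers than positions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    markers = np.sort(_distinct_uniform(n0, L0, rng))
    return SimState(L=L0, markers=markers, counters={"init": n0})


def segmental_duplication(
    state: SimState, rng: np.random.Generator, sd_max_frac: float = 0.05
) -> tuple[SimState, int]:
    """Tandem segmental duplication.

    A region length is drawn uniformly from 1 to ``sd_max_frac`` of the
    *current* sequence length, a start position uniformly along the
    sequence, and the copy is inserted immediately after the source
    region.  Markers inside the source are duplicated into the copy at
    preserved offsets; everything downstream shifts right by the region
    length.  Returns the new state and the number of duplicated markers.
    """
    L = state.L
    assert L >= 2
    max_len = max(int(sd_max_frac * L), 1)
    length = int(rng.integers(1, max_len + 1))
    start = int(rng.integers(0, L - length + 1))
    end = start + length
    m = state.markers
    lo = np.searchsorted(m, start, side="left")
    hi = np.searchsorted(m, end, side="left")
    inside = m[lo:hi]
    downstream = m[hi:] + length
    new_markers = np.concatenate([m[:hi], inside + length, downstream])
    counters = dict(state.counters)
    counters["sd"] = counters.get("sd", 0) + 1
    counters["sd_bp"] = counters.get("sd_bp", 0) + length
    counters["duplicated"] = counters.get("duplicated", 0) + len(inside)
    new_state = SimState(L + length, new_markers, counters)
    # originals sit at indices [lo, hi), their copies at [hi, hi + d)
    new_state.last_duplicated = np.arange(lo, hi + len(inside))
    return new_state, int(len(inside))


def eliminate_markers(
    state: SimState,
    count: int,
    rng: np.random.Generator,
    pool: np.ndarray | None = None,
) -> SimState:
    """Remove ``count`` markers uniformly without replacement.

    ``pool`` restricts the draw to the given marker indices (by default
    all markers are candidates); after a duplication the pool is the
    duplicated markers — either copy of a redundant pair may be the one
    lost.  The sequence itself is untouched: an eliminated element loses
    its identity (diverges beyond recognition) but its DNA remains.
    """
    n = state.n_markers
    candidates = np.arange(n) if pool is None else np.asarray(pool)
    if not (0 <= count <= len(candidates)):
        raise ValueError(f"cannot eliminate {count} of {len(candidates)} markers")
    if count == 0:
        return state
    keep = np.ones(n, dtype=bool)
    keep[rng.choice(candidates, size=count, replace=False)] = False
    counters = dict(state.counters)
    counters["eliminated"] = counters.get("eliminated", 0) + count
    return SimState(state.L, state.markers[keep], counters)


def extra_eliminations(
    state: SimState, k: int, rng: np.random.Generator
) -> SimState:
    """Remove up to ``k`` additional (non-compensated) markers."""
    if k < 0:
        raise ValueError("k must be non-negative")
    count = min(k, state.n_markers)
    new = eliminate_markers(state, count, rng)
    if count:
        new.counters["extra_eliminated"] = (
            new.counters.get("extra_eliminated", 0) + count
        )
        new.counters["eliminated"] -= count  # tracked separately
    return new


def insert_sequence(
    state: SimState, length: int, rng: np.random.Generator
) -> SimState:
    """Insert ``length`` bp of neutral sequence at a uniform position."""
    if length < 1:
        raise ValueError("insertion length must be >= 1")
    point = int(rng.integers(0, state.L + 1))
    markers = np.where(state.markers >= point, state.markers + length, state.markers)
    counters = dict(state.counters)
    counters["inserted_bp"] = counters.get("inserted_bp", 0) + length
    return SimState(state.L + length, markers, counters)


def delete_sequence(
    state: SimState, length: int, rng: np.random.Generator, max_attempts: int = 100
) -> SimState:
    """Delete a marker-free window of ``length`` bp.

    Windows are sampled uniformly; a window containing a marker is
    rejected and resampled (markers are under purifying selection and
    protected).  After ``max_attempts`` rejections the event is skipped.
    """
    if not (1 <= length < state.L):
        raise ValueError("deletion length must be in [1, L)")
    m = state.markers
    for _ in range(max_attempts):
        start = int(rng.integers(0, state.L - length + 1))
        end = start + length
        lo = np.searchsorted(m, start, side="left")
        hi = np.searchsorted(m, end, side="left")
        if lo == hi:  # no marker inside the window
            markers = np.where(m >= end, m - length, m)
            counters = dict(state.counters)
            counters["deleted_bp"] = counters.get("deleted_bp", 0) + length
            return SimState(state.L - length, markers, counters)
    logger.info("deletion of %d bp skipped: no marker-free window found", length)
    counters = dict(state.counters)
    counters["deletions_skipped"] = counters.get("deletions_skipped", 0) + 1
    return SimState(state.L, m.copy(), counters)


# ---------------------------------------------------------------------------
# Driver


def run_model(config: SimConfig) -> SimRun:
    """Run the full event loop and snapshot the spacer CCDF periodically.

    Each SD event is followed by elimination of ``round(fr x duplicated)``
    markers, then ``extra_elims`` further eliminations, then any
    configured insertions and deletions.  Snapshots (CCDF + linear fit)
    are taken every ``snapshot_every`` SDs.  The run terminates early if
    fewer than 3 markers remain.
    """
    rng = np.random.default_rng(config.seed)
    state = init_state(config.n0, config.L0, rng)
    snapshots: list[Snapshot] = []
    event_log: list[dict] = []

    def take_snapshot(n_events: int) -> None:
        sp = state.spacers()
        dist = ccdf(sp)
        fp = config.fit_params
        fit = fit_linear_region(
            dist, fp.r2_min, fp.min_points, fp.points_per_decade, fp.min_slope
        )
        snapshots.append(
            Snapshot(n_events, dist, fit, state.n_markers, state.L)
        )

    completed = True
    for step in range(1, config.n_sd + 1):
        state, dup = segmental_duplication(state, rng, config.sd_max_frac)
        pool = state.last_duplicated if config.elim_pool == "duplicated" else None
        cap = len(pool) if pool is not None else state.n_markers
        n_elim = min(round_half_up(config.fr * dup), cap)
        state = eliminate_markers(state, n_elim, rng, pool=pool)
        extra_actual = min(config.extra_elims, state.n_markers)
        state = extra_eliminations(state, config.extra_elims, rng)
        ins_bp = del_bp = 0
        if config.insertion_rate > 0:
            for _ in range(rng.poisson(config.insertion_rate)):
                ln = max(int(rng.exponential(config.insertion_mean_len)), 1)
                state = insert_sequence(state, ln, rng)
                ins_bp += ln
        if config.deletion_rate > 0:
            for _ in range(rng.poisson(config.deletion_rate)):
                ln = max(int(rng.exponential(config.deletion_mean_len)), 1)
                ln = min(ln, state.L - 1)
                state = delete_sequence(state, ln, rng)
                del_bp += ln
        event_log.append(
            {
                "step": step,
                "duplicated": dup,
                "eliminated": n_elim,
                "extra_eliminated": extra_actual,
                "inserted_bp": ins_bp,
                "deleted_bp_requested": del_bp,
                "n_markers": state.n_markers,
                "L": state.L,
            }
        )
        if state.n_markers < 3:
            logger.warning("marker count fell below 3 at SD %d; stopping", step)
            completed = False
            break
        if step % config.snapshot_every == 0:
            take_snapshot(step)

    if completed and (not snapshots or snapshots[-1].events != config.n_sd):
        take_snapshot(config.n_sd)
    return SimRun(
        snapshots=snapshots,
        final_state=state,
        event_log=event_log,
        completed=completed,
    )
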