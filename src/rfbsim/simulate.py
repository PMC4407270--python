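"""Per-cell stochastic timelines of fork blockage, recombination and restart.

Each simulated cell draws an S-phase start time post-anaphase, fires each
flanking origin independently with its efficiency, and derives blockage and
convergence times from the locus geometry (:mod:`rfbsim.locus`).  A blocked
fork commits to recombination-dependent restart after a random delay; the
recombinase-loading marker (a Rad52 focus at the barrier) is visible from
``blockage + recruitment_lag`` until the first of restart or convergence
(plus an optional persistence).  After restart the fork advances at the
configured velocity and accrues downstream collapse events as a Poisson
process in distance, truncated where it meets the opposing fork.

Defaults encode the observed kinetics: S start 10-15 min post-anaphase
(first PCNA foci), recruitment lag 7.4-12.4 min after blockage, restart
delay 10-60 min, PCNA foci disappearing 40-70 min post-anaphase.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .locus import (
    DEFAULT_HORIZON_MIN,
    LocusMap,
    TimingParams,
    blockage_and_convergence,
)

__all__ = [
    "Outcome",
    "SimulationParams",
    "CellTimeline",
    "simulate_cell",
    "simulate_population",
    "restart_fraction",
    "reporter_hit_rates",
    "timelines_to_frame",
]


class Outcome(str, enum.Enum):
    NO_BLOCKAGE = "no_blockage"
    RESTARTED = "restarted_before_convergence"
    CONVERGED = "converged_while_blocked"


def _draw(interval, rng: np.random.Generator) -> float:
    """Sample from a (lo, hi) uniform bracket or return a scalar point mass."""
    if isinstance(interval, (int, float)):
        return float(interval)
    lo, hi = interval
    if math.isinf(hi) and math.isinf(lo):
        return math.inf
    if hi < lo:
        raise ValueError(f"interval {interval} is not ordered")
    return float(rng.uniform(lo, hi))


@dataclass(frozen=True)
class SimulationParams:
    """Kinetic parameters, minutes.  Brackets are (lo, hi) uniform; a scalar
    is a point mass and ``math.inf`` disables restart entirely.

    ``anaphase_stagger_min`` spreads absolute anaphase times across the
    population to emulate an asynchronous culture (event fields stay relative
    to each cell's own anaphase).
    """

    s_start_min: tuple[float, float] | float = (10.0, 15.0)
    recruitment_lag_min: tuple[float, float] | float = (7.4, 12.4)
    restart_delay_min: tuple[float, float] | float = (10.0, 60.0)
    rad52_persistence_min: float = 0.0
    collapse_hazard_per_kb: float = 0.0
    pcna_end_min: tuple[float, float] | float = (40.0, 70.0)
    anaphase_stagger_min: float = 0.0
    horizon_min: float = DEFAULT_HORIZON_MIN

    def __post_init__(self):
        if self.rad52_persistence_min < 0:
            raise ValueError("rad52_persistence_min must be >= 0")
        if self.collapse_hazard_per_kb < 0:
            raise ValueError("collapse_hazard_per_kb must be >= 0")
        if self.anaphase_stagger_min < 0:
            raise ValueError("anaphase_stagger_min must be >= 0")
        for name in ("s_start_min", "recruitment_lag_min", "restart_delay_min", "pcna_end_min"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) and v[1] < v[0]:
                raise ValueError(f"{name} bracket is not ordered")


@dataclass(frozen=True)
class CellTimeline:
    """Event chain of one cell.  All times are minutes post-anaphase of that
    cell; ``anaphase_min`` is the cell's anaphase on the absolute movie clock.

    ``convergence_min`` is None when censored (no opposing fork within the
    horizon); ``restart_min`` is None when the fork never restarts (no
    blockage, or convergence pre-empts restart).
    """

    cell_id: str
    anaphase_min: float
    s_start_min: float
    blockage_min: float | None
    restart_min: float | None
    convergence_min: float | None
    convergence_censored: bool
    rad52_start_min: float | None
    rad52_end_min: float | None
    pcna_start_min: float
    pcna_end_min: float
    outcome: Outcome
    downstream_collapses: tuple[tuple[float, float], ...] = ()  # (position_kb, time_min)

    def __post_init__(self):
        if self.blockage_min is not None:
            assert self.s_start_min <= self.blockage_min
        if self.rad52_start_min is not None:
            assert self.blockage_min is not None
            assert self.blockage_min <= self.rad52_start_min <= self.rad52_end_min
        for t in (self.restart_min, self.convergence_min):
            if t is not None and self.blockage_min is not None:
                assert t >= self.blockage_min

    @property
    def has_rad52_interval(self) -> bool:
        return self.rad52_start_min is not None


def simulate_cell(
    locus_map: LocusMap,
    timing: TimingParams,
    params: SimulationParams,
    rng: np.random.Generator,
    cell_id: str = "cell0",
    anaphase_min: float = 0.0,
) -> CellTimeline:
    """Simulate one cell's event timeline (times relative to its anaphase)."""
    s_start = _draw(params.s_start_min, rng)
    fired = [o.name for o in locus_map.origins if rng.random() < o.efficiency]

    if locus_map.barrier_orientation == "IO":
        # Inactive orientation: no fork is arrested, the locus replicates
        # passively whichever side arrives first.
        fate_block = None
        fate_conv = None
        censored = False
    else:
        fate = blockage_and_convergence(fired, locus_map, timing, params.horizon_min)
        fate_block = fate.blockage_min
        fate_conv = fate.convergence_min
        censored = fate.censored

    pcna_start = s_start
    pcna_end = max(_draw(params.pcna_end_min, rng), pcna_start)

    if fate_block is None:
        return CellTimeline(
            cell_id, anaphase_min, s_start, None, None,
            None if fate_conv is None else s_start + fate_conv,
            censored, None, None, pcna_start, pcna_end, Outcome.NO_BLOCKAGE,
        )

    blockage = s_start + fate_block
    convergence = None if fate_conv is None else s_start + fate_conv
    if convergence is not None and convergence < blockage:
        # opposing fork reaches the barrier first: the region replicates
        # passively and the arrest interval is empty
        blockage = convergence
    conv_eff = math.inf if convergence is None else convergence

    delay = _draw(params.restart_delay_min, rng)
    restart = blockage + delay if math.isfinite(delay) else math.inf

    if restart < conv_eff:
        outcome = Outcome.RESTARTED
        restart_min: float | None = restart
    else:
        outcome = Outcome.CONVERGED
        restart_min = None

    lag = _draw(params.recruitment_lag_min, rng)
    rad52_start = blockage + lag
    rad52_end = min(restart, conv_eff) + params.rad52_persistence_min
    if not math.isfinite(rad52_end):
        rad52_end = params.horizon_min  # never resolved within the observation window
    if rad52_start >= rad52_end:
        rad52_start = rad52_end = None  # window too short for recruitment

    collapses: list[tuple[float, float]] = []
    if outcome is Outcome.RESTARTED and params.collapse_hazard_per_kb > 0:
        v = timing.velocity_kb_min
        if convergence is not None:
            # Restarted and opposing forks approach each other at equal speed;
            # they meet halfway through the remaining interval.
            track_kb = max(v * (convergence - restart) / 2.0, 0.0)
        else:
            track_kb = max(v * (params.horizon_min - restart), 0.0)
        n_events = rng.poisson(params.collapse_hazard_per_kb * track_kb)
        positions = np.sort(rng.uniform(0.0, track_kb, size=n_events))
        collapses = [(float(p), restart + float(p) / v) for p in positions]

    return CellTimeline(
        cell_id, anaphase_min, s_start, blockage, restart_min, convergence,
        censored, rad52_start, rad52_end, pcna_start, pcna_end, outcome,
        tuple(collapses),
    )


def simulate_population(
    n_cells: int,
    locus_map: LocusMap,
    timing: TimingParams | None = None,
    params: SimulationParams | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[CellTimeline]:
    """Simulate ``n_cells`` independent cells.

    Each cell gets its own child stream spawned from the root seed, so
    enlarging the population does not reshuffle earlier cells.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be >= 1")
    timing = timing or TimingParams()
    params = params or SimulationParams()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = root.spawn(n_cells)
    cells = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        anaphase = (
            float(rng.uniform(0.0, params.anaphase_stagger_min))
            if params.anaphase_stagger_min > 0 else 0.0
        )
        cells.append(
            simulate_cell(locus_map, timing, params, rng,
                          cell_id=f"cell{i:04d}", anaphase_min=anaphase)
        )
    return cells


def restart_fraction(population: Sequence[CellTimeline]) -> float:
    """Fraction of blocked cells whose fork restarts before convergence.

    Computational proxy for the ratio of restarted (large-Y) to converged
    (double-Y) replication structures; assumes the two structure classes are
    equally detectable.
    """
    blocked = [c for c in population if c.blockage_min is not None]
    if not blocked:
        raise ValueError("restart fraction undefined: no blocked cells")
    return sum(c.outcome is Outcome.RESTARTED for c in blocked) / len(blocked)


def reporter_hit_rates(
    population: Sequence[CellTimeline],
    locus_map: LocusMap,
    window_bp: float = 1000.0,
) -> dict[str, float]:
    """Per reporter site: fraction of restarted cells with >= 1 downstream
    collapse within a symmetric ``window_bp``-wide window around the site."""
    restarted = [c for c in population if c.outcome is Outcome.RESTARTED]
    rates: dict[str, float] = {}
    for label, dist_bp in locus_map.reporter_sites:
        lo = (dist_bp - window_bp / 2.0) / 1000.0
        hi = (dist_bp + window_bp / 2.0) / 1000.0
        if not restarted:
            rates[label] = 0.0
            continue
        hits = sum(
            any(lo <= pos <= hi for pos, _ in c.downstream_collapses)
            for c in restarted
        )
        rates[label] = hits / len(restarted)
    return rates


def timelines_to_frame(population: Sequence[CellTimeline]) -> pd.DataFrame:
    """One row per cell; event times in minutes post-anaphase."""
    rows = []
    for c in population:
        rows.append({
            "cell_id": c.cell_id,
            "anaphase_min": c.anaphase_min,
            "s_start_min": c.s_start_min,
            "blockage_min": c.blockage_min,
            "restart_min": c.restart_min,
            "convergence_min": c.convergence_min,
            "convergence_censored": c.convergence_censored,
            "rad52_start_min": c.rad52_start_min,
            "rad52_end_min": c.rad52_end_min,
            "pcna_start_min": c.pcna_start_min,
            "pcna_end_min": c.pcna_end_min,
            "outcome": c.outcome.value,
            "n_downstream_collapses": len(c.downstream_collapses),
            "collapse_positions_kb": json.dumps([p for p, _ in c.downstream_collapses]),
        })
    return pd.DataFrame(rows)
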