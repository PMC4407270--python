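"""Deterministic and enumerative timing arithmetic for forks converging on a
unidirectional replication fork barrier (RFB).

The model: a barrier locus is flanked by replication origins on two sides.
Origins on the *blocking* side (centromere-distal for the active orientation)
send a fork that is arrested at the barrier; origins on the *converging* side
(centromere-proximal) send the opposing fork that eventually merges at the
barrier and completes replication of the region.  Each origin fires
independently in a given S-phase with its own efficiency, all firing at the
same time by default, and forks travel at a constant velocity (default
3.0 kb/min).  The interval between arrest of the first blocked fork and the
arrival of the first opposing fork — the blockage-to-convergence window — is
the time available for recombination to restart the arrested fork.

Because each origin either fires or not, the window has a discrete
distribution over the 2**n firing subsets, which this module enumerates
exactly.  A Monte-Carlo variant lives in :mod:`rfbsim.simulate`.
"""

from __future__ import annotations

import enum
import itertools
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Side",
    "Origin",
    "LocusMap",
    "TimingParams",
    "FateOutcome",
    "WindowDistribution",
    "CENSORED",
    "UNDEFINED",
    "arrival_time",
    "round_report",
    "blockage_and_convergence",
    "window_distribution_enumerate",
    "delete_origin",
    "read_origin_map",
    "write_origin_map",
    "packaged_origin_map",
]

DEFAULT_HORIZON_MIN = 90.0


class Side(str, enum.Enum):
    """Which fork an origin contributes at the barrier."""

    BLOCKING = "blocking"      # centromere-distal: fork is arrested at the barrier
    CONVERGING = "converging"  # centromere-proximal: fork merges at the barrier


class _Sentinel:
    def __init__(self, name: str):
        self._name = name

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self._name


#: Outcome marker: the window opened but its end lies beyond the horizon.
CENSORED = _Sentinel("CENSORED")
#: Outcome marker: no blocked fork ever arrived, so no window exists.
UNDEFINED = _Sentinel("UNDEFINED")


@dataclass(frozen=True)
class Origin:
    """A replication origin flanking the barrier.

    ``distance_bp`` is measured from the origin midpoint to the barrier;
    ``efficiency`` is the probability the origin fires in a given S-phase.
    """

    name: str
    side: Side
    distance_bp: int
    efficiency: float
    offset_min: float = 0.0

    def __post_init__(self):
        if self.distance_bp <= 0:
            raise ValueError(f"origin {self.name}: distance_bp must be > 0")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError(f"origin {self.name}: efficiency must lie in [0, 1]")
        object.__setattr__(self, "side", Side(self.side))


@dataclass(frozen=True)
class LocusMap:
    """Barrier locus geometry: flanking origins plus downstream reporter sites.

    ``barrier_orientation`` is "AO" (active: arrests the blocking-side fork)
    or "IO" (inactive: forks pass through).  ``reporter_sites`` are
    (label, distance_bp downstream of the barrier) pairs, e.g. direct-repeat
    recombination reporters.
    """

    barrier_orientation: str
    origins: tuple[Origin, ...]
    reporter_sites: tuple[tuple[str, int], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "origins", tuple(self.origins))
        object.__setattr__(self, "reporter_sites", tuple(self.reporter_sites))
        if self.barrier_orientation not in ("AO", "IO"):
            raise ValueError("barrier_orientation must be 'AO' or 'IO'")
        names = [o.name for o in self.origins]
        if len(set(names)) != len(names):
            raise ValueError("origin names must be unique within a map")
        if self.barrier_orientation == "AO" and not self.blocking_origins:
            raise ValueError("an AO map must contain at least one blocking-side origin")
        for label, dist in self.reporter_sites:
            if dist < 0:
                raise ValueError(f"reporter site {label}: distance must be >= 0")

    @property
    def blocking_origins(self) -> tuple[Origin, ...]:
        return tuple(o for o in self.origins if o.side is Side.BLOCKING)

    @property
    def converging_origins(self) -> tuple[Origin, ...]:
        return tuple(o for o in self.origins if o.side is Side.CONVERGING)

    def origin(self, name: str) -> Origin:
        for o in self.origins:
            if o.name == name:
                return o
        raise KeyError(f"no origin named {name!r} in map")

    def reporter(self, label: str) -> int:
        for lab, dist in self.reporter_sites:
            if lab == label:
                return dist
        raise KeyError(f"no reporter site labelled {label!r} in map")


@dataclass(frozen=True)
class TimingParams:
    """Fork kinetics: velocity in kb/min and optional per-origin firing offsets.

    All origins fire simultaneously (offset 0) by default; offsets are an
    extension knob and are added to the fork arrival time of that origin.
    """

    velocity_kb_min: float = 3.0
    firing_offsets_min: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.velocity_kb_min <= 0:
            raise ValueError("velocity_kb_min must be > 0")

    def offset(self, origin_name: str) -> float:
        return float(self.firing_offsets_min.get(origin_name, 0.0))


def arrival_time(distance_bp: float, params: TimingParams, offset_min: float = 0.0) -> float:
    """Minutes (post S start) for a fork to travel ``distance_bp`` to the barrier."""
    if distance_bp < 0:
        raise ValueError("distance_bp must be >= 0")
    return distance_bp / (params.velocity_kb_min * 1000.0) + offset_min


def round_report(minutes: float, decimals: int = 1) -> float:
    """Reporting round: half away from zero at ``decimals`` places."""
    scale = 10.0 ** decimals
    return math.copysign(math.floor(abs(minutes) * scale + 0.5), minutes) / scale


def _origin_arrival(origin: Origin, params: TimingParams) -> float:
    return arrival_time(
        origin.distance_bp, params, origin.offset_min + params.offset(origin.name)
    )


@dataclass(frozen=True)
class FateOutcome:
    """Blockage/convergence fate of one S-phase (one firing subset).

    Times are minutes after S start.  ``blockage_min`` is None when no
    blocking-side origin fired (no arrest, window UNDEFINED);
    ``convergence_min`` is None when no converging-side origin fired
    (convergence censored at ``horizon_min``).  ``window_min`` is the arrest
    interval length, 0.0 when the opposing fork arrives first, None when
    undefined or censored.
    """

    blockage_min: float | None
    convergence_min: float | None
    window_min: float | None
    censored: bool
    horizon_min: float

    @property
    def window_key(self):
        """Aggregation key: a float, CENSORED, or UNDEFINED."""
        if self.blockage_min is None:
            return UNDEFINED
        if self.censored:
            return CENSORED
        return self.window_min


def blockage_and_convergence(
    fired: Iterable[str | Origin],
    locus_map: LocusMap,
    params: TimingParams,
    horizon_min: float = DEFAULT_HORIZON_MIN,
) -> FateOutcome:
    """Fate of one S-phase given which origins fired.

    Blockage is the earliest arrival over fired blocking-side origins,
    convergence the earliest over fired converging-side origins.  If the
    converging fork arrives first the region replicates passively and the
    window is 0 (no arrest interval).  An empty fired set is allowed and
    yields UNDEFINED blockage / censored convergence.
    """
    fired_names = {o.name if isinstance(o, Origin) else str(o) for o in fired}
    unknown = fired_names - {o.name for o in locus_map.origins}
    if unknown:
        raise KeyError(f"fired origins not in map: {sorted(unknown)}")

    block_times = [
        _origin_arrival(o, params)
        for o in locus_map.blocking_origins
        if o.name in fired_names
    ]
    conv_times = [
        _origin_arrival(o, params)
        for o in locus_map.converging_origins
        if o.name in fired_names
    ]
    blockage = min(block_times) if block_times else None
    convergence = min(conv_times) if conv_times else None
    censored = convergence is None or convergence > horizon_min
    if censored:
        convergence = None

    if blockage is None:
        window = None
    elif censored:
        window = None
    else:
        window = max(convergence - blockage, 0.0)
    return FateOutcome(blockage, convergence, window, censored and blockage is not None, horizon_min)


@dataclass(frozen=True)
class WindowDistribution:
    """Exact distribution of the blockage-to-convergence window.

    ``support`` maps outcome → probability where an outcome is a numeric
    window in minutes, CENSORED (window opened, end beyond the horizon), or
    UNDEFINED (no blockage).  "Defined" means an arrest window opened
    (blockage occurred), i.e. numeric + censored mass.
    """

    support: tuple[tuple[object, float], ...]
    horizon_min: float

    def __post_init__(self):
        total = sum(p for _, p in self.support)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, not 1")
        for w, _ in self.support:
            if isinstance(w, float) and w < 0:
                raise ValueError("window values must be >= 0")

    @property
    def p_undefined(self) -> float:
        return sum(p for w, p in self.support if w is UNDEFINED)

    @property
    def p_censored(self) -> float:
        return sum(p for w, p in self.support if w is CENSORED)

    @property
    def p_defined(self) -> float:
        """Probability an arrest window opened (numeric or censored end)."""
        return 1.0 - self.p_undefined

    @property
    def numeric_support(self) -> tuple[tuple[float, float], ...]:
        return tuple((w, p) for w, p in self.support if isinstance(w, float))

    @property
    def mean_min(self) -> float:
        """Mean window over numeric (uncensored) outcomes; NaN if none."""
        num = self.numeric_support
        mass = sum(p for _, p in num)
        if mass == 0:
            return math.nan
        return sum(w * p for w, p in num) / mass

    def probability(self, window, atol: float = 1e-9) -> float:
        if window is CENSORED or window is UNDEFINED:
            return sum(p for w, p in self.support if w is window)
        return sum(
            p for w, p in self.support
            if isinstance(w, float) and abs(w - window) <= atol
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w, p in sorted(
            self.support, key=lambda t: (isinstance(t[0], _Sentinel), str(t[0]) if isinstance(t[0], _Sentinel) else t[0])
        ):
            rows.append({"window_min": repr(w) if isinstance(w, _Sentinel) else w, "probability": p})
        return pd.DataFrame(rows, columns=["window_min", "probability"])

    def summary(self) -> dict:
        return {
            "mean_min": self.mean_min,
            "p_defined": self.p_defined,
            "p_censored": self.p_censored,
            "p_undefined": self.p_undefined,
            "horizon_min": self.horizon_min,
        }

    def write(self, tsv_path, json_path=None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2)


MAX_ENUMERATION_ORIGINS = 20


def window_distribution_enumerate(
    locus_map: LocusMap,
    params: TimingParams,
    horizon_min: float = DEFAULT_HORIZON_MIN,
) -> WindowDistribution:
    """Exact window distribution by enumerating all 2**n firing subsets.

    Each subset carries weight prod(eff_i for fired) * prod(1-eff_i for not).
    Exact to floating precision; refuses maps with more than
    ``MAX_ENUMERATION_ORIGINS`` origins (use the Monte-Carlo route in
    :mod:`rfbsim.simulate` instead).
    """
    origins = locus_map.origins
    if len(origins) > MAX_ENUMERATION_ORIGINS:
        raise ValueError(
            f"{len(origins)} origins exceeds the 2^n enumeration limit "
            f"({MAX_ENUMERATION_ORIGINS}); use the Monte-Carlo simulator"
        )
    acc: dict[object, float] = {}
    for fires in itertools.product((False, True), repeat=len(origins)):
        weight = 1.0
        for o, f in zip(origins, fires):
            weight *= o.efficiency if f else 1.0 - o.efficiency
        if weight == 0.0:
            continue
        fired = [o.name for o, f in zip(origins, fires) if f]
        out = blockage_and_convergence(fired, locus_map, params, horizon_min)
        key = out.window_key
        if isinstance(key, float):
            key = round(key, 9)
        acc[key] = acc.get(key, 0.0) + weight
    support = tuple(sorted(
        acc.items(),
        key=lambda t: (isinstance(t[0], _Sentinel), t[0] if not isinstance(t[0], _Sentinel) else 0.0),
    ))
    return WindowDistribution(support, horizon_min)


def delete_origin(locus_map: LocusMap, name: str) -> LocusMap:
    """Return a copy of the map without the named origin (pure)."""
    locus_map.origin(name)  # raises KeyError if absent
    return replace(
        locus_map, origins=tuple(o for o in locus_map.origins if o.name != name)
    )


# --------------------------------------------------------------------------
# I/O: origin maps as TSV with header name, side, distance_bp, efficiency,
# offset_min.  The packaged barrier-locus map ships as a data file.

def read_origin_map(
    path,
    barrier_orientation: str = "AO",
    reporter_sites: Sequence[tuple[str, int]] = (),
) -> LocusMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "side", "distance_bp", "efficiency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"origin map missing columns: {sorted(missing)}")
    if "offset_min" not in df.columns:
        df["offset_min"] = 0.0
    origins = tuple(
        Origin(
            name=str(r["name"]),
            side=Side(r["side"]),
            distance_bp=int(r["distance_bp"]),
            efficiency=float(r["efficiency"]),
            offset_min=float(r["offset_min"]),
        )
        for _, r in df.iterrows()
    )
    return LocusMap(barrier_orientation, origins, tuple(reporter_sites))


def write_origin_map(locus_map: LocusMap, path) -> None:
    df = pd.DataFrame(
        [
            {
                "name": o.name,
                "side": o.side.value,
                "distance_bp": o.distance_bp,
                "efficiency": o.efficiency,
                "offset_min": o.offset_min,
            }
            for o in locus_map.origins
        ]
    )
    df.to_csv(path, sep="\t", index=False)


#: Direct-repeat reporter sites downstream of the barrier: site A 0.2 kb,
#: site B 12.4 kb.
DEFAULT_REPORTER_SITES = (("siteA", 200), ("siteB", 12400))


def packaged_origin_map(barrier_orientation: str = "AO") -> LocusMap:
    """The packaged eight-origin barrier-locus map.

    Distances are the published origin-midpoint-to-barrier values; the
    efficiency of ori-1253 is the published 84%, all other efficiencies are
    placeholders within the published 22-84% range (see the map file and the
    methods note).
    """
    ref = resources.files("rfbsim.data").joinpath("rts1_origin_map.tsv")
    with resources.as_file(ref) as path:
        return read_origin_map(
            path, barrier_orientation=barrier_orientation,
            reporter_sites=DEFAULT_REPORTER_SITES,
        )
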