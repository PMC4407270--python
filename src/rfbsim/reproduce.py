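"""Reproduce the printed kinetic tables and bounds from their stated inputs.

Everything here is recomputed at call time from the packaged locus geometry
and the observation brackets; nothing is copied from a results table.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .locus import LocusMap, TimingParams, arrival_time, packaged_origin_map, round_report
from .microscopy import BackgroundFocusParams, ImagingParams
from .pipeline import recovered_population_summary
from .simulate import SimulationParams

__all__ = [
    "reproduce_timing_table",
    "reproduce_kinetic_bounds",
    "end_to_end_demo",
]

#: Observation brackets (minutes post-anaphase) behind the kinetic bounds:
#: first PCNA foci (S start) and first barrier-colocalized Rad52 foci.
S_START_BRACKET_MIN = (10.0, 15.0)
FIRST_COLOC_BRACKET_MIN = (20.0, 25.0)


def reproduce_timing_table(
    locus_map: LocusMap | None = None,
    velocity_kb_min: float = 3.0,
) -> pd.DataFrame:
    """Origin-to-barrier distances and fork travel times at a fixed velocity.

    Times are computed from the distances (reporting-rounded to 0.1 min),
    never copied.
    """
    locus_map = locus_map or packaged_origin_map()
    params = TimingParams(velocity_kb_min=velocity_kb_min)
    rows = []
    for o in sorted(locus_map.origins, key=lambda o: (o.side.value, o.name)):
        rows.append({
            "origin": o.name,
            "side": o.side.value,
            "distance_bp": o.distance_bp,
            "time_min": round_report(arrival_time(o.distance_bp, params)),
        })
    return pd.DataFrame(rows, columns=["origin", "side", "distance_bp", "time_min"])


def reproduce_kinetic_bounds(locus_map: LocusMap | None = None,
                             velocity_kb_min: float = 3.0) -> dict:
    """Derived kinetic bounds, each with its arithmetic spelled out.

    * Nearest blocking-origin arrival after S start (earliest possible fork
      blockage at the barrier).
    * Earliest recombinase-recruitment window after blockage: first
      colocalized focus bracket minus (earliest S start + earliest blockage).
    * Arrival range of the more distal blocking origins (explains later
      Rad52 appearances).
    """
    locus_map = locus_map or packaged_origin_map()
    params = TimingParams(velocity_kb_min=velocity_kb_min)
    arrivals = sorted(
        (round_report(arrival_time(o.distance_bp, params)), o.name)
        for o in locus_map.blocking_origins
    )
    nearest_min, nearest_name = arrivals[0]
    distal = [t for t, _ in arrivals[1:]]
    s_lo = S_START_BRACKET_MIN[0]
    coloc_lo, coloc_hi = FIRST_COLOC_BRACKET_MIN
    recruit_lo = round_report(coloc_lo - s_lo - nearest_min)
    recruit_hi = round_report(coloc_hi - s_lo - nearest_min)
    return {
        "velocity_kb_min": velocity_kb_min,
        "nearest_origin": nearest_name,
        "nearest_origin_arrival_min": nearest_min,
        "nearest_origin_arithmetic": (
            f"{locus_map.origin(nearest_name).distance_bp} bp / "
            f"{velocity_kb_min * 1000:.0f} bp/min = {nearest_min} min after S start"
        ),
        "recruitment_window_lo_min": recruit_lo,
        "recruitment_window_hi_min": recruit_hi,
        "recruitment_arithmetic": (
            f"first colocalized focus at {coloc_lo}-{coloc_hi} min post-anaphase, "
            f"S start from {s_lo} min, blockage {nearest_min} min later: "
            f"{coloc_lo} - {s_lo} - {nearest_min} = {recruit_lo} min; "
            f"{coloc_hi} - {s_lo} - {nearest_min} = {recruit_hi} min"
        ),
        "distal_origin_arrival_lo_min": min(distal),
        "distal_origin_arrival_hi_min": max(distal),
        "distal_arithmetic": (
            "remaining blocking origins arrive at "
            + ", ".join(f"{t}" for t in distal) + " min after S start"
        ),
    }


def end_to_end_demo(seed: int = 0, out_dir=None, n_cells: int = 60) -> dict:
    """Small full-pipeline run: AO, IO and ori-1253-deleted populations are
    simulated, rendered, scored and summarized; the expected orderings
    (active orientation above inactive baseline; origin deletion extends
    colocalization) are asserted before returning the summaries."""
    from .locus import delete_origin

    imaging = ImagingParams()
    bg = BackgroundFocusParams()
    sim = SimulationParams()
    amap = packaged_origin_map("AO")
    imap = packaged_origin_map("IO")
    dmap = delete_origin(amap, "ori-1253")

    summaries = {}
    for name, m, offset in (("AO", amap, 0), ("IO", imap, 1), ("AO_ori1253d", dmap, 2)):
        s = recovered_population_summary(
            n_cells, m, sim_params=sim, imaging=imaging, bg_focus=bg,
            seed=seed * 3 + offset,
        )
        summaries[name] = s.to_dict()

    ao = summaries["AO"]
    io = summaries["IO"]
    dd = summaries["AO_ori1253d"]
    if not ao["pct_cells_colocalizing"] > io["pct_cells_colocalizing"]:
        raise AssertionError("demo: AO colocalization did not exceed IO baseline")
    if not dd["mean_coloc_timepoints_coloc_cells"] > ao["mean_coloc_timepoints_coloc_cells"]:
        raise AssertionError("demo: origin deletion did not extend colocalization")

    result = {"seed": seed, "n_cells": n_cells, "summaries": summaries}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "demo_summary.json").write_text(json.dumps(result, indent=2))
    return result
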