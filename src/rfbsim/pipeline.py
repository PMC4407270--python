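"""End-to-end drivers: simulate timelines, render movies, score, summarize.

Two routes through the same generative model:

* the *imaging* route renders each cell's synthetic movie and recovers flags
  with the detection/colocalization scorer — the full pipeline under test;
* the *truth* route reads the per-frame focus ground truth directly, skipping
  rendering and detection — cheap enough to evaluate generator expectations
  at large n, against which the imaging route's recovery is compared.

Cells are rendered as individual single-cell fields (a few MB each) rather
than one large mosaic, which keeps memory flat in population size; the model
is identical.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .foci import DetectionParams, build_rasters, score_movie, summarize_rasters, RasterSummary
from .locus import LocusMap, TimingParams
from .microscopy import (
    BackgroundFocusParams,
    CellTruth,
    ImagingParams,
    grid_layout,
    render_movie,
    _build_cell_truth,
)
from .simulate import CellTimeline, SimulationParams, simulate_population

__all__ = [
    "truth_frame_flags",
    "score_population",
    "truth_population_summary",
    "recovered_population_summary",
]


def truth_frame_flags(truths: Sequence[CellTruth], imaging: ImagingParams) -> pd.DataFrame:
    """Per-frame flags straight from ground truth (no rendering/detection)."""
    rows = []
    for c in truths:
        rad52 = c.rad52_frames()
        coloc = c.coloc_frames()
        pcna = {k for e in c.events if e.channel == "pcna" for k in e.frames}
        for k in range(imaging.n_frames):
            rows.append({
                "cell_id": c.cell_id,
                "frame": k,
                "time_min": imaging.frame_time(k),
                "has_rad52": k in rad52,
                "colocalized": k in coloc,
                "has_pcna": k in pcna,
            })
    return pd.DataFrame(rows)


def _anaphase_frame(population: Sequence[CellTimeline]) -> pd.DataFrame:
    return pd.DataFrame(
        {"cell_id": [c.cell_id for c in population],
         "anaphase_min": [c.anaphase_min for c in population],
         "mask_label": [1] * len(population)}
    )


def score_population(
    population: Sequence[CellTimeline],
    imaging: ImagingParams | None = None,
    detection: DetectionParams | None = None,
    bg_focus: BackgroundFocusParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    noise_free: bool = False,
    truth_only: bool = False,
) -> tuple[pd.DataFrame, list[CellTruth]]:
    """Render and score each cell; return (frame flags, ground truths).

    With ``truth_only`` the flags come from the ground truth directly (the
    cheap route for generator expectations).
    """
    imaging = imaging or ImagingParams()
    detection = detection or DetectionParams()
    bg_focus = bg_focus or BackgroundFocusParams()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = root.spawn(len(population))

    truths: list[CellTruth] = []
    flag_parts: list[pd.DataFrame] = []
    for cell, ss in zip(population, streams):
        if truth_only:
            # mirror render_movie's stream layout so identical seeds give
            # identical truths on both routes
            truth_rng = np.random.default_rng(ss.spawn(2)[0].spawn(1)[0])
            layout = grid_layout(1, imaging, cell_ids=[cell.cell_id])
            truth = _build_cell_truth(cell, layout.sites[0], imaging, bg_focus, truth_rng)
            truths.append(truth)
            flag_parts.append(truth_frame_flags([truth], imaging))
        else:
            movie, truth = render_movie(
                [cell], params=imaging, bg_focus=bg_focus, seed=ss,
                noise_free=noise_free,
            )
            truths.extend(truth.cells)
            labels = movie.layout.label_volume(imaging)
            _, flags = score_movie(movie, labels, _anaphase_frame([cell]), detection)
            flag_parts.append(flags)
    return pd.concat(flag_parts, ignore_index=True), truths


def _summary_from_flags(flags: pd.DataFrame, population: Sequence[CellTimeline],
                        imaging: ImagingParams) -> RasterSummary:
    raster = build_rasters(flags, _anaphase_frame(population)[["cell_id", "anaphase_min"]]
                           .assign(mask_label=1), imaging)
    return summarize_rasters(raster, imaging.frame_interval_min)


def truth_population_summary(
    n_cells: int,
    locus_map: LocusMap,
    timing: TimingParams | None = None,
    sim_params: SimulationParams | None = None,
    imaging: ImagingParams | None = None,
    bg_focus: BackgroundFocusParams | None = None,
    seed: int = 0,
) -> RasterSummary:
    """Generator-expectation route: simulate + ground-truth flags, no imaging."""
    imaging = imaging or ImagingParams()
    root = np.random.SeedSequence(seed)
    sim_ss, score_ss = root.spawn(2)
    population = simulate_population(n_cells, locus_map, timing, sim_params, seed=sim_ss)
    flags, _ = score_population(
        population, imaging, bg_focus=bg_focus, seed=score_ss, truth_only=True,
    )
    return _summary_from_flags(flags, population, imaging)


def recovered_population_summary(
    n_cells: int,
    locus_map: LocusMap,
    timing: TimingParams | None = None,
    sim_params: SimulationParams | None = None,
    imaging: ImagingParams | None = None,
    detection: DetectionParams | None = None,
    bg_focus: BackgroundFocusParams | None = None,
    seed: int = 0,
    noise_free: bool = False,
) -> RasterSummary:
    """Full-pipeline route: simulate, render, detect, colocalize, summarize."""
    imaging = imaging or ImagingParams()
    root = np.random.SeedSequence(seed)
    sim_ss, score_ss = root.spawn(2)
    population = simulate_population(n_cells, locus_map, timing, sim_params, seed=sim_ss)
    flags, _ = score_population(
        population, imaging, detection, bg_focus, seed=score_ss,
        noise_free=noise_free,
    )
    return _summary_from_flags(flags, population, imaging)
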