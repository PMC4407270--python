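"""Ground-truthed synthetic 3D time-lapse movies of barrier-locus cells.

Emulates the imaging regime of the live-cell experiments: asynchronous
fission-yeast cells imaged every 5 min for 90 min post-anaphase, 16 focal
planes at 0.3 um, three channels — a lacO/LacI locus marker (always visible),
Rad52 (visible while the cell's timeline says recombination is engaged), and
PCNA (multiple nuclear foci during S-phase).  Foci are 3D Gaussian spots on a
uniform nuclear background; Poisson shot noise plus Gaussian read noise are
applied last, so the noise-free expectation is available for every voxel.

Truth-space colocalization is a binary per-frame attribute: a Rad52 focus
engaged at the barrier is rendered within a sub-pixel offset of the marker
focus, any other ("elsewhere") Rad52 focus at a configurable minimum
separation.  A configurable fraction of cells receives one elsewhere event
per movie, emulating the background of spontaneous repair foci; a fraction of
those sit at the marker by chance, which is what produces the nonzero
baseline colocalization of inactive-orientation cells.

Pixel size and nuclear dimensions were not published and are documented
assumptions (see docs/methods.md).  Coordinates are 0-based; z index 0 is the
bottom plane.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .simulate import CellTimeline

__all__ = [
    "CHANNELS",
    "ImagingParams",
    "BackgroundFocusParams",
    "CellSite",
    "Layout",
    "grid_layout",
    "FocusEvent",
    "CellTruth",
    "GroundTruth",
    "SyntheticMovie",
    "render_movie",
    "write_movie",
    "read_movie",
    "MovieFormatError",
]

CHANNELS = ("marker", "rad52", "pcna")


@dataclass(frozen=True)
class ImagingParams:
    """Acquisition and optics parameters.

    Defaults: 19 frames at 5 min covering 0-90 min, 16 z-planes at 0.3 um.
    ``pixel_size_um`` (0.16: EMCCD 16-um pixels through a 100x objective) and
    the nuclear radius are assumptions, not published values.
    """

    frame_interval_min: float = 5.0
    n_frames: int = 19
    z_planes: int = 16
    z_step_um: float = 0.3
    pixel_size_um: float = 0.16
    psf_sigma_xy_um: float = 0.20
    psf_sigma_z_um: float = 0.50
    base_level: float = 20.0      # extranuclear counts
    nuclear_level: float = 100.0  # counts inside the nucleus
    focus_amplitude: dict = field(
        default_factory=lambda: {"marker": 600.0, "rad52": 600.0, "pcna": 500.0}
    )
    read_noise_sigma: float = 4.0
    poisson_noise: bool = True
    nucleus_radius_um: float = 1.2
    n_pcna_foci: int = 4

    def __post_init__(self):
        for name in ("frame_interval_min", "z_step_um", "pixel_size_um",
                     "psf_sigma_xy_um", "psf_sigma_z_um", "nucleus_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_frames < 1 or self.z_planes < 1:
            raise ValueError("n_frames and z_planes must be >= 1")
        if any(a < 0 for a in self.focus_amplitude.values()):
            raise ValueError("focus amplitudes must be >= 0")

    def frame_time(self, k: int) -> float:
        return k * self.frame_interval_min

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min


@dataclass(frozen=True)
class BackgroundFocusParams:
    """"Elsewhere" Rad52 repair foci unrelated to the barrier.

    Calibrated so inactive-orientation summaries sit near the observed
    baseline: ~79% of cells show some Rad52 focus, ~20% a chance
    colocalization lasting 1-2 timepoints (mean 1.5).
    """

    prob_per_cell: float = 0.79
    coloc_prob: float = 0.25
    start_bracket_min: tuple[float, float] = (20.0, 80.0)
    duration_timepoints: tuple[int, ...] = (1, 2)
    min_separation_um: float = 0.8
    coloc_offset_um: float = 0.12


@dataclass(frozen=True)
class CellSite:
    """Placement of one cell's nucleus in the field (pixel coordinates)."""

    cell_id: str
    center_y_px: float
    center_x_px: float
    center_z: float
    radius_um: float


@dataclass(frozen=True)
class Layout:
    field_shape_px: tuple[int, int]  # (Y, X)
    sites: tuple[CellSite, ...]

    def __post_init__(self):
        object.__setattr__(self, "sites", tuple(self.sites))
        h, w = self.field_shape_px
        for s in self.sites:
            if not (0 <= s.center_y_px < h and 0 <= s.center_x_px < w):
                raise ValueError(f"cell {s.cell_id} lies outside the field")

    def nucleus_mask(self, site: CellSite, params: ImagingParams) -> np.ndarray:
        """Boolean (Z, Y, X) ellipsoid mask of one nucleus."""
        zz, yy, xx = np.meshgrid(
            np.arange(params.z_planes),
            np.arange(self.field_shape_px[0]),
            np.arange(self.field_shape_px[1]),
            indexing="ij",
        )
        r_xy = site.radius_um / params.pixel_size_um
        r_z = site.radius_um / params.z_step_um
        d2 = (
            ((yy - site.center_y_px) ** 2 + (xx - site.center_x_px) ** 2) / r_xy ** 2
            + ((zz - site.center_z) ** 2) / r_z ** 2
        )
        return d2 <= 1.0

    def label_volume(self, params: ImagingParams) -> np.ndarray:
        """(Z, Y, X) integer label volume: 0 background, i+1 for sites[i]."""
        labels = np.zeros((params.z_planes, *self.field_shape_px), dtype=np.int32)
        for i, site in enumerate(self.sites):
            labels[self.nucleus_mask(site, params)] = i + 1
        return labels

    def anaphase_table(self, population: Sequence[CellTimeline]) -> pd.DataFrame:
        rows = [
            {"cell_id": c.cell_id, "anaphase_min": c.anaphase_min, "mask_label": i + 1}
            for i, c in enumerate(population)
        ]
        return pd.DataFrame(rows)


def grid_layout(
    n_cells: int,
    params: ImagingParams,
    tile_px: int = 32,
    cell_ids: Sequence[str] | None = None,
) -> Layout:
    """Non-overlapping square grid of nuclei, one per tile."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    r_px = params.nucleus_radius_um / params.pixel_size_um
    if tile_px < 2 * (r_px + 2):
        raise ValueError(
            f"tile_px={tile_px} too small for nucleus radius {r_px:.1f} px"
        )
    ncol = int(math.ceil(math.sqrt(n_cells)))
    nrow = int(math.ceil(n_cells / ncol))
    sites = []
    for i in range(n_cells):
        row, col = divmod(i, ncol)
        cid = cell_ids[i] if cell_ids is not None else f"cell{i:04d}"
        sites.append(
            CellSite(
                cell_id=cid,
                center_y_px=row * tile_px + tile_px / 2,
                center_x_px=col * tile_px + tile_px / 2,
                center_z=(params.z_planes - 1) / 2,
                radius_um=params.nucleus_radius_um,
            )
        )
    return Layout((nrow * tile_px, ncol * tile_px), tuple(sites))


@dataclass(frozen=True)
class FocusEvent:
    """One focus: a channel, a fixed 3D position, and the frames it spans."""

    channel: str
    frames: tuple[int, ...]
    z: float
    y: float
    x: float
    amplitude: float
    colocalized: bool = False  # truth attribute, rad52 channel only


@dataclass(frozen=True)
class CellTruth:
    cell_id: str
    anaphase_min: float
    site: CellSite
    events: tuple[FocusEvent, ...]

    def foci_in_frame(self, channel: str, frame: int) -> list[FocusEvent]:
        return [e for e in self.events if e.channel == channel and frame in e.frames]

    def coloc_frames(self) -> set[int]:
        out: set[int] = set()
        for e in self.events:
            if e.channel == "rad52" and e.colocalized:
                out.update(e.frames)
        return out

    def rad52_frames(self) -> set[int]:
        out: set[int] = set()
        for e in self.events:
            if e.channel == "rad52":
                out.update(e.frames)
        return out


@dataclass(frozen=True)
class GroundTruth:
    cells: tuple[CellTruth, ...]
    params: ImagingParams

    def to_json_dict(self) -> dict:
        return {
            "cells": [
                {
                    "cell_id": c.cell_id,
                    "anaphase_min": c.anaphase_min,
                    "site": asdict(c.site),
                    "events": [asdict(e) for e in c.events],
                }
                for c in self.cells
            ]
        }


@dataclass
class SyntheticMovie:
    """5-D intensity stack (time, channel, z, y, x), uint16 counts."""

    data: np.ndarray
    params: ImagingParams
    layout: Layout
    channels: tuple[str, ...] = CHANNELS
    seed: int | None = None

    def __post_init__(self):
        expected = (
            self.params.n_frames, len(self.channels), self.params.z_planes,
            *self.layout.field_shape_px,
        )
        if self.data.shape != expected:
            raise ValueError(f"stack shape {self.data.shape} != expected {expected}")
        if self.data.min() < 0:
            raise ValueError("intensity counts must be >= 0")


class MovieFormatError(ValueError):
    """A movie file or its sidecar metadata is malformed or missing."""


def _frames_in_interval(start: float, end: float, anaphase: float,
                        params: ImagingParams) -> tuple[int, ...]:
    """Movie frames whose absolute time lies in [anaphase+start, anaphase+end]."""
    times = params.frame_times
    lo, hi = anaphase + start, anaphase + end
    return tuple(int(k) for k in np.nonzero((times >= lo) & (times <= hi))[0])


def _random_point_in_nucleus(site: CellSite, params: ImagingParams,
                             rng: np.random.Generator,
                             max_frac: float = 0.5) -> tuple[float, float, float]:
    """Uniform point within ``max_frac`` of the nuclear radius (z, y, x)."""
    r_xy = site.radius_um / params.pixel_size_um
    r_z = site.radius_um / params.z_step_um
    while True:
        u = rng.uniform(-1, 1, size=3)
        if np.sum(u ** 2) <= 1.0:
            break
    u *= max_frac
    return (
        site.center_z + u[0] * r_z,
        site.center_y_px + u[1] * r_xy,
        site.center_x_px + u[2] * r_xy,
    )


def _build_cell_truth(
    timeline: CellTimeline,
    site: CellSite,
    params: ImagingParams,
    bg: BackgroundFocusParams,
    rng: np.random.Generator,
) -> CellTruth:
    events: list[FocusEvent] = []
    amp = params.focus_amplitude
    all_frames = tuple(range(params.n_frames))

    marker_pos = _random_point_in_nucleus(site, params, rng, max_frac=0.35)
    events.append(FocusEvent("marker", all_frames, *marker_pos, amp["marker"]))

    def offset_from_marker(radius_um: float) -> tuple[float, float, float]:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dz = direction[0] * radius_um / params.z_step_um
        dy = direction[1] * radius_um / params.pixel_size_um
        dx = direction[2] * radius_um / params.pixel_size_um
        return (marker_pos[0] + dz, marker_pos[1] + dy, marker_pos[2] + dx)

    # Barrier-engaged Rad52: sub-pixel offset from the marker.
    if timeline.has_rad52_interval:
        frames = _frames_in_interval(
            timeline.rad52_start_min, timeline.rad52_end_min,
            timeline.anaphase_min, params,
        )
        if frames:
            pos = offset_from_marker(rng.uniform(0, bg.coloc_offset_um))
            events.append(FocusEvent("rad52", frames, *pos, amp["rad52"], colocalized=True))

    # Elsewhere repair focus (may itself sit at the marker by chance).
    if rng.random() < bg.prob_per_cell:
        start = rng.uniform(*bg.start_bracket_min)
        dur_tp = int(rng.choice(bg.duration_timepoints))
        # background events occupy whole acquisition frames
        k0 = int(round((timeline.anaphase_min + start) / params.frame_interval_min))
        frames = tuple(
            k for k in range(k0, k0 + dur_tp) if 0 <= k < params.n_frames
        )
        if frames:
            chance_coloc = rng.random() < bg.coloc_prob
            if chance_coloc:
                pos = offset_from_marker(rng.uniform(0, bg.coloc_offset_um))
            else:
                # keep well clear of the marker, inside the nucleus
                for _ in range(100):
                    pos = _random_point_in_nucleus(site, params, rng, max_frac=0.9)
                    d_um = math.sqrt(
                        ((pos[0] - marker_pos[0]) * params.z_step_um) ** 2
                        + ((pos[1] - marker_pos[1]) * params.pixel_size_um) ** 2
                        + ((pos[2] - marker_pos[2]) * params.pixel_size_um) ** 2
                    )
                    if d_um >= bg.min_separation_um:
                        break
                else:  # pragma: no cover - geometry guarantees a hit
                    raise RuntimeError("could not place a separated background focus")
            events.append(
                FocusEvent("rad52", frames, *pos, amp["rad52"], colocalized=chance_coloc)
            )

    # PCNA: several nuclear foci during the replication period.
    pcna_frames = _frames_in_interval(
        timeline.pcna_start_min, timeline.pcna_end_min, timeline.anaphase_min, params,
    )
    if pcna_frames and amp["pcna"] > 0:
        for _ in range(params.n_pcna_foci):
            pos = _random_point_in_nucleus(site, params, rng, max_frac=0.8)
            events.append(FocusEvent("pcna", pcna_frames, *pos, amp["pcna"]))

    return CellTruth(timeline.cell_id, timeline.anaphase_min, site, tuple(events))


def _add_gaussian_spot(plane_stack: np.ndarray, event: FocusEvent,
                       params: ImagingParams) -> None:
    """Add a 3D Gaussian to a (Z, Y, X) float volume, local patch only."""
    sz = params.psf_sigma_z_um / params.z_step_um
    sxy = params.psf_sigma_xy_um / params.pixel_size_um
    Z, Y, X = plane_stack.shape
    z0 = max(int(event.z - 4 * sz), 0)
    z1 = min(int(event.z + 4 * sz) + 2, Z)
    y0 = max(int(event.y - 4 * sxy), 0)
    y1 = min(int(event.y + 4 * sxy) + 2, Y)
    x0 = max(int(event.x - 4 * sxy), 0)
    x1 = min(int(event.x + 4 * sxy) + 2, X)
    zz = np.arange(z0, z1)[:, None, None]
    yy = np.arange(y0, y1)[None, :, None]
    xx = np.arange(x0, x1)[None, None, :]
    g = event.amplitude * np.exp(
        -((zz - event.z) ** 2) / (2 * sz ** 2)
        - ((yy - event.y) ** 2) / (2 * sxy ** 2)
        - ((xx - event.x) ** 2) / (2 * sxy ** 2)
    )
    plane_stack[z0:z1, y0:y1, x0:x1] += g


def render_movie(
    population: Sequence[CellTimeline],
    params: ImagingParams | None = None,
    layout: Layout | None = None,
    bg_focus: BackgroundFocusParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    noise_free: bool = False,
) -> tuple[SyntheticMovie, GroundTruth]:
    """Render a multi-cell field movie with its ground truth.

    Spots are added to the nuclear background as 3D Gaussians; Poisson shot
    noise on the expectation and Gaussian read noise are applied last (or
    skipped entirely with ``noise_free``).
    """
    params = params or ImagingParams()
    if layout is None:
        layout = grid_layout(
            len(population), params, cell_ids=[c.cell_id for c in population]
        )
    if len(layout.sites) != len(population):
        raise ValueError("layout must provide one site per cell")
    bg_focus = bg_focus or BackgroundFocusParams()
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    truth_ss, noise_ss = root.spawn(2)
    truth_streams = truth_ss.spawn(len(population))

    cells = tuple(
        _build_cell_truth(tl, site, params, bg_focus, np.random.default_rng(ss))
        for tl, site, ss in zip(population, layout.sites, truth_streams)
    )
    truth = GroundTruth(cells, params)

    T, C = params.n_frames, len(CHANNELS)
    Z = params.z_planes
    Y, X = layout.field_shape_px
    expectation = np.full((T, C, Z, Y, X), params.base_level, dtype=np.float64)

    # Nuclear background (same for every frame and channel).
    nuc = np.zeros((Z, Y, X), dtype=bool)
    for site in layout.sites:
        nuc |= layout.nucleus_mask(site, params)
    expectation[:, :, nuc] += params.nuclear_level - params.base_level

    for cell in cells:
        for e in cell.events:
            ci = CHANNELS.index(e.channel)
            for k in e.frames:
                _add_gaussian_spot(expectation[k, ci], e, params)

    if noise_free:
        data = np.round(expectation).astype(np.uint16)
    else:
        rng = np.random.default_rng(noise_ss)
        noisy = rng.poisson(expectation).astype(np.float64)
        noisy += rng.normal(0.0, params.read_noise_sigma, size=noisy.shape)
        data = np.clip(np.round(noisy), 0, np.iinfo(np.uint16).max).astype(np.uint16)

    seed_int = None
    if not isinstance(seed, np.random.SeedSequence):
        seed_int = int(seed)
    movie = SyntheticMovie(data, params, layout, CHANNELS, seed_int)
    return movie, truth


# --------------------------------------------------------------------------
# File round trip: multi-page TIFF plus JSON sidecar; truth as JSON.

def write_movie(movie: SyntheticMovie, out_dir, truth: GroundTruth | None = None,
                stem: str = "movie") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif = out_dir / f"{stem}.tif"
    tifffile.imwrite(tif, movie.data)
    sidecar = {
        "channels": list(movie.channels),
        "seed": movie.seed,
        "imaging_params": {**asdict(movie.params)},
        "layout": {
            "field_shape_px": list(movie.layout.field_shape_px),
            "sites": [asdict(s) for s in movie.layout.sites],
        },
        "axes": "TCZYX",
        "shape": list(movie.data.shape),
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    if truth is not None:
        (out_dir / f"{stem}.truth.json").write_text(
            json.dumps(truth.to_json_dict(), indent=2)
        )
    return tif


def read_movie(tif_path) -> SyntheticMovie:
    tif_path = Path(tif_path)
    sidecar_path = tif_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise MovieFormatError(f"missing sidecar metadata: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("channels", "imaging_params", "layout", "shape"):
        if key not in meta:
            raise MovieFormatError(f"sidecar missing field {key!r}")
    data = tifffile.imread(tif_path)
    data = np.asarray(data).reshape(meta["shape"])
    params = ImagingParams(**meta["imaging_params"])
    layout = Layout(
        tuple(meta["layout"]["field_shape_px"]),
        tuple(CellSite(**s) for s in meta["layout"]["sites"]),
    )
    return SyntheticMovie(data, params, layout, tuple(meta["channels"]), meta.get("seed"))
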