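"""Focus detection, colocalization and per-cell raster summaries.

Codifies the manual scoring rules of the source experiments: a focus is a
connected set of voxels at least k times brighter than the background of its
cell (k between 3 and 5, default 3) containing a 2x2-pixel in-plane square in
at least one z-section; foci in two channels colocalize when their voxel sets
overlap by at least 2 voxels.  Per cell, the presence of a Rad52 focus and
its colocalization with the locus marker is recorded every 5 min for 90 min
post-anaphase, and population summaries (incidence, mean timepoints, longest
consecutive run, end relative to PCNA-focus loss, discontinuity) are
computed from those rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .microscopy import SyntheticMovie, ImagingParams

__all__ = [
    "DetectionParams",
    "FocusCall",
    "detect_foci",
    "colocalize",
    "score_movie",
    "build_rasters",
    "RasterSummary",
    "summarize_rasters",
    "duration_bounds",
]

_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


@dataclass(frozen=True)
class DetectionParams:
    """Threshold and footprint rules.

    ``k`` multiplies the background estimate (median intensity within the
    cell mask, re-estimated once with detected focus voxels excluded, or the
    whole-frame median with ``background_estimator='frame-median'``).
    """

    k: float = 3.0
    min_footprint_px: tuple[int, int] = (2, 2)
    min_overlap_px: int = 2
    background_estimator: str = "cell-median"
    projection_overlap: bool = False  # overlap on 2D max-projection footprints

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if min(self.min_footprint_px) < 1 or self.min_overlap_px < 1:
            raise ValueError("footprint and overlap must be >= 1 px")
        if self.background_estimator not in ("cell-median", "frame-median"):
            raise ValueError("unknown background estimator")


@dataclass(frozen=True)
class FocusCall:
    """One detected focus: connected voxel set above threshold."""

    voxels: frozenset  # of (z, y, x) tuples
    centroid: tuple[float, float, float]  # (z, y, x), intensity weighted
    peak: float
    integrated: float
    cell_id: str = ""
    channel: str = ""
    frame: int = -1

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def footprint_2d(self) -> frozenset:
        return frozenset((y, x) for _, y, x in self.voxels)


def _has_square(slice_mask: np.ndarray, h: int, w: int) -> bool:
    if slice_mask.shape[0] < h or slice_mask.shape[1] < w:
        return False
    window = slice_mask[: slice_mask.shape[0] - h + 1, : slice_mask.shape[1] - w + 1].copy()
    for dy in range(h):
        for dx in range(w):
            window &= slice_mask[dy: slice_mask.shape[0] - h + 1 + dy,
                                 dx: slice_mask.shape[1] - w + 1 + dx]
    return bool(window.any())


def _component_calls(vol: np.ndarray, above: np.ndarray,
                     params: DetectionParams) -> list[FocusCall]:
    labels, n = ndimage.label(above, structure=_STRUCT_3D)
    calls = []
    h, w = params.min_footprint_px
    for sl, idx in zip(ndimage.find_objects(labels), range(1, n + 1)):
        comp = labels[sl] == idx
        # footprint rule: an in-plane h x w solid square in some z-section
        if not any(_has_square(comp[z], h, w) for z in range(comp.shape[0])):
            continue
        zz, yy, xx = np.nonzero(comp)
        z0, y0, x0 = sl[0].start, sl[1].start, sl[2].start
        vals = vol[sl][comp]
        wsum = vals.sum()
        centroid = (
            float((zz * vals).sum() / wsum) + z0,
            float((yy * vals).sum() / wsum) + y0,
            float((xx * vals).sum() / wsum) + x0,
        )
        voxels = frozenset(
            (int(z + z0), int(y + y0), int(x + x0)) for z, y, x in zip(zz, yy, xx)
        )
        calls.append(FocusCall(voxels, centroid, float(vals.max()), float(wsum)))
    return calls


def detect_foci(volume: np.ndarray, mask: np.ndarray,
                params: DetectionParams | None = None) -> list[FocusCall]:
    """Detect foci in one (Z, Y, X) volume restricted to a cell mask.

    Threshold = k x background; background = median within the mask,
    re-estimated once with first-pass focus voxels excluded.  Deterministic.
    """
    params = params or DetectionParams()
    vol = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if not mask.any():
        raise ValueError("empty cell mask")

    def background(exclude: np.ndarray | None) -> float:
        if params.background_estimator == "frame-median":
            sel = np.ones_like(mask) if exclude is None else ~exclude
        else:
            sel = mask if exclude is None else (mask & ~exclude)
        if not sel.any():
            sel = mask
        return float(np.median(vol[sel]))

    thr = params.k * background(None)
    above = (vol > thr) & mask
    calls = _component_calls(vol, above, params)
    if calls:
        # one background iteration with focus voxels excluded
        exclude = np.zeros_like(mask)
        for c in calls:
            for z, y, x in c.voxels:
                exclude[z, y, x] = True
        thr = params.k * background(exclude)
        above = (vol > thr) & mask
        calls = _component_calls(vol, above, params)
    return calls


def colocalize(calls_a: Sequence[FocusCall], calls_b: Sequence[FocusCall],
               min_overlap_px: int = 2,
               projection: bool = False) -> list[tuple[FocusCall, FocusCall]]:
    """Pair foci across two channels by voxel-set overlap.

    A pair is reported when the intersection holds at least
    ``min_overlap_px`` voxels; each call pairs with at most one partner
    (largest overlap wins, ties broken by call order).  Symmetric up to pair
    order.  With ``projection`` the overlap is counted on 2D
    maximum-projection footprints instead of 3D voxel sets.
    """
    cand = []
    for i, a in enumerate(calls_a):
        fa = a.footprint_2d() if projection else a.voxels
        for j, b in enumerate(calls_b):
            fb = b.footprint_2d() if projection else b.voxels
            ov = len(fa & fb)
            if ov >= min_overlap_px:
                cand.append((ov, i, j))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for ov, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((calls_a[i], calls_b[j]))
    return pairs


# --------------------------------------------------------------------------
# Movie-level scoring

def score_movie(
    movie: SyntheticMovie,
    labels: np.ndarray,
    anaphase_table: pd.DataFrame,
    params: DetectionParams | None = None,
    return_call_objects: bool = False,
):
    """Detect and colocalize foci in every cell and frame of a movie.

    ``labels`` is a (Z, Y, X) integer volume (0 = background) and
    ``anaphase_table`` maps cell_id -> anaphase_min, mask_label.

    Returns (calls, frame_flags): one row per focus call, and one row per
    cell x frame with has_rad52 / colocalized / has_pcna flags on the
    absolute movie clock.  With ``return_call_objects`` the FocusCall
    objects (with their voxel sets, in field coordinates) are returned as a
    third element.
    """
    params = params or DetectionParams()
    channels = list(movie.channels)
    for ch in ("marker", "rad52", "pcna"):
        if ch not in channels:
            raise ValueError(f"movie lacks channel {ch!r}")
    boxes = ndimage.find_objects(labels)

    call_rows = []
    flag_rows = []
    call_objects: list[FocusCall] = []
    margin = 2
    for _, cellrow in anaphase_table.iterrows():
        cell_id = cellrow["cell_id"]
        lab = int(cellrow["mask_label"])
        sl = boxes[lab - 1]
        if sl is None:
            raise ValueError(f"mask label {lab} absent from label volume")
        sl = tuple(
            slice(max(s.start - margin, 0), min(s.stop + margin, dim))
            for s, dim in zip(sl, labels.shape)
        )
        mask = labels[sl] == lab
        for k in range(movie.params.n_frames):
            per_channel: dict[str, list[FocusCall]] = {}
            origin = tuple(s.start for s in sl)
            for ch in ("marker", "rad52", "pcna"):
                vol = movie.data[k, channels.index(ch)][sl]
                calls = [
                    FocusCall(
                        frozenset(tuple(v + o for v, o in zip(vox, origin))
                                  for vox in c.voxels),
                        tuple(c + o for c, o in zip(c.centroid, origin)),
                        c.peak, c.integrated,
                        cell_id=cell_id, channel=ch, frame=k,
                    )
                    for c in detect_foci(vol, mask, params)
                ]
                per_channel[ch] = calls
                call_objects.extend(calls)
                for c in calls:
                    call_rows.append({
                        "cell_id": cell_id, "frame": k, "channel": ch,
                        "time_min": movie.params.frame_time(k),
                        "z": c.centroid[0], "y": c.centroid[1], "x": c.centroid[2],
                        "n_voxels": c.n_voxels, "peak": c.peak,
                        "integrated": c.integrated,
                    })
            pairs = colocalize(
                per_channel["rad52"], per_channel["marker"],
                params.min_overlap_px, params.projection_overlap,
            )
            flag_rows.append({
                "cell_id": cell_id,
                "frame": k,
                "time_min": movie.params.frame_time(k),
                "has_rad52": bool(per_channel["rad52"]),
                "colocalized": bool(pairs),
                "has_pcna": bool(per_channel["pcna"]),
            })
    calls_df = pd.DataFrame(
        call_rows,
        columns=["cell_id", "frame", "channel", "time_min", "z", "y", "x",
                 "n_voxels", "peak", "integrated"],
    )
    flags_df = pd.DataFrame(flag_rows)
    if return_call_objects:
        return calls_df, flags_df, call_objects
    return calls_df, flags_df


# --------------------------------------------------------------------------
# Anaphase-staged rasters

STAGED_TIMEPOINTS_MIN = tuple(range(0, 95, 5))  # 0, 5, ..., 90


def build_rasters(
    frame_flags: pd.DataFrame,
    anaphase_table: pd.DataFrame,
    imaging: ImagingParams,
    timepoints_min: Sequence[float] = STAGED_TIMEPOINTS_MIN,
) -> pd.DataFrame:
    """Stage per-frame flags onto per-cell timepoints post-anaphase.

    Each staged timepoint t maps to the acquisition frame minimising
    |frame_time - (anaphase + t)| (ties to the earlier frame).  Cells whose
    staged window is not fully covered by acquisitions are excluded.
    Returns one row per (cell, timepoint).
    """
    if "anaphase_min" not in anaphase_table.columns:
        raise ValueError("anaphase table must carry anaphase_min")
    rows = []
    dt = imaging.frame_interval_min
    for _, cellrow in anaphase_table.iterrows():
        cell_id = cellrow["cell_id"]
        if pd.isna(cellrow["anaphase_min"]):
            raise ValueError(f"cell {cell_id}: missing anaphase time")
        ana = float(cellrow["anaphase_min"])
        sub = frame_flags[frame_flags["cell_id"] == cell_id].set_index("frame")
        complete = True
        cell_rows = []
        for t in timepoints_min:
            target = ana + t
            k = int(math.ceil(target / dt - 0.5))  # nearest frame, ties earlier
            if not (0 <= k < imaging.n_frames) or abs(k * dt - target) > dt / 2:
                complete = False
                break
            if k not in sub.index:
                complete = False
                break
            f = sub.loc[k]
            cell_rows.append({
                "cell_id": cell_id,
                "timepoint_min": float(t),
                "frame": k,
                "has_rad52": bool(f["has_rad52"]),
                "colocalized": bool(f["colocalized"]) and bool(f["has_rad52"]),
                "has_pcna": bool(f["has_pcna"]),
            })
        if complete:
            rows.extend(cell_rows)
    return pd.DataFrame(
        rows, columns=["cell_id", "timepoint_min", "frame",
                       "has_rad52", "colocalized", "has_pcna"],
    )


def _longest_run(flags: np.ndarray) -> int:
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def _gaps(flags: np.ndarray) -> int:
    """Longest internal gap (timepoints) between the first and last True."""
    idx = np.nonzero(flags)[0]
    if len(idx) < 2:
        return 0
    longest = 0
    for a, b in zip(idx[:-1], idx[1:]):
        longest = max(longest, b - a - 1)
    return longest


@dataclass(frozen=True)
class RasterSummary:
    n_cells: int
    pct_cells_with_rad52: float
    mean_rad52_timepoints: float
    sem_rad52_timepoints: float
    pct_cells_colocalizing: float
    mean_coloc_timepoints_all_cells: float
    mean_coloc_timepoints_coloc_cells: float
    sem_coloc_timepoints_coloc_cells: float
    mean_longest_run_timepoints: float
    pct_end_before_pcna_loss: float
    n_cells_with_gaps: int
    pct_cells_with_gaps: float
    max_gap_min: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_rasters(raster: pd.DataFrame,
                      frame_interval_min: float = 5.0) -> RasterSummary:
    """Population summary of anaphase-staged rasters.

    Mean colocalized timepoints is reported with both denominators (all
    complete cells, and colocalizing cells only).  The longest run is the
    maximal consecutive colocalized streak per cell, averaged over
    colocalizing cells.
    """
    if raster.empty:
        raise ValueError("no complete rasters to summarize")
    cells = []
    for cell_id, g in raster.sort_values("timepoint_min").groupby("cell_id"):
        rad52 = g["has_rad52"].to_numpy()
        coloc = g["colocalized"].to_numpy()
        pcna = g["has_pcna"].to_numpy()
        t = g["timepoint_min"].to_numpy()
        rec = {
            "has_rad52": bool(rad52.any()),
            "n_rad52": int(rad52.sum()),
            "colocalizes": bool(coloc.any()),
            "n_coloc": int(coloc.sum()),
            "longest_run": _longest_run(coloc),
            "gap_tp": _gaps(coloc),
        }
        if coloc.any() and pcna.any():
            # float, not np.bool_: object-dtype bool sums saturate in pandas
            rec["end_before_pcna"] = float(t[coloc][-1] < t[pcna][-1])
        else:
            rec["end_before_pcna"] = math.nan
        cells.append(rec)
    df = pd.DataFrame(cells)
    n = len(df)
    coloc_df = df[df["colocalizes"]]

    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else math.nan

    both = df[df["end_before_pcna"].notna()]
    return RasterSummary(
        n_cells=n,
        pct_cells_with_rad52=100.0 * df["has_rad52"].mean(),
        mean_rad52_timepoints=float(df["n_rad52"].mean()),
        sem_rad52_timepoints=_sem(df["n_rad52"]),
        pct_cells_colocalizing=100.0 * df["colocalizes"].mean(),
        mean_coloc_timepoints_all_cells=float(df["n_coloc"].mean()),
        mean_coloc_timepoints_coloc_cells=(
            float(coloc_df["n_coloc"].mean()) if len(coloc_df) else 0.0
        ),
        sem_coloc_timepoints_coloc_cells=(
            _sem(coloc_df["n_coloc"]) if len(coloc_df) else math.nan
        ),
        mean_longest_run_timepoints=(
            float(coloc_df["longest_run"].mean()) if len(coloc_df) else 0.0
        ),
        pct_end_before_pcna_loss=(
            100.0 * both["end_before_pcna"].mean() if len(both) else math.nan
        ),
        n_cells_with_gaps=int((df["gap_tp"] > 0).sum()),
        pct_cells_with_gaps=100.0 * float((df["gap_tp"] > 0).mean()),
        max_gap_min=float(df["gap_tp"].max() * frame_interval_min),
    )


def duration_bounds(n_timepoints: float, interval_min: float) -> tuple[float, float]:
    """Duration interval implied by n consecutive detections at a fixed
    acquisition interval: at least (n-1) and less than n intervals.

    E.g. a mean of 3.4 timepoints at 5 min brackets the duration to
    [12, 17) min.
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    if interval_min <= 0:
        raise ValueError("interval_min must be > 0")
    return ((n_timepoints - 1) * interval_min, n_timepoints * interval_min)
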