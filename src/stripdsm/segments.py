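"""Transect segmentation: from flight paths and sighting records to the
per-segment count table that the abundance model consumes.

A strip transect of bandwidth ``b`` (1400 m in the motivating surveys) is
cut into consecutive arc-length slices of length ``b``, so each full
segment covers an approximately square strip of b x b = 1.96 km^2. Each
georeferenced photo record (a group of animals with its size) is assigned
to the segment whose strip contains it; segment covariates (mean
elevation, distance to coast, forest fraction) are summarized over the
strip footprint, and segments at >= 95 % forest cover are flagged
excluded from modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import substring

__all__ = [
    "Segment", "segmentize_transect", "assign_records",
    "summarize_covariates", "collinearity_screen", "segment_table",
    "build_segment_table", "survey_effort_summary",
]

FOREST_EXCLUSION = 0.95


@dataclass
class Segment:
    """One strip-transect sampling unit."""

    id: str
    transect: int
    order: int
    centerline: LineString
    length: float            # m
    bandwidth: float         # m
    season: str = ""
    count: float = 0.0
    mean_elevation: float = np.nan
    distance_to_coast: float = np.nan
    forest_fraction: float = np.nan
    excluded: bool = False

    @property
    def area(self) -> float:
        """Effort area in km^2 (length x bandwidth)."""
        return self.length * self.bandwidth / 1e6

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.centerline.interpolate(0.5, normalized=True)
        return (c.x, c.y)

    @property
    def strip(self) -> Polygon:
        """Strip footprint: the centerline buffered by bandwidth/2, flat caps."""
        return self.centerline.buffer(self.bandwidth / 2.0, cap_style="flat")


def segmentize_transect(path: LineString | np.ndarray, bandwidth: float,
                        min_fraction: float = 0.5, transect: int = 0,
                        season: str = "") -> list[Segment]:
    """Cut a flight path into consecutive segments of arc length = bandwidth.

    A terminal remainder shorter than ``min_fraction * bandwidth`` is
    dropped; otherwise it is kept with its true (smaller) length, hence a
    proportionally smaller effort area. Order indices are contiguous from 0.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if not (0.0 <= min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in [0, 1]")
    if not isinstance(path, LineString):
        arr = np.asarray(path, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("degenerate path: need at least two vertices")
        path = LineString(arr)
    if len(path.coords) < 2 or path.length == 0:
        raise ValueError("degenerate path: need at least two distinct vertices")

    L = path.length
    n_full = int(np.floor(L / bandwidth + 1e-9))
    remainder = L - n_full * bandwidth
    if remainder < 1e-6:
        remainder = 0.0
    cuts = [i * bandwidth for i in range(n_full + 1)]
    keep_remainder = remainder > 0 and remainder >= min_fraction * bandwidth
    if keep_remainder:
        cuts.append(L)
    segments = []
    for i in range(len(cuts) - 1):
        sub = substring(path, cuts[i], cuts[i + 1])
        segments.append(Segment(
            id=f"t{transect}-s{i}", transect=transect, order=i,
            centerline=sub, length=cuts[i + 1] - cuts[i],
            bandwidth=bandwidth, season=season))
    return segments


def assign_records(segments: list[Segment], records: pd.DataFrame,
                   bandwidth: float | None = None):
    """Assign each sighting record to the segment whose strip contains it.

    Records carry columns ``x``, ``y``, ``group_size``. A record is matched
    by (1) finding the transect whose centerline is nearest in perpendicular
    distance, requiring that distance <= bandwidth/2, then (2) locating the
    along-track arc position and picking the segment covering it; a record
    exactly on the boundary between consecutive segments goes to the lower
    order index. Records outside every strip are returned unassigned.

    Returns ``(segments, unassigned)`` where ``unassigned`` is the subset
    of ``records``; segment counts are incremented in place by group size.
    Conservation: sum of counts + sum of unassigned sizes = sum of record
    sizes.
    """
    if len(records) and (records["group_size"] < 1).any():
        bad = records.loc[records["group_size"] < 1]
        raise ValueError(f"records with group size < 1: {bad.index.tolist()}")
    if bandwidth is None:
        bandwidth = segments[0].bandwidth if segments else 0.0

    # reconstruct per-transect paths and cumulative segment spans
    by_transect: dict[int, list[Segment]] = {}
    for s in segments:
        by_transect.setdefault(s.transect, []).append(s)
    paths = {}
    for t, segs in by_transect.items():
        segs.sort(key=lambda s: s.order)
        coords = list(segs[0].centerline.coords)
        for s in segs[1:]:
            coords.extend(list(s.centerline.coords)[1:])
        paths[t] = LineString(coords)

    unassigned_idx = []
    for idx, rec in records.iterrows():
        pt = Point(rec["x"], rec["y"])
        best_t, best_d = None, np.inf
        for t, path in paths.items():
            d = path.distance(pt)
            if d < best_d:
                best_t, best_d = t, d
        if best_t is None or best_d > bandwidth / 2.0 + 1e-9:
            unassigned_idx.append(idx)
            continue
        segs = by_transect[best_t]
        s_arc = paths[best_t].project(pt)
        # boundary at an exact multiple of the slice length -> lower index
        cum = 0.0
        chosen = None
        for s in segs:
            if s_arc <= cum + s.length + 1e-9:
                chosen = s
                break
            cum += s.length
        if chosen is None:  # beyond a dropped terminal remainder
            unassigned_idx.append(idx)
            continue
        chosen.count += float(rec["group_size"])
    return segments, records.loc[unassigned_idx]


def summarize_covariates(segment_or_cell, landscape) -> None:
    """Area-weighted covariate summary of a strip (or grid cell) footprint.

    Sets ``mean_elevation``, ``forest_fraction`` (area-weighted means of
    the landscape rasters over the footprint), ``distance_to_coast``
    (Euclidean, from the centroid) and the >= 95 % forest ``excluded``
    flag, in place. Raises ``ValueError`` when the footprint lies fully
    outside the landscape extent.
    """
    poly = segment_or_cell.strip
    w, elev, forest = landscape.weighted_values(poly)
    if w == 0:
        raise ValueError(
            f"footprint of {segment_or_cell.id} lies outside the landscape extent")
    segment_or_cell.mean_elevation = elev
    segment_or_cell.forest_fraction = forest
    cx, cy = segment_or_cell.centroid
    segment_or_cell.distance_to_coast = landscape.distance_to_coast(
        np.array([[cx, cy]]))[0]
    segment_or_cell.excluded = bool(forest >= FOREST_EXCLUSION)


def collinearity_screen(x: np.ndarray, y: np.ndarray,
                        threshold: float = 0.4) -> tuple[float, bool]:
    """Pearson correlation between two candidate covariates and the
    separate-models decision: |r| >= threshold means the covariates are too
    collinear to enter one model together."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, bool(abs(r) >= threshold)


def segment_table(segments: list[Segment]) -> pd.DataFrame:
    """Flatten segments into the tabular form used by the model fitters."""
    rows = []
    for s in segments:
        cx, cy = s.centroid
        rows.append({
            "id": s.id, "transect": s.transect, "order": s.order,
            "x": cx, "y": cy, "length": s.length, "area": s.area,
            "season": s.season, "count": s.count,
            "elevation": s.mean_elevation, "dist_coast": s.distance_to_coast,
            "forest": s.forest_fraction, "excluded": s.excluded,
        })
    return pd.DataFrame(rows)


def build_segment_table(paths, records: pd.DataFrame, landscape,
                        bandwidth: float = 1400.0, min_fraction: float = 0.5,
                        season: str = "") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full segmentation stage: slice every path, assign records, summarize
    covariates. Returns (segment table, unassigned records)."""
    segments: list[Segment] = []
    for t, path in enumerate(paths):
        segments.extend(segmentize_transect(
            path, bandwidth, min_fraction, transect=t, season=season))
    segments, unassigned = assign_records(segments, records, bandwidth)
    for s in segments:
        summarize_covariates(s, landscape)
    return segment_table(segments), unassigned


def survey_effort_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-survey (and per-season) accounting of effort, photographic
    records and individuals, from a record table with columns ``survey``,
    ``season``, ``group_size`` and optionally ``effort_km``.

    Returns one row per survey plus season subtotals and a grand total row
    (survey = "total"), counting one photographic record per table row and
    summing group sizes into individuals.
    """
    req = {"survey", "season", "group_size"}
    if not req.issubset(records.columns):
        raise ValueError(f"record table needs columns {sorted(req)}")
    per = records.groupby(["season", "survey"], sort=True).agg(
        photo_records=("group_size", "size"),
        individuals=("group_size", "sum")).reset_index()
    if "effort_km" in records.columns:
        eff = records.groupby(["season", "survey"])["effort_km"].first()
        per["effort_km"] = eff.values
    season = per.groupby("season", sort=True).agg(
        photo_records=("photo_records", "sum"),
        individuals=("individuals", "sum")).reset_index()
    season["survey"] = "subtotal"
    total = pd.DataFrame([{
        "season": "all", "survey": "total",
        "photo_records": per["photo_records"].sum(),
        "individuals": per["individuals"].sum(),
    }])
    return pd.concat([per, season, total], ignore_index=True)
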