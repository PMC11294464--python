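"""Longitudinal fiber tracking and dissolution-event analysis.

Fibers observed at consecutive time points are matched by minimizing a
combined color + spatial cost with an optimal one-to-one assignment; pairs
above a cost gate dissolve into unmatched sets, which become eliminations
(unmatched on the earlier side) and births (unmatched on the later side).
Tracks stitched across all intervals feed dissolution-event detection: each
eliminated fiber's footprint, dilated by a small radius, collects the
newborn fibers of the following window as its replacements. Downstream
summaries give the replacement-count distribution, medial-edge spatial bias,
and cohort elimination fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .barcode import BarcodeConfig, delta_e, rgb_to_lab

__all__ = [
    "TrackerConfig",
    "Track",
    "TrackTable",
    "DissolutionEvent",
    "match_fibers",
    "classify_fates",
    "detect_dissolution_events",
    "categorize_events",
    "compartment_bias",
    "elimination_fraction",
]

REPLACEMENT_CATEGORIES = ("0", "1", "2", "3", "4", ">=5")


@dataclass
class TrackerConfig:
    """Matching weights, cost gate and event-window geometry.

    ``w_color`` and ``w_space`` weight the normalized color and spatial cost
    terms and must sum to 1. ``d_max`` (µm) normalizes centroid displacement;
    ``max_cost`` gates implausible matches into birth/death. Dissolution
    events collect newborns within ``event_window`` observation intervals
    whose centroids fall inside the parent footprint dilated by
    ``event_radius`` µm.
    """

    w_color: float = 0.5
    w_space: float = 0.5
    max_cost: float = 0.6
    d_max: float = 30.0
    event_radius: float = 5.0
    event_window: int = 1

    def __post_init__(self) -> None:
        if self.w_color < 0 or self.w_space < 0 \
                or abs(self.w_color + self.w_space - 1.0) > 1e-9:
            raise ValueError("w_color and w_space must be nonnegative and "
                             "sum to 1")
        if not (0.0 <= self.max_cost <= 1.0):
            raise ValueError("max_cost must be in [0, 1]")
        if self.d_max <= 0 or self.event_radius < 0 or self.event_window < 1:
            raise ValueError("invalid geometry parameters")


@dataclass
class Track:
    """One fiber identity over time: (time, fiber_id) points and fates."""

    track_id: int
    points: list[tuple[float, int]] = field(default_factory=list)
    fate: str = "persist"        # 'persist' | 'eliminated'
    newborn: bool = False
    eliminated_at: float | None = None

    @property
    def start(self) -> float:
        return self.points[0][0]

    @property
    def end(self) -> float:
        return self.points[-1][0]

    def fiber_at(self, t: float) -> int | None:
        for tt, fid in self.points:
            if tt == t:
                return fid
        return None


@dataclass
class TrackTable:
    """All tracks of one animal plus the observation time grid."""

    tracks: list[Track]
    times: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            for t, fid in tr.points:
                rows.append({"track_id": tr.track_id, "time": t,
                             "fiber_id": fid, "fate": tr.fate,
                             "newborn": tr.newborn,
                             "eliminated_at": tr.eliminated_at})
        return pd.DataFrame(rows, columns=["track_id", "time", "fiber_id",
                                           "fate", "newborn",
                                           "eliminated_at"])


@dataclass
class DissolutionEvent:
    """One eliminated fiber and the newborn fibers filling its footprint."""

    parent_track_id: int
    time: float
    replacement_ids: tuple[int, ...]
    compartment: str
    medial_edge: bool

    @property
    def replacement_count(self) -> int:
        return len(self.replacement_ids)

    @property
    def category(self) -> str:
        n = self.replacement_count
        return str(n) if n < 5 else ">=5"


def _color_cost(row_a, row_b, bc: BarcodeConfig) -> float:
    lab_a = rgb_to_lab(np.clip([row_a["c1"], row_a["c2"], row_a["c3"]], 0, 1))
    lab_b = rgb_to_lab(np.clip([row_b["c1"], row_b["c2"], row_b["c3"]], 0, 1))
    return min(delta_e(lab_a, lab_b, bc.de_metric) / bc.de_saturation, 1.0)


def match_fibers(records_a: pd.DataFrame, records_b: pd.DataFrame,
                 config: TrackerConfig | None = None,
                 barcode_config: BarcodeConfig | None = None
                 ) -> tuple[dict[int, int], set[int], set[int]]:
    """Optimal one-to-one fiber matching between two time points.

    Cost(i, j) = w_color * (delta-E / saturation, clipped) +
    w_space * min(||centroid displacement|| / d_max, 1). The assignment
    minimizes total cost (Hungarian algorithm); pairs above ``max_cost`` are
    dissolved into the unmatched sets. Deterministic for fixed inputs.

    Returns (matches a->b by fiber_id, unmatched ids in a, unmatched ids in b).
    """
    config = config or TrackerConfig()
    barcode_config = barcode_config or BarcodeConfig()
    if len(records_a) == 0 or len(records_b) == 0:
        return ({}, set(records_a.get("fiber_id", pd.Series(dtype=int))),
                set(records_b.get("fiber_id", pd.Series(dtype=int))))
    a = records_a.sort_values("fiber_id").reset_index(drop=True)
    b = records_b.sort_values("fiber_id").reset_index(drop=True)
    if a["fiber_id"].duplicated().any() or b["fiber_id"].duplicated().any():
        raise ValueError("duplicate fiber ids within one frame")

    pa = a[["x", "y"]].to_numpy(float)
    pb = b[["x", "y"]].to_numpy(float)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    space = np.minimum(d / config.d_max, 1.0)
    cost = config.w_space * space
    if config.w_color > 0:
        has_color = {"c1", "c2", "c3"}.issubset(a.columns) \
            and {"c1", "c2", "c3"}.issubset(b.columns)
        if not has_color:
            raise ValueError("color columns required when w_color > 0")
        labs_a = np.array([rgb_to_lab(np.clip(v, 0, 1))
                           for v in a[["c1", "c2", "c3"]].to_numpy(float)])
        labs_b = np.array([rgb_to_lab(np.clip(v, 0, 1))
                           for v in b[["c1", "c2", "c3"]].to_numpy(float)])
        de = np.sqrt(((labs_a[:, None, :] - labs_b[None, :, :]) ** 2)
                     .sum(axis=2))
        cost = cost + config.w_color * np.minimum(
            de / barcode_config.de_saturation, 1.0)

    rows, cols = linear_sum_assignment(cost)
    matches: dict[int, int] = {}
    for i, j in zip(rows, cols):
        if cost[i, j] <= config.max_cost:
            matches[int(a.loc[i, "fiber_id"])] = int(b.loc[j, "fiber_id"])
    unmatched_a = set(a["fiber_id"].astype(int)) - set(matches)
    unmatched_b = set(b["fiber_id"].astype(int)) - set(matches.values())
    return matches, unmatched_a, unmatched_b


def classify_fates(frames: dict[float, pd.DataFrame],
                   config: TrackerConfig | None = None,
                   barcode_config: BarcodeConfig | None = None) -> TrackTable:
    """Stitch per-interval assignments into tracks with fate labels.

    Fibers unmatched on the earlier side of an interval are eliminated at the
    later time; fibers unmatched on the later side open newborn tracks.
    Every observed fiber belongs to exactly one track.
    """
    times = tuple(sorted(frames))
    if not times:
        return TrackTable(tracks=[], times=())
    for t in times:
        if frames[t]["fiber_id"].duplicated().any():
            raise ValueError(f"duplicate fiber ids at time {t}")

    tracks: list[Track] = []
    open_by_fiber: dict[int, Track] = {}
    next_tid = 0
    for fid in sorted(frames[times[0]]["fiber_id"].astype(int)):
        tr = Track(track_id=next_tid, points=[(times[0], fid)])
        next_tid += 1
        tracks.append(tr)
        open_by_fiber[fid] = tr

    for t_prev, t_next in zip(times, times[1:]):
        matches, lost, born = match_fibers(frames[t_prev], frames[t_next],
                                           config, barcode_config)
        new_open: dict[int, Track] = {}
        for fa, fb in matches.items():
            tr = open_by_fiber[fa]
            tr.points.append((t_next, fb))
            new_open[fb] = tr
        for fa in sorted(lost):
            tr = open_by_fiber[fa]
            tr.fate = "eliminated"
            tr.eliminated_at = t_next
        for fb in sorted(born):
            tr = Track(track_id=next_tid, points=[(t_next, fb)],
                       newborn=True)
            next_tid += 1
            tracks.append(tr)
            new_open[fb] = tr
        open_by_fiber = new_open
    return TrackTable(tracks=tracks, times=times)


def detect_dissolution_events(table: TrackTable,
                              frames: dict[float, pd.DataFrame],
                              footprints: dict[int, tuple[float, float, float]],
                              config: TrackerConfig | None = None
                              ) -> list[DissolutionEvent]:
    """Pair each elimination with the newborn fibers inside its footprint.

    ``footprints`` maps fiber_id -> (cx, cy, radius) in µm, the circular
    cross-section footprint of the fiber at its last observation. A newborn
    fiber within ``event_window`` intervals of the elimination whose centroid
    lies inside the footprint dilated by ``event_radius`` is a replacement.
    A birth inside several dilated footprints goes to the parent with the
    nearest centroid (ties to the lower parent track id), so replacement sets
    are disjoint. Eliminations without a stored footprint are skipped with a
    warning.
    """
    import warnings
    config = config or TrackerConfig()
    times = table.times
    t_index = {t: i for i, t in enumerate(times)}

    eliminated = [tr for tr in table.tracks if tr.fate == "eliminated"]
    newborn = [tr for tr in table.tracks if tr.newborn]

    # candidate (parent, birth) pairs
    parents: list[tuple[Track, tuple[float, float, float]]] = []
    for tr in eliminated:
        last_fid = tr.points[-1][1]
        fp = footprints.get(last_fid)
        if fp is None:
            warnings.warn(f"missing footprint for fiber {last_fid}; "
                          "event skipped")
            continue
        parents.append((tr, fp))

    claims: dict[int, tuple[float, int]] = {}  # birth track -> (dist, parent)
    for tr, (cx, cy, r) in parents:
        t_dead = tr.eliminated_at
        for nb in newborn:
            if t_index[nb.start] - t_index[t_dead] > config.event_window - 1 \
                    or nb.start < t_dead:
                continue
            row = frames[nb.start]
            rec = row[row["fiber_id"] == nb.points[0][1]]
            if rec.empty:
                continue
            bx, by = float(rec.iloc[0]["x"]), float(rec.iloc[0]["y"])
            dist = math.hypot(bx - cx, by - cy)
            if dist <= r + config.event_radius:
                prev = claims.get(nb.track_id)
                if prev is None or (dist, tr.track_id) < prev:
                    claims[nb.track_id] = (dist, tr.track_id)

    by_parent: dict[int, list[int]] = {tr.track_id: [] for tr, _ in parents}
    for nb_tid, (_, parent_tid) in sorted(claims.items()):
        by_parent[parent_tid].append(nb_tid)

    events = []
    for tr, (cx, cy, r) in parents:
        last_t, last_fid = tr.points[-1]
        row = frames[last_t]
        rec = row[row["fiber_id"] == last_fid].iloc[0]
        events.append(DissolutionEvent(
            parent_track_id=tr.track_id,
            time=tr.eliminated_at,
            replacement_ids=tuple(sorted(by_parent[tr.track_id])),
            compartment=str(rec["compartment"]),
            medial_edge=bool(rec["medial_edge"])))
    return events


def categorize_events(events: list[DissolutionEvent]
                      ) -> tuple[dict[str, float], float]:
    """Replacement-count distribution (percent) and the >=1-birth fraction."""
    if not events:
        raise ValueError("at least one event is required")
    counts = {c: 0 for c in REPLACEMENT_CATEGORIES}
    for e in events:
        counts[e.category] += 1
    n = len(events)
    dist = {c: 100.0 * counts[c] / n for c in REPLACEMENT_CATEGORIES}
    frac_ge1 = 100.0 - dist["0"]
    return dist, frac_ge1


def compartment_bias(events: list[DissolutionEvent]) -> dict[str, float]:
    """Medial-edge event fraction per compartment (percent)."""
    out = {}
    for comp in ("dorsal", "ventral"):
        sub = [e for e in events if e.compartment == comp]
        if sub:
            out[comp] = 100.0 * sum(e.medial_edge for e in sub) / len(sub)
    return out


def elimination_fraction(table: TrackTable, cohort_time: float,
                         time: float,
                         cohort_ids: set[int] | None = None) -> float:
    """Percent of the cohort eliminated by ``time``.

    The cohort is the set of tracks existing at ``cohort_time`` (optionally
    restricted to the fiber ids in ``cohort_ids``, e.g. the tagged subset).
    Monotone non-decreasing in ``time`` for a fixed cohort.
    """
    cohort = [tr for tr in table.tracks
              if tr.start <= cohort_time
              and (tr.fate != "eliminated" or tr.eliminated_at > cohort_time)]
    if cohort_ids is not None:
        cohort = [tr for tr in cohort
                  if tr.fiber_at(cohort_time) in cohort_ids]
    if not cohort:
        raise ValueError("empty cohort")
    gone = sum(1 for tr in cohort
               if tr.fate == "eliminated" and tr.eliminated_at <= time)
    return 100.0 * gone / len(cohort)
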