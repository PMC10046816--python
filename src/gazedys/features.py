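"""Trigger-based gaze-complexity features.

Two features quantify the spatial complexity of the gaze trajectory during
reading, without any parsing into fixations and saccades.  Both scan the
cleaned point sequence with a sliding window of four consecutive points
(stride 1) and treat a detected pattern as a *trigger*:

* SI feature — the trigger fires when the polyline through the four points
  self-intersects, i.e. its first segment (p1, p2) crosses its third
  (p3, p4).  (Adjacent segments always share an endpoint, so only the
  non-adjacent pair is informative.)
* VAS feature — the trigger fires when the four points contain exactly two
  changes of vertical (y) movement direction, the maximum possible over
  three deltas.

Each trigger opens a 250 ms scoring window — roughly one average fixation —
starting at the quadruple's 4th point.  The vertical alteration score (VAS)
of the window, the number of direction changes of y within it, is added to
the trial's running total.  The total starts at 0 and can only grow, and
every trigger event keeps its anchor point, so the locations in the text
where the score accrued (points of reading struggle) remain traceable.

Zero vertical deltas inherit the last known direction: a momentarily
stationary gaze neither manufactures nor erases a direction change.  The
direction reached at the end of a triggering quadruple is carried into its
scoring window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import CleanTrial, downsample, reading_time

#: Scoring-window length after each trigger, ms (≈ one average fixation).
WINDOW_MS: float = 250.0

#: Slack for time-window membership, ms.  Timestamps are floats (a 60 Hz
#: step of 1000/60 ms is not exactly representable), so membership of the
#: sample exactly 250 ms after the trigger must not hinge on the last ulp.
_T_TOL: float = 1e-6

KINDS = ("SI", "VAS")


@dataclass(frozen=True)
class TriggerEvent:
    """A detected SI or VAS pattern and the score accrued in its window.

    ``index`` is the position of the 4th point of the triggering quadruple;
    ``anchor`` is that point's (x, y), which localizes the struggle.
    """

    kind: str
    index: int
    t: float
    anchor: Tuple[float, float]
    contribution: int


@dataclass
class FeatureResult:
    """A trial's total feature value with its full event decomposition.

    Invariant (asserted on construction): ``total`` equals the sum of the
    event contributions, and events are ordered by index.
    """

    trial_id: str
    subject_id: str
    group: str
    cc: str
    rate_hz: float
    kind: str
    window_ms: float
    total: int
    events: Tuple[TriggerEvent, ...]

    def __post_init__(self) -> None:
        self.events = tuple(self.events)
        if self.total != sum(e.contribution for e in self.events):
            raise ValueError("total must equal the sum of event contributions")
        if any(b.index <= a.index for a, b in zip(self.events, self.events[1:])):
            raise ValueError("events must be strictly ordered by index")

    def events_frame(self) -> pd.DataFrame:
        """Events as a tidy table (columns of the event-export CSV)."""
        return pd.DataFrame(
            [(self.trial_id, e.kind, e.index, e.t, e.anchor[0], e.anchor[1], e.contribution)
             for e in self.events],
            columns=["trial_id", "kind", "index", "t_ms", "x", "y", "contribution"],
        )


def _orient(ax, ay, bx, by, cx, cy):
    """Twice the signed area of triangle (a, b, c); sign gives orientation."""
    return (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)


def _on_bbox(ax, ay, bx, by, cx, cy):
    """Whether c lies inside the bounding box of segment (a, b)."""
    return (
        (np.minimum(ax, bx) <= cx) & (cx <= np.maximum(ax, bx))
        & (np.minimum(ay, by) <= cy) & (cy <= np.maximum(ay, by))
    )


def _segments_intersect_arrays(x1, y1, x2, y2, x3, y3, x4, y4):
    """Vectorized closed-segment intersection test for (p1,p2) vs (p3,p4)."""
    o1 = _orient(x1, y1, x2, y2, x3, y3)
    o2 = _orient(x1, y1, x2, y2, x4, y4)
    o3 = _orient(x3, y3, x4, y4, x1, y1)
    o4 = _orient(x3, y3, x4, y4, x2, y2)
    proper = (((o1 > 0) & (o2 < 0)) | ((o1 < 0) & (o2 > 0))) & (
        ((o3 > 0) & (o4 < 0)) | ((o3 < 0) & (o4 > 0))
    )
    touch = (
        ((o1 == 0) & _on_bbox(x1, y1, x2, y2, x3, y3))
        | ((o2 == 0) & _on_bbox(x1, y1, x2, y2, x4, y4))
        | ((o3 == 0) & _on_bbox(x3, y3, x4, y4, x1, y1))
        | ((o4 == 0) & _on_bbox(x3, y3, x4, y4, x2, y2))
    )
    return proper | touch


def segments_intersect(p1, p2, p3, p4) -> bool:
    """Whether closed segment (p1, p2) intersects closed segment (p3, p4).

    Touching configurations — a shared point, an endpoint on the other
    segment, collinear overlap — count as intersection, and a zero-length
    segment behaves as a point.  Non-finite coordinates are rejected.
    """
    pts = np.asarray([p1, p2, p3, p4], dtype=float)
    if pts.shape != (4, 2) or not np.isfinite(pts).all():
        raise ValueError("expected four finite planar points")
    (x1, y1), (x2, y2), (x3, y3), (x4, y4) = pts
    return bool(_segments_intersect_arrays(x1, y1, x2, y2, x3, y3, x4, y4))


def y_direction_changes(y: Sequence[float], carry_in: int = 0) -> Tuple[int, int]:
    """Count changes of vertical movement direction along ``y``.

    Successive deltas are reduced to effective directions: the sign of the
    delta, with a zero delta inheriting the last known direction (from
    ``carry_in``, encoded as +1 / -1 / 0 = none, or from earlier deltas).
    The count is the number of strict sign flips of the effective direction;
    the direction in force at the end is returned so it can be carried into
    a following window.
    """
    if carry_in not in (-1, 0, 1):
        raise ValueError("carry_in must be -1, 0 or +1")
    y = np.asarray(y, dtype=float)
    count = 0
    cur = carry_in
    if y.size >= 2:
        for d in np.sign(np.diff(y)).astype(int):
            if d != 0:
                if cur != 0 and d != cur:
                    count += 1
                cur = d
    return count, cur


def _quad_vas_counts(y: np.ndarray) -> np.ndarray:
    """Direction-change count (carry none) for every length-4 window of y."""
    s = np.sign(np.diff(y)).astype(np.int8)
    d1, d2, d3 = s[:-2], s[1:-1], s[2:]
    e1 = d1
    e2 = np.where(d2 != 0, d2, e1)
    e3 = np.where(d3 != 0, d3, e2)
    return (e1 * e2 == -1).astype(np.int8) + (e2 * e3 == -1).astype(np.int8)


def detect_si_triggers(clean: CleanTrial) -> np.ndarray:
    """Indices i (of the quadruple's 4th point) where (p[i-3..i]) self-intersects."""
    if clean.n_points < 4:
        return np.empty(0, dtype=int)
    x, y = clean.x, clean.y
    hit = _segments_intersect_arrays(
        x[:-3], y[:-3], x[1:-2], y[1:-2], x[2:-1], y[2:-1], x[3:], y[3:]
    )
    return np.nonzero(hit)[0] + 3


def detect_vas_triggers(clean: CleanTrial) -> np.ndarray:
    """Indices i where the quadruple (p[i-3..i]) shows two y-direction changes."""
    if clean.n_points < 4:
        return np.empty(0, dtype=int)
    return np.nonzero(_quad_vas_counts(clean.y) == 2)[0] + 3


def score_window(clean: CleanTrial, trigger_index: int, window_ms: float = WINDOW_MS) -> int:
    """VAS accrued in the window following a trigger.

    The window point set is the trigger's 4th point plus every point with
    t in (t_trigger, t_trigger + window_ms]; the effective direction at the
    end of the triggering quadruple is carried in.  A window truncated by
    the trial end simply scores its available points.
    """
    i = int(trigger_index)
    if not 3 <= i < clean.n_points:
        raise ValueError(f"trigger index {i} out of range")
    _, carry = y_direction_changes(clean.y[i - 3 : i + 1], 0)
    end = int(np.searchsorted(clean.t, clean.t[i] + window_ms + _T_TOL, side="right"))
    count, _ = y_direction_changes(clean.y[i:end], carry)
    return count


def extract_feature(
    clean: CleanTrial,
    kind: str,
    window_ms: float = WINDOW_MS,
    suppress_overlap: bool = False,
) -> FeatureResult:
    """Run one trigger detector over a trial and accumulate window scores.

    The total starts at 0; every trigger's window contribution is added.
    With ``suppress_overlap`` a trigger whose 4th point falls inside an
    already-open window is skipped (both readings of overlapping windows
    are supported; counting every trigger is the default).
    """
    kind = kind.upper()
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    detect = detect_si_triggers if kind == "SI" else detect_vas_triggers
    events = []
    open_until = -np.inf
    for i in detect(clean):
        t_i = float(clean.t[i])
        if suppress_overlap and t_i <= open_until + _T_TOL:
            continue
        contribution = score_window(clean, i, window_ms)
        events.append(TriggerEvent(
            kind=kind,
            index=int(i),
            t=t_i,
            anchor=(float(clean.x[i]), float(clean.y[i])),
            contribution=contribution,
        ))
        open_until = t_i + window_ms
    return FeatureResult(
        trial_id=clean.trial_id,
        subject_id=clean.subject_id,
        group=clean.group,
        cc=clean.cc,
        rate_hz=clean.rate_hz,
        kind=kind,
        window_ms=window_ms,
        total=sum(e.contribution for e in events),
        events=tuple(events),
    )


def extract_cohort_features(
    cleaned: Iterable[CleanTrial],
    window_ms: float = WINDOW_MS,
    suppress_overlap: bool = False,
    downsample_factor: int = 2,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Build the cohort feature table and event table for cleaned trials.

    For each trial, both features are extracted at the native rate and after
    decimation by ``downsample_factor`` (60 -> 30 Hz by default), and the
    total reading time is added as the baseline feature.  Returns
    ``(records, events)`` tidy DataFrames matching the exchange CSV formats.
    """
    records = []
    event_frames = []
    for tr in cleaned:
        low = downsample(tr, downsample_factor)
        for kind in KINDS:
            for variant in (tr, low):
                res = extract_feature(variant, kind, window_ms, suppress_overlap)
                name = f"{kind.lower()}_{int(round(variant.rate_hz))}"
                records.append((tr.subject_id, tr.group, tr.cc, name, float(res.total)))
                if res.events:
                    ev = res.events_frame()
                    ev["kind"] = f"{kind}_{int(round(variant.rate_hz))}"
                    event_frames.append(ev)
        records.append((tr.subject_id, tr.group, tr.cc, "reading_time", reading_time(tr)))
    records_df = pd.DataFrame(
        records, columns=["subject_id", "group", "cc", "feature_name", "value"]
    )
    events_df = (
        pd.concat(event_frames, ignore_index=True)
        if event_frames
        else pd.DataFrame(columns=["trial_id", "kind", "index", "t_ms", "x", "y", "contribution"])
    )
    return records_df, events_df


__all__ = [
    "WINDOW_MS", "KINDS", "TriggerEvent", "FeatureResult",
    "segments_intersect", "y_direction_changes",
    "detect_si_triggers", "detect_vas_triggers",
    "score_window", "extract_feature", "extract_cohort_features",
]
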