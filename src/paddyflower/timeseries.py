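"""Diurnal and daily flowering dynamics from per-image detections.

Detections are assembled into a strictly time-ordered series of
(timestamp, FBN, FCBN) entries, optionally joined with manually counted
flowering panicle numbers (FPN) on exact timestamps. Missing acquisitions
stay missing — entries are never imputed. Daily peaks are located on the
raw series (no smoothing), and automated counts are validated against the
manual ones by Pearson correlation over pairwise-complete entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime

import numpy as np
import pandas as pd
from scipy import stats

from .detection import DetectionResult
from .image_io import CountAnnotation

__all__ = [
    "SeriesEntry",
    "FloweringSeries",
    "NO_FLOWERING",
    "build_series",
    "daily_peak",
    "pearson_r",
]


class _NoFlowering:
    """Sentinel for a day on which the chosen metric is zero throughout."""

    def __repr__(self) -> str:  # pragma: no cover
        return "NO_FLOWERING"


#: Returned by :func:`daily_peak` for an all-zero day.
NO_FLOWERING = _NoFlowering()


@dataclass(frozen=True)
class SeriesEntry:
    timestamp: datetime
    fbn: int
    fcbn: int
    fpn: int | None = None


@dataclass
class FloweringSeries:
    """Time-ordered flowering counts with a per-date index."""

    entries: list[SeriesEntry]
    day_index: dict[date, list[SeriesEntry]] = field(default_factory=dict)
    unmatched_annotations: list[CountAnnotation] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": [e.timestamp for e in self.entries],
                "fbn": [e.fbn for e in self.entries],
                "fcbn": [e.fcbn for e in self.entries],
                "fpn": [e.fpn for e in self.entries],
            }
        )


def build_series(
    detections: list[tuple[datetime, DetectionResult]],
    annotations: list[CountAnnotation] | None = None,
) -> FloweringSeries:
    """Sort detections by timestamp and join FPN annotations exactly.

    Raises on duplicate timestamps; annotations with no exactly matching
    detection timestamp are kept in ``unmatched_annotations`` (the join log).
    """
    for ts, _ in detections:
        if ts is None:
            raise ValueError("every detection must carry a timestamp")
    ordered = sorted(detections, key=lambda pair: pair[0])
    stamps = [ts for ts, _ in ordered]
    dupes = sorted({t for t in stamps if stamps.count(t) > 1})
    if dupes:
        raise ValueError(f"duplicate detection timestamps: {dupes}")
    fpn_by_ts = {a.timestamp: a.fpn for a in (annotations or [])}
    entries = [
        SeriesEntry(timestamp=ts, fbn=res.fbn, fcbn=res.fcbn, fpn=fpn_by_ts.get(ts))
        for ts, res in ordered
    ]
    matched = {e.timestamp for e in entries if e.fpn is not None}
    unmatched = [a for a in (annotations or []) if a.timestamp not in matched]
    day_index: dict[date, list[SeriesEntry]] = {}
    for e in entries:
        day_index.setdefault(e.timestamp.date(), []).append(e)
    return FloweringSeries(entries=entries, day_index=day_index,
                           unmatched_annotations=unmatched)


def daily_peak(series: FloweringSeries, day: date, metric: str = "fcbn"):
    """Timestamp of the day's maximum of ``metric`` ('fbn' or 'fcbn').

    Ties resolve to the earliest timestamp. A day whose metric is zero
    throughout returns the :data:`NO_FLOWERING` sentinel; a day with no
    entries raises.
    """
    if metric not in ("fbn", "fcbn"):
        raise ValueError(f"metric must be 'fbn' or 'fcbn', got {metric!r}")
    entries = series.day_index.get(day)
    if not entries:
        raise KeyError(f"no entries for date {day}")
    values = [getattr(e, metric) for e in entries]
    if max(values) == 0:
        return NO_FLOWERING
    # entries are time-sorted, so argmax lands on the earliest tie
    return entries[int(np.argmax(values))].timestamp


def pearson_r(x, y) -> float:
    """Sample Pearson correlation over pairwise-complete entries.

    Pairs where either value is missing (None/NaN) are dropped; at least 3
    complete pairs are required and neither sequence may be constant.
    """
    xa = np.asarray([np.nan if v is None else float(v) for v in x])
    ya = np.asarray([np.nan if v is None else float(v) for v in y])
    if xa.shape != ya.shape:
        raise ValueError(f"sequence lengths differ: {xa.shape[0]} vs {ya.shape[0]}")
    ok = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[ok], ya[ok]
    if xa.size < 3:
        raise ValueError(f"need >= 3 pairwise-complete pairs, got {xa.size}")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("correlation undefined for a constant sequence")
    return float(stats.pearsonr(xa, ya).statistic)
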