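"""Case/control segmentation and analysis-window framing.

An elevated-ICP event (case) is a run of at least 10 consecutive minutes
with ICP >= 20 cm H2O; events are independent only if their onsets are at
least 5 h apart.  Each kept event anchors a 4-h case record spanning the
240 minutes before onset, provided that span does not intersect any other
qualifying run or the 60-min washout after a run resolves.  Control periods
are 6-h stretches in which ICP stays below 20 cm H2O throughout; their
final 240 minutes form the control analysis record, anchored at the period
end so case and control records are structurally identical.

Every 240-min analysis record is tiled by 8 non-overlapping, consecutive
30-min analysis windows.  Window *w* ends ``30*(w-1)`` minutes before the
anchor, i.e. window 1 is the half hour immediately before the anchor
(0-min prediction horizon) and window 2 the 30-60 min window (30-min
horizon).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import CHANNELS, VitalsRecord

ICP_THRESHOLD = 20.0
EVENT_DURATION = 10
INDEPENDENCE_GAP = 300
CONTROL_DURATION = 360
WASHOUT = 60
RECORD_LEN = 240
WINDOW_LEN = 30
N_WINDOWS = 8


@dataclass
class CaseEvent:
    onset: int          # first minute of the qualifying run
    run_end: int        # first minute after the run (resolution)


@dataclass
class ControlPeriod:
    start: int
    end: int            # exclusive; anchor = end

    @property
    def anchor(self) -> int:
        return self.end

    @property
    def analysis_span(self) -> tuple[int, int]:
        return (self.end - RECORD_LEN, self.end)


@dataclass
class AnalysisWindow:
    index: int          # 1..8

    @property
    def horizon(self) -> int:
        """Prediction horizon in minutes (time from window end to anchor)."""
        return WINDOW_LEN * (self.index - 1)

    def span(self, anchor: int) -> tuple[int, int]:
        return (anchor - self.horizon - WINDOW_LEN, anchor - self.horizon)


@dataclass
class Segment:
    """A labeled 240-min analysis record cut from a corrected full record."""

    segment_id: str
    patient_id: str
    record_id: str
    label: str                       # "case" | "control"
    anchor: int                      # global minute of the anchor
    span: tuple[int, int]
    data: dict[str, np.ndarray] = field(repr=False, default=None)

    def window_values(self, channel: str, window: AnalysisWindow) -> np.ndarray:
        lo, hi = window.span(self.anchor)
        off = self.span[0]
        return self.data[channel][lo - off:hi - off]


@dataclass
class Rejection:
    record_id: str
    anchor: int
    reason: str


def find_event_runs(icp: np.ndarray, threshold: float = ICP_THRESHOLD,
                    duration: int = EVENT_DURATION) -> list[CaseEvent]:
    """Maximal runs of >= ``duration`` consecutive supra-threshold minutes.

    Missing (NaN) minutes break runs: an event must be observed.
    """
    above = np.asarray(icp, dtype=float) >= threshold   # NaN compares False
    events: list[CaseEvent] = []
    n = len(above)
    t = 0
    while t < n:
        if above[t]:
            s = t
            while t < n and above[t]:
                t += 1
            if t - s >= duration:
                events.append(CaseEvent(onset=s, run_end=t))
        else:
            t += 1
    return events


def find_case_events(icp: np.ndarray, threshold: float = ICP_THRESHOLD,
                     duration: int = EVENT_DURATION) -> list[int]:
    """Onsets (first minutes) of qualifying runs, in time order."""
    return [e.onset for e in find_event_runs(icp, threshold, duration)]


def enforce_independence(onsets: list[int],
                         min_gap: int = INDEPENDENCE_GAP) -> list[int]:
    """Greedy left-to-right thinning: keep an onset iff it is at least
    ``min_gap`` minutes after the last kept onset."""
    kept: list[int] = []
    for o in onsets:
        if not kept or o - kept[-1] >= min_gap:
            kept.append(o)
    return kept


def extract_case_record(record: VitalsRecord, onset: int,
                        runs: list[CaseEvent] | None = None,
                        record_len: int = RECORD_LEN,
                        washout: int = WASHOUT,
                        ) -> tuple[int, int] | Rejection:
    """Span of the 4-h case record before ``onset``, or a rejection.

    Rejected when the history is too short, or when the span intersects
    another qualifying run or the ``washout`` minutes after that run's
    resolution (ICP must stay quiet for an hour before data re-enters).
    """
    if onset < record_len:
        return Rejection(record.record_id, onset, "insufficient_history")
    lo, hi = onset - record_len, onset
    if runs is None:
        runs = find_event_runs(record.channels["ICP"])
    for r in runs:
        if r.onset == onset:
            continue
        blocked_hi = r.run_end + washout
        if lo < blocked_hi and r.onset < hi:
            return Rejection(record.record_id, onset,
                             "overlaps_event_or_washout")
    return (lo, hi)


def find_control_periods(icp: np.ndarray,
                         duration: int = CONTROL_DURATION,
                         threshold: float = ICP_THRESHOLD,
                         ) -> list[ControlPeriod]:
    """Greedy non-overlapping tiling of maximal sub-threshold stretches.

    Each stretch of consecutive minutes with ICP < threshold contributes
    ``len // duration`` control periods, tiled from the stretch start.
    Missing ICP minutes are tolerated inside a stretch (they are not
    supra-threshold; heavy missingness is excluded by QC downstream).
    """
    x = np.asarray(icp, dtype=float)
    supra = x >= threshold
    periods: list[ControlPeriod] = []
    n = len(x)
    t = 0
    while t < n:
        if supra[t]:
            t += 1
            continue
        s = t
        while t < n and not supra[t]:
            t += 1
        for k in range(s, t - duration + 1, duration):
            periods.append(ControlPeriod(start=k, end=k + duration))
    return periods


def window_segment(segment_len: int = RECORD_LEN,
                   window_len: int = WINDOW_LEN,
                   n_windows: int = N_WINDOWS) -> list[AnalysisWindow]:
    """The 8 analysis windows tiling a 240-min record (w=1 nearest anchor)."""
    if n_windows * window_len != segment_len:
        raise ValueError("windows do not tile the analysis record")
    return [AnalysisWindow(index=w) for w in range(1, n_windows + 1)]


def segment_record(record: VitalsRecord,
                   channels: tuple[str, ...] = CHANNELS,
                   record_len: int = RECORD_LEN,
                   ) -> tuple[list[Segment], list[Rejection]]:
    """Cut one corrected record into labeled case and control segments."""
    icp = record.channels["ICP"]
    runs = find_event_runs(icp)
    onsets = enforce_independence([r.onset for r in runs])
    segments: list[Segment] = []
    rejections: list[Rejection] = []

    for i, onset in enumerate(onsets):
        res = extract_case_record(record, onset, runs=runs,
                                  record_len=record_len)
        if isinstance(res, Rejection):
            rejections.append(res)
            continue
        lo, hi = res
        segments.append(Segment(
            segment_id=f"{record.record_id}_case{i}",
            patient_id=record.patient_id,
            record_id=record.record_id,
            label="case", anchor=onset, span=(lo, hi),
            data={ch: record.channels[ch][lo:hi].copy() for ch in channels},
        ))

    for i, cp in enumerate(find_control_periods(icp)):
        lo, hi = cp.analysis_span
        segments.append(Segment(
            segment_id=f"{record.record_id}_ctrl{i}",
            patient_id=record.patient_id,
            record_id=record.record_id,
            label="control", anchor=cp.anchor, span=(lo, hi),
            data={ch: record.channels[ch][lo:hi].copy() for ch in channels},
        ))
    return segments, rejections
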