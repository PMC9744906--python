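"""Two-step blood-pressure artifact detection, removal and adjudication.

The artifact pass operates on the systolic pressure stream, where line
flushes, blood draws and transducer faults are most dramatic:

1. *Wide artifact*: a 5-min block slides one minute at a time; any value
   whose deviation from the block's first (already-corrected) datapoint
   exceeds two record-SDs is flagged and immediately forward-filled, so
   block anchors stay at the pre-excursion level.  The record SD is
   computed once, on the raw series, before any correction.
2. *Narrow artifact*: any remaining minute-to-minute relative change above
   30% (against the corrected previous value) is flagged and forward-filled.

At flagged minutes all four BP-linked streams (SBP, DBP, MAP, CPP) are
corrected together; non-BP channels are never touched.  Ties exactly at the
thresholds are not flagged (strict inequality).  Deviations are two-sided:
dropouts from disconnections point downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import BP_CHANNELS, VitalsRecord

WIDE = "wide"
NARROW = "narrow"


@dataclass
class ArtifactMask:
    """Per-minute artifact flags on the BP-linked channels with step labels.

    The wide and narrow labels are disjoint: the first detector to fire
    claims the minute.
    """

    flags: np.ndarray                  # bool, one entry per minute
    labels: dict[str, np.ndarray] = field(default=None)
    record_sd: float | None = None     # the raw-record SD that defined it

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.labels is None:
            self.labels = {WIDE: np.zeros_like(self.flags),
                           NARROW: np.zeros_like(self.flags)}

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def union(self, other: "ArtifactMask") -> "ArtifactMask":
        """Combine masks; minutes already claimed keep their first label."""
        flags = self.flags | other.flags
        labels = {
            WIDE: self.labels[WIDE] | (other.labels[WIDE] & ~self.flags),
            NARROW: self.labels[NARROW] | (other.labels[NARROW] & ~self.flags),
        }
        return ArtifactMask(flags=flags, labels=labels,
                            record_sd=self.record_sd or other.record_sd)


@dataclass
class QCReport:
    record_id: str
    record_sd: float
    replaced_minutes: int
    replaced_fraction: float
    missing_fraction: dict[str, float]
    concurrent_hours: float
    verdict: str                       # pass | exclude_missing | exclude_concurrency

    def as_dict(self) -> dict:
        d = vars(self).copy()
        d["missing_fraction"] = dict(self.missing_fraction)
        return d


def record_sbp_sd(record: VitalsRecord) -> float:
    """SD of the entire raw SBP series (missing minutes excluded)."""
    x = record.channels["SBP"]
    x = x[~np.isnan(x)]
    return float(np.std(x)) if x.size else 0.0


def detect_wide(sbp: np.ndarray, record_sd: float, block_len: int = 5,
                step: int = 1, k: float = 2.0) -> tuple[ArtifactMask, np.ndarray]:
    """Sliding-block wide-artifact detector.

    Returns the mask and the corrected (forward-filled) series.  A single
    left-to-right pass: within each block anchored at its first corrected
    datapoint, values deviating from the anchor by more than ``k`` record-SDs
    are flagged and replaced by the previous retained value before the block
    slides on.  NaN minutes are never flagged and never serve as fill values.
    """
    x = np.asarray(sbp, dtype=float)
    n = len(x)
    valid = ~np.isnan(x)
    if record_sd == 0.0 and np.unique(x[valid]).size > 1:
        raise RuntimeError("record_sd = 0 for a non-constant series")
    corrected = x.copy()
    flags = np.zeros(n, dtype=bool)
    if not valid.any():
        mask = ArtifactMask(flags)
        return mask, corrected
    thr = k * record_sd
    for start in range(0, max(n - block_len + 1, 1), step):
        anchor = corrected[start]
        if np.isnan(anchor):
            continue
        for j in range(start + 1, min(start + block_len, n)):
            v = corrected[j]
            if np.isnan(v) or flags[j]:
                continue
            if abs(v - anchor) > thr:
                flags[j] = True
                corrected[j] = _previous_retained(corrected, flags, j, anchor)
    mask = ArtifactMask(flags)
    mask.labels[WIDE] = flags.copy()
    return mask, corrected


def _previous_retained(corrected: np.ndarray, flags: np.ndarray, j: int,
                       fallback: float) -> float:
    for i in range(j - 1, -1, -1):
        if not np.isnan(corrected[i]):
            return corrected[i]
    return fallback


def detect_narrow(sbp: np.ndarray, rel_threshold: float = 0.30,
                  ) -> tuple[ArtifactMask, np.ndarray]:
    """Causal minute-to-minute relative-change detector on the
    wide-corrected series.

    Minute *t* is flagged iff |x_t - x_{t-1}| / x_{t-1} exceeds the
    threshold, where x_{t-1} is the corrected previous value; flagged values
    are immediately forward-filled so the return from a spike is not itself
    flagged.  A zero previous value makes the ratio undefined and the minute
    is treated as artifact.  Comparisons are only made between consecutive
    non-missing minutes.
    """
    x = np.asarray(sbp, dtype=float)
    n = len(x)
    corrected = x.copy()
    flags = np.zeros(n, dtype=bool)
    for t in range(1, n):
        prev = corrected[t - 1]
        cur = corrected[t]
        if np.isnan(cur) or np.isnan(prev):
            continue
        if prev == 0.0 or abs(cur - prev) / abs(prev) > rel_threshold:
            flags[t] = True
            corrected[t] = prev
    mask = ArtifactMask(flags)
    mask.labels[NARROW] = flags.copy()
    return mask, corrected


def remove_and_fill(record: VitalsRecord, mask: ArtifactMask) -> VitalsRecord:
    """Replace SBP/DBP/MAP/CPP at masked minutes by their most recent
    unmasked (and non-missing) values; other channels untouched; idempotent.

    A mask covering minute 0 is backfilled from the first clean minute.
    """
    rec = record.copy()
    flags = mask.flags
    if len(flags) != rec.n_minutes:
        raise ValueError("mask length does not match record")
    for ch in BP_CHANNELS:
        x = rec.channels[ch]
        last = np.nan
        pending: list[int] = []          # leading masked minutes to backfill
        for t in range(len(x)):
            if flags[t]:
                if np.isnan(last):
                    pending.append(t)
                else:
                    x[t] = last
            elif not np.isnan(x[t]):
                last = x[t]
                if pending:
                    x[pending] = last
                    pending = []
    return rec


def detect_artifacts(record: VitalsRecord, block_len: int = 5, k: float = 2.0,
                     rel_threshold: float = 0.30,
                     record_sd: float | None = None) -> ArtifactMask:
    """Full two-step detection on the SBP stream (wide, then narrow)."""
    sd = record_sbp_sd(record) if record_sd is None else record_sd
    wide_mask, corrected = detect_wide(record.channels["SBP"], sd,
                                       block_len=block_len, k=k)
    narrow_mask, _ = detect_narrow(corrected, rel_threshold=rel_threshold)
    mask = wide_mask.union(narrow_mask)
    mask.record_sd = sd
    return mask


def correct_record(record: VitalsRecord, block_len: int = 5, k: float = 2.0,
                   rel_threshold: float = 0.30,
                   record_sd: float | None = None,
                   ) -> tuple[VitalsRecord, ArtifactMask]:
    """Detect and remove BP artifacts; returns corrected record and mask.

    The record SD that parameterizes the wide detector is a one-time
    property of the *raw* record (computed before any correction); when
    re-applying the pass to an already-corrected record, supply the
    original SD (``mask.record_sd``) -- the pass is then idempotent.
    """
    mask = detect_artifacts(record, block_len=block_len, k=k,
                            rel_threshold=rel_threshold, record_sd=record_sd)
    return remove_and_fill(record, mask), mask


def adjudicate(record: VitalsRecord, mask: ArtifactMask,
               span: tuple[int, int] | None = None,
               missing_limit: float = 0.10) -> QCReport:
    """Record-level pass/fail adjudication.

    ``span`` restricts the missingness / poor-quality accounting to one
    analysis record (e.g. a 4-h case span); concurrency (simultaneous EKG,
    ABP and ICP coverage) is assessed on the whole record, mirroring the
    exclusion of monitoring records with under 4 h of concurrent data.
    A span is insufficient when the union of missing and artifact-replaced
    minutes exceeds ``missing_limit`` of its length in any BP stream.
    """
    lo, hi = (0, record.n_minutes) if span is None else span
    length = hi - lo
    flags = mask.flags[lo:hi]
    replaced = int(flags.sum())
    missing_fraction = {}
    poor = False
    for ch in BP_CHANNELS:
        miss = record.missing[ch][lo:hi]
        missing_fraction[ch] = float(miss.mean()) if length else 0.0
        if length and float((miss | flags).mean()) > missing_limit:
            poor = True
    concurrent = (~record.missing["HR_ekg"] & ~record.missing["SBP"]
                  & ~record.missing["ICP"])
    concurrent_hours = float(concurrent.sum()) / 60.0
    if poor:
        verdict = "exclude_missing"
    elif concurrent_hours < 4.0:
        verdict = "exclude_concurrency"
    else:
        verdict = "pass"
    return QCReport(
        record_id=record.record_id,
        record_sd=record_sbp_sd(record),
        replaced_minutes=replaced,
        replaced_fraction=replaced / length if length else 0.0,
        missing_fraction=missing_fraction,
        concurrent_hours=concurrent_hours,
        verdict=verdict,
    )
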