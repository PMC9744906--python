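"""Containers for minute-resolution multichannel vital-sign records.

A :class:`VitalsRecord` holds one patient-episode of bedside-monitor data
sampled on a strict 1-minute grid: arterial blood pressures (systolic,
diastolic, mean; mmHg), intracranial pressure (ICP; cm H2O), cerebral
perfusion pressure (CPP; mmHg), EKG-derived heart rate and plethysmographic
pulse rate (bpm), and oxygen saturation (%).  Missing minutes are stored as
NaN in the channel arrays and mirrored in a boolean ``missing`` mask.

ICP is kept in cm H2O (the clinical event threshold is 20 cm H2O); CPP is
computed in mmHg as MAP - ICP * :data:`ICP_CMH2O_TO_MMHG`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Channel order used throughout the package.
CHANNELS = ("SBP", "DBP", "MAP", "ICP", "CPP", "HR_ekg", "PR_pleth", "SpO2")

#: Blood-pressure-linked channels corrected together by the artifact pass.
BP_CHANNELS = ("SBP", "DBP", "MAP", "CPP")

#: Unit conversion: 1 cm H2O = 0.7355 mmHg, so CPP[mmHg] = MAP - ICP * k.
ICP_CMH2O_TO_MMHG = 0.7355

#: Grouping of feature channels into the physiologic signals used for
#: importance heatmaps (the three arterial pressures form one ABP signal;
#: EKG matches the bedside-monitor naming of the heart-rate stream).
SIGNAL_OF_CHANNEL = {
    "SBP": "ABP",
    "DBP": "ABP",
    "MAP": "ABP",
    "ICP": "ICP",
    "CPP": "CPP",
    "HR_ekg": "EKG",
    "PR_pleth": "Pleth",
    "SpO2": "SpO2",
}


@dataclass
class VitalsRecord:
    """One episode of minute-sampled multichannel monitor data."""

    record_id: str
    patient_id: str
    channels: dict[str, np.ndarray]
    missing: dict[str, np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must share one time grid")
        if self.missing is None:
            self.missing = {
                ch: np.isnan(np.asarray(v, dtype=float))
                for ch, v in self.channels.items()
            }
        self.channels = {
            ch: np.asarray(v, dtype=float) for ch, v in self.channels.items()
        }
        self.missing = {
            ch: np.asarray(v, dtype=bool) for ch, v in self.missing.items()
        }

    @property
    def n_minutes(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def t(self) -> np.ndarray:
        """Minutes since record start (integer grid, step 1)."""
        return np.arange(self.n_minutes)

    def copy(self) -> "VitalsRecord":
        return VitalsRecord(
            record_id=self.record_id,
            patient_id=self.patient_id,
            channels={ch: v.copy() for ch, v in self.channels.items()},
            missing={ch: v.copy() for ch, v in self.missing.items()},
        )

    # -- invariant checks -------------------------------------------------

    def clean_minutes(self) -> np.ndarray:
        """Minutes where no channel is missing."""
        ok = np.ones(self.n_minutes, dtype=bool)
        for m in self.missing.values():
            ok &= ~m
        return ok

    def check_physiology(self, exclude: np.ndarray | None = None,
                         cpp_tol: float = 0.5) -> dict[str, float]:
        """Fraction of evaluated minutes violating each physiologic invariant.

        ``exclude`` marks minutes (e.g. injected artifacts) left out of the
        check.  Returns violation fractions for the pressure ordering
        DBP < MAP < SBP, the CPP = MAP - k*ICP consistency, and range checks.
        """
        ok = self.clean_minutes()
        if exclude is not None:
            ok &= ~exclude
        n = max(int(ok.sum()), 1)
        c = self.channels
        order_bad = ((c["DBP"][ok] >= c["MAP"][ok])
                     | (c["MAP"][ok] >= c["SBP"][ok])).sum()
        cpp_bad = (np.abs(c["CPP"][ok] - (c["MAP"][ok]
                   - c["ICP"][ok] * ICP_CMH2O_TO_MMHG)) > cpp_tol).sum()
        spo2 = c["SpO2"][ok]
        range_bad = ((spo2 < 0) | (spo2 > 100)).sum()
        for ch in ("SBP", "DBP", "MAP", "ICP", "CPP"):
            range_bad += (c[ch][ok] < 0).sum()
        return {
            "ordering": order_bad / n,
            "cpp_consistency": cpp_bad / n,
            "range": range_bad / n,
        }

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: record_id, patient_id, minute, channel, value,
        missing_flag."""
        frames = []
        for ch in CHANNELS:
            frames.append(pd.DataFrame({
                "record_id": self.record_id,
                "patient_id": self.patient_id,
                "minute": self.t,
                "channel": ch,
                "value": self.channels[ch],
                "missing_flag": self.missing[ch].astype(int),
            }))
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VitalsRecord":
        rid = df["record_id"].iloc[0]
        pid = df["patient_id"].iloc[0]
        channels, missing = {}, {}
        for ch, grp in df.groupby("channel", sort=False):
            grp = grp.sort_values("minute")
            t = grp["minute"].to_numpy()
            if len(t) and not np.array_equal(t, np.arange(t[0], t[0] + len(t))):
                raise ValueError(f"channel {ch}: time grid not 1-min spaced")
            channels[ch] = grp["value"].to_numpy(dtype=float)
            missing[ch] = grp["missing_flag"].to_numpy(dtype=bool)
        return cls(record_id=rid, patient_id=pid, channels=channels,
                   missing=missing)


@dataclass
class EffectConfig:
    """Magnitudes of the pre-event (prodromal) signatures planted before an
    elevated-ICP event, ramped linearly over ``span_min`` minutes to onset.

    The six signatures mirror the directions reported for real pre-event
    physiology: rising ICP level and ICP irregularity, rising heart-rate
    histogram entropy, falling DBP trend, shrinking SBP variability and
    smoothing (lower sample entropy) of MAP.  ``magnitude`` scales all six
    at once; 0 yields a null cohort where case and control pre-anchor data
    are drawn from the same stochastic process.
    """

    magnitude: float = 1.0
    span_min: int = 240
    ramp: bool = True                 # ramp effects linearly toward onset
    icp_mean_delta: float = 2.8       # cm H2O added to ICP level at onset
    icp_entropy_noise: float = 0.45   # sd of extra white noise on ICP
    hr_swing: float = 4.5             # bpm amplitude of cyclic HR swings
    dbp_drift: float = -4.5           # mmHg drift of all ABP streams at onset
    sbp_sd_shrink: float = 0.33       # fraction of SBP fluctuation removed
    map_smooth: float = 0.45          # blend weight toward smoothed MAP

    @classmethod
    def null(cls) -> "EffectConfig":
        return cls(magnitude=0.0)

    def scaled(self, magnitude: float) -> "EffectConfig":
        return replace(self, magnitude=magnitude)


@dataclass
class GroundTruth:
    """Simulator-side truth for one record: event onsets, injected-artifact
    mask (per BP channel), planted effect, and the quiet intervals built as
    control periods."""

    event_onsets: list[int]
    artifact_mask_true: dict[str, np.ndarray]
    prodrome_effect: EffectConfig
    control_intervals: list[tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "event_onsets": [int(o) for o in self.event_onsets],
            "artifact_minutes": {
                ch: np.flatnonzero(m).tolist()
                for ch, m in self.artifact_mask_true.items()
            },
            "n_minutes": int(len(next(iter(self.artifact_mask_true.values())))),
            "prodrome_effect": vars(self.prodrome_effect),
            "control_intervals": [[int(a), int(b)]
                                  for a, b in self.control_intervals],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        n = d["n_minutes"]
        masks = {}
        for ch, idx in d["artifact_minutes"].items():
            m = np.zeros(n, dtype=bool)
            m[idx] = True
            masks[ch] = m
        return cls(
            event_onsets=list(d["event_onsets"]),
            artifact_mask_true=masks,
            prodrome_effect=EffectConfig(**d["prodrome_effect"]),
            control_intervals=[tuple(iv) for iv in d["control_intervals"]],
        )


def write_cohort(path: str | Path, records: Sequence[VitalsRecord],
                 truths: Sequence[GroundTruth] | None = None) -> None:
    """Write records as one long-format delimited file plus a JSON sidecar
    of ground truth (if given)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat([r.to_frame() for r in records], ignore_index=True).to_csv(
        path, index=False)
    if truths is not None:
        sidecar = {r.record_id: t.to_dict() for r, t in zip(records, truths)}
        path.with_suffix(".truth.json").write_text(
            json.dumps(sidecar, indent=1))


def read_cohort(path: str | Path) -> tuple[list[VitalsRecord],
                                           dict[str, GroundTruth]]:
    path = Path(path)
    df = pd.read_csv(path)
    records = [VitalsRecord.from_frame(grp)
               for _, grp in df.groupby("record_id", sort=False)]
    truths: dict[str, GroundTruth] = {}
    sidecar = path.with_suffix(".truth.json")
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        truths = {rid: GroundTruth.from_dict(d) for rid, d in raw.items()}
    return records, truths
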