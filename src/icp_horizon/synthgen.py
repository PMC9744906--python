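"""Synthetic cohorts of minute-resolution pediatric ICU vital signs.

Each simulated patient contributes one continuous monitor record assembled
from quiet 6-h stretches (control periods) and event blocks (a 4-h
pre-event span, a sustained run of ICP >= 20 cm H2O, and a 1-h
post-resolution washout).  Channel dynamics are mean-reverting: each signal
is a patient-level baseline plus a slow Ornstein-Uhlenbeck component
(hemodynamic drift over hours) plus a fast OU component (minute-scale
fluctuation).  Blood pressures are generated structurally -- DBP and pulse
pressure, with SBP = DBP + PP and MAP between them -- so the ordering
DBP < MAP < SBP holds by construction, and CPP = MAP - 0.7355 * ICP.

The generator returns exact ground truth (event onsets, injected-artifact
minutes, control intervals) so every downstream stage can be scored against
a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import (BP_CHANNELS, ICP_CMH2O_TO_MMHG, EffectConfig,
                      GroundTruth, VitalsRecord)

ICP_EVENT_THRESHOLD = 20.0       # cm H2O
QUIET_ICP_CEILING = 19.4         # quiet minutes clipped below threshold


class ConfigurationError(ValueError):
    """Raised for cohort configurations that cannot host analysis records."""


@dataclass
class ArtifactConfig:
    """Injected blood-pressure artifact process.

    Wide artifacts are multi-minute excursions far outside the record's own
    variability (line flushes, transducer drops -- mostly negative); narrow
    artifacts are single-minute relative jumps well above 30%.  Rates are
    events per 4-h (240-min) span so longer records scale linearly; the
    defaults corrupt about 2.8 minutes per 4-h record.
    """

    wide_rate_per_4h: float = 0.5
    wide_dur_min: int = 2
    wide_dur_max: int = 5
    wide_amp_lo: float = 25.0     # mmHg magnitude
    wide_amp_hi: float = 60.0
    narrow_rate_per_4h: float = 1.05
    narrow_rel_lo: float = 0.40   # relative single-minute change
    narrow_rel_hi: float = 0.80


@dataclass
class MissingnessConfig:
    """Contiguous data gaps: off-unit transport (all channels) or arterial
    line/sensor dysfunction (BP channels only)."""

    gap_rate_per_4h: float = 0.10
    gap_dur_min: int = 4
    gap_dur_max: int = 45
    p_all_channels: float = 0.5


@dataclass
class CohortConfig:
    """Study-scale cohort layout: ~10 analysis segments per patient with a
    ~1-in-11 case fraction reproduces the reference scale of roughly 20 case
    events and 200 control periods from 22 patients."""

    n_patients: int = 22
    segments_per_patient: int = 10
    case_fraction: float = 1.0 / 11.0
    record_len: int = 240          # analysis record, minutes
    control_duration: int = 360    # control period, minutes
    washout: int = 60              # post-resolution quiet span, minutes
    event_dur_min: int = 12
    event_dur_max: int = 25
    effect: EffectConfig = field(default_factory=EffectConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)

    def __post_init__(self) -> None:
        if self.record_len < 240:
            raise ConfigurationError(
                "record_len < 240 min cannot host a 4-h analysis record")
        if self.control_duration < self.record_len:
            raise ConfigurationError(
                "control_duration shorter than the analysis record")
        if not 0.0 <= self.case_fraction <= 1.0:
            raise ConfigurationError("case_fraction must be in [0, 1]")


# --------------------------------------------------------------------------
# base signal process


def _ou(n: int, sd: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary mean-zero Ornstein-Uhlenbeck (AR(1)) path."""
    if n == 0:
        return np.zeros(0)
    phi = np.exp(-1.0 / tau)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _baselines(rng: np.random.Generator) -> dict[str, float]:
    return {
        "DBP": rng.normal(62.0, 6.0),
        "PP": max(rng.normal(46.0, 6.0), 28.0),
        "HR": rng.normal(105.0, 12.0),
        "ICP": float(np.clip(rng.normal(12.0, 2.0), 6.0, 16.0)),
        "SpO2": float(np.clip(rng.normal(97.5, 1.0), 90.0, 100.0)),
    }


def _osc(n: int, amp: float, p_lo: float, p_hi: float,
         rng: np.random.Generator) -> np.ndarray:
    """Quasi-periodic slow oscillation (vasomotor-type cyclic variation)."""
    period = rng.uniform(p_lo, p_hi)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return amp * np.sin(2.0 * np.pi * np.arange(n) / period + phase)


def _channel_path(n: int, level: float, sd_slow: float, amp: float,
                  sd_fast: float, rng: np.random.Generator,
                  tau_slow: float = 150.0, tau_fast: float = 8.0,
                  p_lo: float = 8.0, p_hi: float = 20.0) -> np.ndarray:
    return (level + _ou(n, sd_slow, tau_slow, rng)
            + _osc(n, amp, p_lo, p_hi, rng) + _ou(n, sd_fast, tau_fast, rng))


def _base_channels(n: int, base: dict[str, float],
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Continuous clean channel paths of length ``n`` for one patient.

    Each signal = patient baseline + slow mean-reverting drift (hours) +
    quasi-periodic oscillation (minutes) + fast mean-reverting fluctuation.
    Minute-averaged bedside data are smooth at the 1-min scale; the fast
    component is correspondingly gentle.
    """
    dbp = _channel_path(n, base["DBP"], 3.0, 2.0, 0.6, rng)
    pp = _channel_path(n, base["PP"], 2.5, 1.5, 0.5, rng)
    pp = np.clip(pp, 22.0, None)
    sbp = dbp + pp
    m_extra = _ou(n, 0.8, 8.0, rng)
    mp = dbp + pp / 3.0 + np.clip(m_extra, -5.0, 5.0)
    icp = _channel_path(n, base["ICP"], 1.2, 1.2, 0.5, rng, p_lo=6.0,
                        p_hi=15.0)
    hr = _channel_path(n, base["HR"], 4.0, 2.0, 0.8, rng)
    pr = hr + rng.normal(0.0, 0.8, size=n)
    spo2 = np.clip(_channel_path(n, base["SpO2"], 0.5, 0.4, 0.3, rng),
                   0.0, 100.0)
    ch = {"SBP": sbp, "DBP": np.clip(dbp, 1.0, None), "MAP": mp, "ICP": icp,
          "HR_ekg": hr, "PR_pleth": pr, "SpO2": spo2}
    _enforce_ordering(ch)
    ch["ICP"] = np.clip(ch["ICP"], 0.0, None)
    ch["CPP"] = np.clip(ch["MAP"] - ch["ICP"] * ICP_CMH2O_TO_MMHG, 0.0, None)
    return ch


def _enforce_ordering(ch: dict[str, np.ndarray]) -> None:
    """Pin MAP strictly between DBP and SBP (margin 0.5 mmHg each side)."""
    ch["SBP"] = np.maximum(ch["SBP"], ch["DBP"] + 1.5)
    ch["MAP"] = np.clip(ch["MAP"], ch["DBP"] + 0.5, ch["SBP"] - 0.5)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    pad = w // 2
    xp = np.pad(x, pad, mode="edge")
    kernel = np.ones(w) / w
    return np.convolve(xp, kernel, mode="valid")[: len(x)]


# --------------------------------------------------------------------------
# prodrome planting


def plant_prodrome(record: VitalsRecord, onset: int, effect: EffectConfig,
                   rng: np.random.Generator | None = None) -> VitalsRecord:
    """Plant the six pre-event signatures over the ``effect.span_min``
    minutes preceding ``onset``, ramped linearly toward the event.

    Raises ``ValueError`` if ``onset`` leaves less than a 4-h history.
    CPP is recomputed from the modified MAP and ICP so the record's
    physiologic invariants still hold.
    """
    if onset < 240:
        raise ValueError(f"onset at minute {onset} leaves <4 h of history")
    rng = np.random.default_rng(0) if rng is None else rng
    rec = record.copy()
    mag = effect.magnitude
    if mag == 0.0:
        return rec
    start = max(0, onset - effect.span_min)
    span = slice(start, onset)
    n = onset - start
    if effect.ramp:
        ramp = np.linspace(0.0, 1.0, n, endpoint=False) + 1.0 / n
    else:
        ramp = np.ones(n)
    c = rec.channels

    # ICP: rising level and rising irregularity (higher sample entropy)
    c["ICP"][span] += mag * effect.icp_mean_delta * ramp
    c["ICP"][span] += rng.normal(0.0, 1.0, n) * (
        mag * effect.icp_entropy_noise * ramp)

    # HR: regular cyclic swings (sympathetic surges) spread the window
    # histogram toward uniform, raising binned entropy
    period = rng.uniform(10.0, 16.0)
    phase = rng.uniform(0.0, 1.0)
    frac = (np.arange(n) / period + phase) % 1.0
    tri = 4.0 * np.abs(frac - 0.5) - 1.0
    swing = mag * effect.hr_swing * ramp * tri
    c["HR_ekg"][span] += swing
    c["PR_pleth"][span] += swing

    # ABP: common downward drift (falling DBP trend / mean change)
    drift = mag * effect.dbp_drift * ramp
    for chn in ("SBP", "DBP", "MAP"):
        c[chn][span] += drift

    # SBP: shrink fluctuation about its local level (lower SD)
    shrink = np.clip(mag * effect.sbp_sd_shrink, 0.0, 0.95)
    local = _moving_average(c["SBP"][span], 15)
    c["SBP"][span] = local + (1.0 - shrink * ramp) * (c["SBP"][span] - local)

    # MAP: blend toward a smoothed path (lower sample entropy)
    w = np.clip(mag * effect.map_smooth, 0.0, 1.0) * ramp
    sm = _moving_average(c["MAP"][span], 5)
    c["MAP"][span] = (1.0 - w) * c["MAP"][span] + w * sm

    _enforce_ordering(c)
    for chn in ("SBP", "DBP", "MAP", "ICP"):
        c[chn] = np.clip(c[chn], 0.0, None)
    c["CPP"] = np.clip(c["MAP"] - c["ICP"] * ICP_CMH2O_TO_MMHG, 0.0, None)
    return rec


# --------------------------------------------------------------------------
# artifacts and missingness


def add_wide_excursion(record: VitalsRecord, start: int, dur: int,
                       amp: float) -> np.ndarray:
    """Add a multi-minute excursion of ``amp`` mmHg to all BP channels
    in place; returns the boolean mask of corrupted minutes."""
    n = record.n_minutes
    sl = slice(start, min(start + dur, n))
    for ch in BP_CHANNELS:
        record.channels[ch][sl] = np.clip(
            record.channels[ch][sl] + amp, 0.0, None)
    mask = np.zeros(n, dtype=bool)
    mask[sl] = True
    return mask


def add_narrow_spike(record: VitalsRecord, minute: int,
                     rel: float) -> np.ndarray:
    """Scale all BP channels at one minute by ``1 + rel`` in place;
    returns the boolean mask of the corrupted minute."""
    for ch in BP_CHANNELS:
        record.channels[ch][minute] *= (1.0 + rel)
    mask = np.zeros(record.n_minutes, dtype=bool)
    mask[minute] = True
    return mask


def inject_artifacts(record: VitalsRecord, config: ArtifactConfig,
                     seed: int | np.random.Generator,
                     ) -> tuple[VitalsRecord, dict[str, np.ndarray]]:
    """Corrupt BP-linked channels with wide and narrow artifacts.

    Corruption is coherent across SBP/DBP/MAP/CPP (a flushed or kinked
    arterial line distorts every derived pressure).  Returns the corrupted
    record and the true per-channel artifact mask.  Artifacts are never
    placed on missing minutes.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rec = record.copy()
    n = rec.n_minutes
    mask = np.zeros(n, dtype=bool)
    placeable = ~np.any([rec.missing[ch] for ch in BP_CHANNELS], axis=0)
    scale = n / 240.0

    n_wide = rng.poisson(config.wide_rate_per_4h * scale)
    for _ in range(n_wide):
        dur = int(rng.integers(config.wide_dur_min, config.wide_dur_max + 1))
        for _try in range(10):
            start = int(rng.integers(1, max(n - dur, 2)))
            sl = slice(start, start + dur)
            if not placeable[sl].all() or mask[sl].any():
                continue
            amp = rng.uniform(config.wide_amp_lo, config.wide_amp_hi)
            sign = -1.0 if rng.random() < 0.75 else 1.0
            for ch in BP_CHANNELS:
                rec.channels[ch][sl] = np.clip(
                    rec.channels[ch][sl] + sign * amp, 0.0, None)
            mask[sl] = True
            break

    n_narrow = rng.poisson(config.narrow_rate_per_4h * scale)
    for _ in range(n_narrow):
        for _try in range(10):
            t = int(rng.integers(1, n))
            if not placeable[t] or mask[t] or mask[t - 1]:
                continue
            rel = rng.uniform(config.narrow_rel_lo, config.narrow_rel_hi)
            factor = 1.0 + rel if rng.random() < 0.5 else 1.0 / (1.0 + rel)
            for ch in BP_CHANNELS:
                rec.channels[ch][t] *= factor
            mask[t] = True
            break

    true_mask = {ch: mask.copy() for ch in BP_CHANNELS}
    return rec, true_mask


def inject_missingness(record: VitalsRecord, config: MissingnessConfig,
                       rng: np.random.Generator,
                       avoid: np.ndarray | None = None) -> VitalsRecord:
    """Blank contiguous gaps (NaN + missing flag); gaps avoid ``avoid``
    minutes so the true artifact mask stays disjoint from missingness."""
    rec = record.copy()
    n = rec.n_minutes
    n_gaps = rng.poisson(config.gap_rate_per_4h * n / 240.0)
    for _ in range(n_gaps):
        dur = int(rng.integers(config.gap_dur_min, config.gap_dur_max + 1))
        for _try in range(8):
            start = int(rng.integers(0, max(n - dur, 1)))
            sl = slice(start, start + dur)
            if avoid is not None and avoid[sl].any():
                continue
            chans = (list(rec.channels) if rng.random() < config.p_all_channels
                     else list(BP_CHANNELS))
            for ch in chans:
                rec.channels[ch][sl] = np.nan
                rec.missing[ch][sl] = True
            break
    return rec


# --------------------------------------------------------------------------
# cohort assembly


@dataclass
class _Block:
    kind: str          # "control" | "case"
    length: int
    event_dur: int = 0


def _plan_patient(cfg: CohortConfig, rng: np.random.Generator) -> list[_Block]:
    blocks: list[_Block] = []
    for _ in range(cfg.segments_per_patient):
        if rng.random() < cfg.case_fraction:
            dur = int(rng.integers(cfg.event_dur_min, cfg.event_dur_max + 1))
            blocks.append(_Block("case", cfg.record_len + dur + cfg.washout,
                                 event_dur=dur))
        else:
            blocks.append(_Block("control", cfg.control_duration))
    rng.shuffle(blocks)
    return blocks


def generate_record(patient_id: str, record_id: str, cfg: CohortConfig,
                    rng: np.random.Generator,
                    ) -> tuple[VitalsRecord, GroundTruth]:
    """Simulate one patient record according to a random block plan."""
    blocks = _plan_patient(cfg, rng)
    total = sum(b.length for b in blocks)
    base = _baselines(rng)
    channels = _base_channels(total, base, rng)
    rec = VitalsRecord(record_id=record_id, patient_id=patient_id,
                       channels=channels)

    onsets: list[int] = []
    controls: list[tuple[int, int]] = []
    pos = 0
    for b in blocks:
        if b.kind == "control":
            controls.append((pos, pos + b.length))
            pos += b.length
            continue
        onset = pos + cfg.record_len
        run = slice(onset, onset + b.event_dur)
        # prodrome over the pre-onset span, then the sustained run
        rec = plant_prodrome(rec, onset, cfg.effect, rng)
        icp = rec.channels["ICP"]
        peak = rng.uniform(2.0, 6.0)
        bump = np.abs(_ou(b.event_dur, 1.0, 5.0, rng))
        icp[run] = np.clip(ICP_EVENT_THRESHOLD + 0.4 + peak * np.sin(
            np.linspace(0.15, np.pi - 0.15, b.event_dur)) + bump,
            ICP_EVENT_THRESHOLD + 0.2, None)
        # decay back under threshold through the washout
        wo = slice(onset + b.event_dur, onset + b.event_dur + cfg.washout)
        decay = np.linspace(QUIET_ICP_CEILING - 0.5, base["ICP"],
                            cfg.washout)
        icp[wo] = decay + _ou(cfg.washout, 0.5, 4.0, rng)
        onsets.append(onset)
        pos += b.length

    # clip all non-event minutes safely below threshold
    icp = rec.channels["ICP"]
    quiet = np.ones(total, dtype=bool)
    for o, b in zip(onsets, [b for b in blocks if b.kind == "case"]):
        quiet[o:o + b.event_dur] = False
    icp[quiet] = np.clip(icp[quiet], 0.0, QUIET_ICP_CEILING)
    rec.channels["CPP"] = np.clip(
        rec.channels["MAP"] - icp * ICP_CMH2O_TO_MMHG, 0.0, None)

    rec, true_mask = inject_artifacts(rec, cfg.artifact, rng)
    # gaps avoid injected artifacts (truth masks stay disjoint from
    # missingness) and event runs (every true event remains observable)
    avoid = np.any(list(true_mask.values()), axis=0)
    avoid[~quiet] = True
    rec = inject_missingness(rec, cfg.missingness, rng, avoid=avoid)
    # re-blank artifact mask on minutes that became missing (should be none)
    for ch in true_mask:
        true_mask[ch] &= ~rec.missing[ch]

    truth = GroundTruth(event_onsets=onsets, artifact_mask_true=true_mask,
                        prodrome_effect=cfg.effect,
                        control_intervals=controls)
    return rec, truth


def generate_cohort(n_patients: int, cohort_config: CohortConfig | None = None,
                    seed: int = 0,
                    ) -> tuple[list[VitalsRecord], list[GroundTruth]]:
    """Simulate ``n_patients`` records with exact ground truth.

    Deterministic for a fixed seed and config.  With the default config the
    cohort approximates a 10:1 control:case imbalance.
    """
    if n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    cfg = cohort_config if cohort_config is not None else CohortConfig()
    cfg = replace(cfg, n_patients=n_patients)
    rng = np.random.default_rng(seed)
    records, truths = [], []
    for i in range(n_patients):
        pid = f"P{i:03d}"
        rec, truth = generate_record(pid, f"{pid}_R0", cfg, rng)
        records.append(rec)
        truths.append(truth)
    return records, truths
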