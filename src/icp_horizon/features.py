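"""Per-window statistical features of minute-sampled vital-sign series.

Eighteen statistics are computed per channel per 30-min analysis window:
location (mean, median, max, min, quantiles 0.2/0.4/0.6/0.8), dispersion
(variance, SD -- population denominator n), four aggregated moments of the
one-sided FFT magnitude spectrum (treating the normalized magnitudes over
frequency indices k = 0..n//2 as a probability distribution: its variance,
centroid, kurtosis and skew), complexity (sample entropy with m=2 and
r = 0.2*SD under the Chebyshev metric, self-matches excluded; Shannon
entropy of a 10-bin equal-width histogram, natural log), and change
(summed absolute first difference; net change per minute).

Statistics that are undefined on a window -- sample entropy with no
template matches, spectral moments of a zero spectrum, anything on fewer
than two non-missing samples -- are returned as NaN markers and imputed
downstream (median imputation for linear models; tree models consume the
marker natively).
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .records import CHANNELS
from .segmentation import AnalysisWindow, Segment, window_segment

STAT_NAMES = (
    "mean", "median", "max", "min", "q20", "q40", "q60", "q80",
    "variance", "sd",
    "fft_agg_variance", "fft_centroid", "fft_kurtosis", "fft_skew",
    "sample_entropy", "binned_entropy", "abs_change", "mean_change",
)

BP_ONLY = ("SBP", "DBP", "MAP")
CHANNEL_SETS = {"full": CHANNELS, "bp_only": BP_ONLY}

ID_COLUMNS = ("segment_id", "patient_id", "label")


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) = -ln(A/B); NaN when no matches exist or SD is zero."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= m + 1:
        return math.nan
    if r is None:
        sd = float(np.std(x))
        if sd == 0.0:
            return math.nan
        r = 0.2 * sd
    def _count(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)[: n - m]
        # Chebyshev distances between all template pairs, self-pairs excluded
        d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=-1)
        iu = np.triu_indices(len(templ), k=1)
        return int((d[iu] <= r).sum())
    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def binned_entropy(x: np.ndarray, bins: int = 10) -> float:
    """Shannon entropy (nats) of an equal-width histogram over [min, max]."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / len(x)
    return float(-(p * np.log(p)).sum())


def fft_moments(x: np.ndarray) -> dict[str, float]:
    """Aggregated moments of the one-sided FFT magnitude spectrum.

    The normalized magnitudes p_k = |F_k| / sum|F| over k = 0..n//2 are
    treated as a distribution on the frequency index; returns its centroid,
    variance, skew and kurtosis (the latter two NaN when the spectral
    variance vanishes, e.g. a constant series).
    """
    x = np.asarray(x, dtype=float)
    mag = np.abs(np.fft.rfft(x))
    total = mag.sum()
    nan = {"fft_centroid": math.nan, "fft_agg_variance": math.nan,
           "fft_skew": math.nan, "fft_kurtosis": math.nan}
    if total == 0.0 or not np.isfinite(total):
        return nan
    p = mag / total
    k = np.arange(len(p))
    c = float((k * p).sum())
    v = float((((k - c) ** 2) * p).sum())
    out = {"fft_centroid": c, "fft_agg_variance": v}
    if v <= 0.0:
        out["fft_skew"] = math.nan
        out["fft_kurtosis"] = math.nan
    else:
        s = math.sqrt(v)
        out["fft_skew"] = float(((((k - c) / s) ** 3) * p).sum())
        out["fft_kurtosis"] = float(((((k - c) / s) ** 4) * p).sum())
    return out


def extract_features(x: np.ndarray) -> dict[str, float]:
    """The 18 statistics of one analysis-window series.

    Missing (NaN) samples are dropped; with fewer than two remaining
    samples every statistic is the NaN undefined marker.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        return {name: math.nan for name in STAT_NAMES}
    q20, q40, q60, q80 = np.quantile(x, [0.2, 0.4, 0.6, 0.8])
    var = float(np.var(x))
    out = {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "max": float(np.max(x)),
        "min": float(np.min(x)),
        "q20": float(q20), "q40": float(q40),
        "q60": float(q60), "q80": float(q80),
        "variance": var,
        "sd": math.sqrt(var),
        "sample_entropy": sample_entropy(x),
        "binned_entropy": binned_entropy(x),
        "abs_change": float(np.abs(np.diff(x)).sum()),
        "mean_change": float((x[-1] - x[0]) / (len(x) - 1)),
    }
    out.update(fft_moments(x))
    return out


def feature_columns(channels: Iterable[str]) -> list[str]:
    """Stable column naming: ``<channel>__<statistic>``."""
    return [f"{ch}__{stat}" for ch in channels for stat in STAT_NAMES]


def signal_map(columns: Iterable[str]) -> dict[str, str]:
    """Map feature columns to their source channel (prefix before '__')."""
    return {col: col.split("__", 1)[0] for col in columns}


def build_tables(segments: Iterable[Segment],
                 windows: list[AnalysisWindow] | None = None,
                 channels: str | tuple[str, ...] = "full",
                 ) -> dict[int, pd.DataFrame]:
    """One labeled feature table per analysis-window index.

    ``channels`` is the full eight-stream set or the BP-only ablation
    subset {SBP, DBP, MAP}; only the enabled channels are ever read.
    """
    if isinstance(channels, str):
        channels = CHANNEL_SETS[channels]
    if windows is None:
        windows = window_segment()
    cols = feature_columns(channels)
    tables: dict[int, pd.DataFrame] = {}
    segments = list(segments)
    for w in windows:
        rows = []
        for seg in segments:
            row: dict[str, object] = {
                "segment_id": seg.segment_id,
                "patient_id": seg.patient_id,
                "label": seg.label,
            }
            for ch in channels:
                stats = extract_features(seg.window_values(ch, w))
                for stat, val in stats.items():
                    row[f"{ch}__{stat}"] = val
            rows.append(row)
        tables[w.index] = pd.DataFrame(rows, columns=list(ID_COLUMNS) + cols)
    return tables
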