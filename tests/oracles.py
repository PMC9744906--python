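"""Independent reference implementations used to cross-check the package:
naive per-statistic computations (pure-python loops) and brute-force
per-minute segmentation scanners."""

import cmath
import math


# -- feature statistics -----------------------------------------------------


def naive_quantile(xs, q):
    s = sorted(xs)
    pos = q * (len(s) - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (pos - lo) * (s[hi] - s[lo])


def naive_sampen(xs, m=2):
    n = len(xs)
    sd = math.sqrt(sum((v - sum(xs) / n) ** 2 for v in xs) / n)
    if sd == 0:
        return math.nan
    r = 0.2 * sd

    def count(mm):
        c = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if all(abs(xs[i + k] - xs[j + k]) <= r for k in range(mm)):
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return math.nan
    return -math.log(a / b)


def naive_binned_entropy(xs, bins=10):
    lo, hi = min(xs), max(xs)
    if lo == hi:
        return 0.0
    counts = [0] * bins
    for v in xs:
        idx = min(int((v - lo) / (hi - lo) * bins), bins - 1)
        counts[idx] += 1
    ent = 0.0
    for c in counts:
        if c:
            p = c / len(xs)
            ent -= p * math.log(p)
    return ent


def naive_fft_moments(xs):
    n = len(xs)
    mags = []
    for k in range(n // 2 + 1):
        f = sum(x * cmath.exp(-2j * cmath.pi * k * t / n)
                for t, x in enumerate(xs))
        mags.append(abs(f))
    total = sum(mags)
    p = [m / total for m in mags]
    c = sum(k * pk for k, pk in enumerate(p))
    v = sum((k - c) ** 2 * pk for k, pk in enumerate(p))
    out = {"fft_centroid": c, "fft_agg_variance": v}
    if v <= 0:
        out["fft_skew"] = math.nan
        out["fft_kurtosis"] = math.nan
    else:
        s = math.sqrt(v)
        out["fft_skew"] = sum(((k - c) / s) ** 3 * pk
                              for k, pk in enumerate(p))
        out["fft_kurtosis"] = sum(((k - c) / s) ** 4 * pk
                                  for k, pk in enumerate(p))
    return out


def naive_all(xs):
    n = len(xs)
    mean = sum(xs) / n
    var = sum((v - mean) ** 2 for v in xs) / n
    out = {
        "mean": mean,
        "median": naive_quantile(xs, 0.5),
        "max": max(xs), "min": min(xs),
        "q20": naive_quantile(xs, 0.2), "q40": naive_quantile(xs, 0.4),
        "q60": naive_quantile(xs, 0.6), "q80": naive_quantile(xs, 0.8),
        "variance": var, "sd": math.sqrt(var),
        "sample_entropy": naive_sampen(xs),
        "binned_entropy": naive_binned_entropy(xs),
        "abs_change": sum(abs(xs[i + 1] - xs[i]) for i in range(n - 1)),
        "mean_change": (xs[-1] - xs[0]) / (n - 1),
    }
    out.update(naive_fft_moments(xs))
    return out


# -- segmentation -----------------------------------------------------------


def brute_case_onsets(icp, threshold=20.0, duration=10):
    """O(n * duration) scan: a minute is an onset iff it starts >=duration
    supra-threshold minutes and the previous minute is not supra."""
    n = len(icp)
    onsets = []
    for t in range(n):
        if t + duration > n:
            break
        if not all(icp[t + k] >= threshold for k in range(duration)):
            continue
        if t > 0 and icp[t - 1] >= threshold:
            continue
        onsets.append(t)
    return onsets


def brute_control_periods(icp, duration=360, threshold=20.0):
    """Per-minute greedy scan of quiet stretches, tiled from each
    maximal stretch start."""
    n = len(icp)
    periods = []
    next_free = 0
    for s in range(n):
        if s < next_free:
            continue
        if s + duration > n:
            break
        if all(not (icp[s + k] >= threshold) for k in range(duration)):
            stretch_start = s
            while stretch_start > 0 and not (icp[stretch_start - 1]
                                             >= threshold):
                stretch_start -= 1
            if (s - stretch_start) % duration == 0:
                periods.append((s, s + duration))
                next_free = s + duration
    return periods
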