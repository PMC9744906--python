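"""SHAP-style attribution of the gradient-boosted bundles and the
per-signal x per-window differential-expression heatmap.

Attributions are exact TreeSHAP values computed by the booster itself
(``pred_contribs``): for every scored row the per-feature contributions
plus the base value equal the model's margin output (local accuracy).
Feature importance is the mean absolute attribution over the test rows of
one Monte-Carlo iteration; the top-20 features of each (window, iteration)
cell, pooled over the 10 iterations, are counted by source physiologic
signal to build the heatmap -- each window column therefore sums to
20 x 10 = 200 entries.  Attribution is supported for the tree bundles
only; linear-model coefficients are reported separately and never mixed
into the heatmap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost

from .modeling import BenchmarkResult, FittedModel
from .records import SIGNAL_OF_CHANNEL

TOP_K = 20

#: Row order of the heatmap (display names follow monitor terminology).
SIGNALS = ("ABP", "ICP", "CPP", "EKG", "Pleth", "SpO2")


class UnsupportedModelError(TypeError):
    """Attribution requested for a non-tree model family."""


def attribute(model: FittedModel, X: pd.DataFrame,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-row, per-feature TreeSHAP attributions and base values.

    Only exact for tree ensembles; other families raise
    :class:`UnsupportedModelError`.
    """
    if model.family != "xgb":
        raise UnsupportedModelError(
            f"exact additive attribution is implemented for the XGB "
            f"bundles only, not {model.family!r}")
    booster = model.estimator.get_booster()
    dm = xgboost.DMatrix(X[model.feature_names], missing=np.nan)
    contrib = booster.predict(dm, pred_contribs=True)
    return contrib[:, :-1], contrib[:, -1]


def mean_abs_attribution(model: FittedModel, X: pd.DataFrame) -> pd.Series:
    contrib, _ = attribute(model, X)
    return pd.Series(np.abs(contrib).mean(axis=0), index=model.feature_names)


def rank_top(importance: pd.Series, k: int = TOP_K) -> list[str]:
    """Top-k feature names by importance, ties broken lexicographically."""
    order = sorted(importance.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in order[:k]]


@dataclass
class ShapSummary:
    """Ranked top-k lists and averaged importances per analysis window."""

    ranked: dict[tuple[int, int], list[str]]       # (window, iteration)
    averaged: dict[int, pd.Series]                 # window -> mean importance
    top_k: int = TOP_K
    n_iterations: int = 10


def summarize_attributions(result: BenchmarkResult, top_k: int = TOP_K,
                           ) -> ShapSummary:
    """Attribution summary over every stored (window, iteration) bundle."""
    ranked: dict[tuple[int, int], list[str]] = {}
    per_window: dict[int, list[pd.Series]] = {}
    for (w, it), (model, test) in sorted(result.xgb_bundles.items()):
        imp = mean_abs_attribution(model, test)
        ranked[(w, it)] = rank_top(imp, k=top_k)
        per_window.setdefault(w, []).append(imp)
    averaged = {w: pd.concat(series, axis=1).mean(axis=1)
                for w, series in per_window.items()}
    n_iter = max((it for _, it in ranked), default=0)
    return ShapSummary(ranked=ranked, averaged=averaged, top_k=top_k,
                       n_iterations=n_iter)


@dataclass
class SignalWindowHeatmap:
    """counts[signal, window] = pooled top-k entries from that signal."""

    counts: pd.DataFrame                   # signals x windows
    channel_counts: pd.DataFrame           # channels x windows
    top_k: int = TOP_K
    n_iterations: int = 10


def heatmap(summary: ShapSummary,
            signal_map: dict[str, str] | None = None) -> SignalWindowHeatmap:
    """Pool the ranked lists into per-signal x per-window counts.

    Raises if any (window, iteration) cell of the grid is missing, so a
    partial benchmark cannot silently produce an under-filled column.
    """
    windows = sorted({w for w, _ in summary.ranked})
    iters = sorted({it for _, it in summary.ranked})
    gaps = [(w, it) for w in windows for it in iters
            if (w, it) not in summary.ranked]
    if gaps:
        raise ValueError(f"missing attribution cells: {gaps}")
    chan_counts = pd.DataFrame(0, index=sorted(SIGNAL_OF_CHANNEL),
                               columns=windows)
    for (w, _it), names in summary.ranked.items():
        for name in names:
            ch = name.split("__", 1)[0]
            chan_counts.loc[ch, w] += 1
    if signal_map is None:
        signal_map = SIGNAL_OF_CHANNEL
    sig = chan_counts.groupby(
        [signal_map.get(ch, ch) for ch in chan_counts.index]).sum()
    sig = sig.reindex([s for s in SIGNALS if s in sig.index])
    return SignalWindowHeatmap(counts=sig, channel_counts=chan_counts,
                               top_k=summary.top_k,
                               n_iterations=len(iters))


def bp_fraction(hm: SignalWindowHeatmap, window: int) -> dict[str, float]:
    """Shares of the window's ABP-derived top entries from SBP/DBP/MAP.

    Undefined (NaN shares) when the window has no ABP-derived entries.
    """
    counts = {ch: int(hm.channel_counts.loc[ch, window])
              for ch in ("SBP", "DBP", "MAP")}
    total = sum(counts.values())
    if total == 0:
        return {ch: math.nan for ch in counts}
    return {ch: c / total for ch, c in counts.items()}


def lr_importances(model: FittedModel) -> pd.Series:
    """Absolute standardized coefficients of a fitted LR bundle, reported
    separately from the tree attributions."""
    if model.family != "lr":
        raise UnsupportedModelError("coefficient report is for LR bundles")
    clf = model.estimator.named_steps["clf"]
    return pd.Series(np.abs(clf.coef_[0]), index=model.feature_names)


# -- plotting ---------------------------------------------------------------


def plot_heatmap(hm: SignalWindowHeatmap, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    m = hm.counts.to_numpy()
    im = ax.imshow(m, cmap="Blues", aspect="auto")
    ax.set_xticks(range(m.shape[1]),
                  [f"{30*(w-1)}-{30*w}" for w in hm.counts.columns])
    ax.set_yticks(range(m.shape[0]), hm.counts.index)
    ax.set_xlabel("analysis window (min before anchor)")
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            ax.text(j, i, int(m[i, j]), ha="center", va="center",
                    fontsize=8,
                    color="white" if m[i, j] > m.max() / 2 else "black")
    fig.colorbar(im, ax=ax, label=f"top-{hm.top_k} features pooled over "
                                  f"{hm.n_iterations} iterations")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_importance(importance: pd.Series, path: str, k: int = TOP_K) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = importance.sort_values(ascending=False).head(k)[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.3 * k + 1))
    ax.barh(top.index, top.to_numpy(), color="#3b6ea5")
    ax.set_xlabel("mean |attribution|")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
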