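"""Sequential model-based hyperparameter search.

A compact Bayesian-optimization loop: parameters are mapped to the unit
cube (log-scaled where requested), an initial batch is sampled at random,
then a Gaussian-process surrogate (Matern 5/2) proposes the next point by
expected improvement over a random candidate set.  Deterministic under a
fixed seed.  A budget of one evaluation collapses gracefully to the
documented default parameters of the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern


@dataclass
class Real:
    name: str
    lo: float
    hi: float
    log: bool = False

    def decode(self, u: float) -> float:
        if self.log:
            return float(np.exp(np.log(self.lo)
                                + u * (np.log(self.hi) - np.log(self.lo))))
        return float(self.lo + u * (self.hi - self.lo))


@dataclass
class Integer:
    name: str
    lo: int
    hi: int

    def decode(self, u: float) -> int:
        return int(np.clip(round(self.lo + u * (self.hi - self.lo)),
                           self.lo, self.hi))


Dimension = Real | Integer


def _decode(space: Sequence[Dimension], u: np.ndarray) -> dict:
    return {dim.name: dim.decode(float(ui)) for dim, ui in zip(space, u)}


def smbo_minimize(objective: Callable[[dict], float],
                  space: Sequence[Dimension], n_calls: int,
                  seed: int = 0, n_initial: int = 8,
                  n_candidates: int = 256) -> tuple[dict, list[tuple[dict, float]]]:
    """Minimize ``objective`` over ``space`` with ``n_calls`` evaluations.

    Returns the best parameter dict and the full evaluation history.
    """
    rng = np.random.default_rng(seed)
    d = len(space)
    n_init = min(max(n_initial, 1), n_calls)
    us = [rng.random(d) for _ in range(n_init)]
    history: list[tuple[dict, float]] = []
    X, y = [], []
    for u in us:
        params = _decode(space, u)
        val = float(objective(params))
        history.append((params, val))
        X.append(u)
        y.append(val)

    while len(history) < n_calls:
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=np.full(d, 0.3),
                          length_scale_bounds=(5e-2, 1e1)),
            alpha=1e-4, normalize_y=True,
            random_state=int(rng.integers(2**31)))
        gp.fit(np.array(X), np.array(y))
        cand = rng.random((n_candidates, d))
        mu, sigma = gp.predict(cand, return_std=True)
        best = min(y)
        sigma = np.maximum(sigma, 1e-12)
        z = (best - mu) / sigma
        ei = (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)
        u = cand[int(np.argmax(ei))]
        params = _decode(space, u)
        val = float(objective(params))
        history.append((params, val))
        X.append(u)
        y.append(val)

    best_params, _ = min(history, key=lambda h: h[1])
    return best_params, history
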