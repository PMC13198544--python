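"""WAIC model comparison from pointwise posterior log-likelihoods.

WAIC estimates out-of-sample predictive accuracy from the whole posterior:
``lppd`` is the summed log of the posterior-mean pointwise likelihood, and the
effective number of parameters ``p_waic`` is the summed posterior variance of
the pointwise log-likelihood (the variance form).  Reported on the deviance
scale, ``waic = -2 (lppd - p_waic)``, so smaller is better; ``delta_waic``
rescales a set of models so the best one sits at exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["WaicResult", "waic", "delta_waic"]


@dataclass(frozen=True)
class WaicResult:
    lppd: float
    p_waic: float
    waic: float
    se: float
    n_trials: int
    n_draws: int


def waic(pointwise: np.ndarray) -> WaicResult:
    """WAIC from a (trials x draws) matrix of log-likelihoods."""
    ll = np.asarray(pointwise, dtype=float)
    if ll.ndim != 2 or ll.shape[1] < 1:
        raise ValueError("pointwise must be a (trials x draws) matrix")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihoods must be finite")
    n, S = ll.shape
    if S == 1:
        warnings.warn("single posterior draw: p_waic is 0", stacklevel=2)
    lppd_i = logsumexp(ll, axis=1) - np.log(S)
    p_i = np.var(ll, axis=1, ddof=0)
    elpd_i = lppd_i - p_i
    se = float(np.sqrt(n * np.var(-2.0 * elpd_i, ddof=0))) if n > 1 else 0.0
    return WaicResult(
        lppd=float(lppd_i.sum()),
        p_waic=float(p_i.sum()),
        waic=float(-2.0 * elpd_i.sum()),
        se=se,
        n_trials=n,
        n_draws=S,
    )


def delta_waic(results: list[WaicResult | float]) -> np.ndarray:
    """WAIC differences relative to the best (lowest-WAIC) model.

    The best model's delta is exactly zero; all others are non-negative.
    """
    if len(results) == 0:
        raise ValueError("need at least one model")
    vals = np.array(
        [r.waic if isinstance(r, WaicResult) else float(r) for r in results]
    )
    return vals - vals.min()
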