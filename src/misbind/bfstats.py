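"""Default-prior Bayes factors and within-subject error bars.

t tests use the JZS construction: the standardized effect size receives a
zero-centred Cauchy prior (default scale 0.707) and the Bayes factor is the
ratio of the marginal likelihood of the observed t statistic under that prior
to its likelihood under the point null, computed by adaptive quadrature of the
noncentral-t density.  Correlations use the analogous default construction
with a stretched-beta prior on the population correlation and Fisher's exact
sampling density of r.  Evidence bands follow the conventional cutpoints
(3 / 10 / 30 / 100, mirrored for the null side).

Condition-wise error bars use the Loftus-Masson normalization: each subject's
mean across conditions is removed (and the grand mean restored) before
computing per-condition standard errors, so between-subject offsets do not
inflate the error bars of a within-subject design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.special import betaln, hyp2f1

__all__ = [
    "BayesFactorResult",
    "bf_ttest",
    "bf_correlation",
    "bf_sensitivity",
    "interpret_bf",
    "within_subject_sem",
]

DEFAULT_PRIOR_SCALE = 0.707

_BANDS_H1 = (
    (100.0, "extreme evidence for H1"),
    (30.0, "very strong evidence for H1"),
    (10.0, "strong evidence for H1"),
    (3.0, "moderate evidence for H1"),
)


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    test: str  # paired | one_sample | independent | correlation
    n: int
    n2: int | None = None
    prior_scale: float = DEFAULT_PRIOR_SCALE

    @property
    def band(self) -> str:
        return interpret_bf(self.bf10)


def interpret_bf(bf10: float) -> str:
    """Evidence category of a Bayes factor, per the conventional cutpoints."""
    if not np.isfinite(bf10) or bf10 <= 0:
        raise ValueError("bf10 must be a positive finite number")
    for cut, label in _BANDS_H1:
        if bf10 > cut:
            return label
    if bf10 >= 1.0 / 3.0:
        return "anecdotal"
    for cut, label in _BANDS_H1:
        if bf10 < 1.0 / cut:
            return label.replace("H1", "H0")
    return "moderate evidence for H0"


def _t_and_dof(x, y, paired):
    x = np.asarray(x, dtype=float)
    if y is None or paired:
        d = x if y is None else x - np.asarray(y, dtype=float)
        n = d.size
        if n < 2:
            raise ValueError("need at least 2 observations")
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("degenerate data: zero variance")
        t = d.mean() / (sd / math.sqrt(n))
        return t, n - 1, float(n), n, None, "paired" if y is not None else "one_sample"
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 observations per group")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("degenerate data: zero variance")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, n1 + n2 - 2, n1 * n2 / (n1 + n2), n1, n2, "independent"


def _jzs_bf_from_t(t: float, nu: int, n_eff: float, scale: float) -> float:
    """JZS Bayes factor by quadrature over the Cauchy effect-size prior."""

    def integrand(delta):
        return stats.nct.pdf(t, nu, delta * math.sqrt(n_eff)) * stats.cauchy.pdf(
            delta, scale=scale
        )

    # split at the MLE of the effect size so quad sees the likelihood peak
    centre = t / math.sqrt(n_eff)
    marg, _ = _split_quad(integrand, centre)
    null = stats.t.pdf(t, nu)
    return marg / null


def _split_quad(f, centre: float) -> tuple[float, float]:
    lo, el = integrate.quad(f, -np.inf, min(0.0, centre), limit=200,
                            epsabs=1e-12, epsrel=1e-10)
    mid, em = integrate.quad(f, min(0.0, centre), max(0.0, centre), limit=200,
                             epsabs=1e-12, epsrel=1e-10)
    hi, eh = integrate.quad(f, max(0.0, centre), np.inf, limit=200,
                            epsabs=1e-12, epsrel=1e-10)
    return lo + mid + hi, el + em + eh


def bf_ttest(
    x,
    y=None,
    paired: bool = False,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> BayesFactorResult:
    """Default-prior Bayes factor t test.

    ``y=None`` is a one-sample test against zero; ``paired=True`` tests the
    element-wise differences; otherwise an independent-samples test with a
    pooled variance.
    """
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    if paired and (y is None or len(np.atleast_1d(x)) != len(np.atleast_1d(y))):
        raise ValueError("paired test requires two equal-length samples")
    t, nu, n_eff, n1, n2, kind = _t_and_dof(x, y, paired)
    bf = _jzs_bf_from_t(t, nu, n_eff, prior_scale)
    return BayesFactorResult(bf10=float(bf), test=kind, n=n1, n2=n2,
                             prior_scale=prior_scale)


def _corr_kernel(rho, r: float, n: int):
    """Sampling-density kernel of the observed correlation r given rho
    (r-only factors dropped: they cancel in the Bayes-factor ratio)."""
    return (
        (1.0 - rho**2) ** ((n - 1) / 2.0)
        * (1.0 - rho * r) ** (1.5 - n)
        * hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)
    )


def _stretched_beta_logpdf(rho, width: float):
    a = 1.0 / width
    return (a - 1.0) * np.log1p(-np.square(rho)) - (2.0 * a - 1.0) * math.log(2.0) - betaln(a, a)


def bf_correlation(
    x, y, prior_scale: float = DEFAULT_PRIOR_SCALE
) -> BayesFactorResult:
    """Default Bayes factor for a Pearson correlation.

    The population correlation receives a stretched-beta prior of width
    ``prior_scale`` on (-1, 1); the marginal likelihood of the observed r is
    computed by quadrature against the exact sampling density of r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate data: constant input")
    if prior_scale <= 0:
        raise ValueError("prior_scale must be positive")
    n = int(x.size)
    r = float(np.corrcoef(x, y)[0, 1])

    def integrand(rho):
        return _corr_kernel(rho, r, n) * math.exp(
            _stretched_beta_logpdf(rho, prior_scale)
        )

    marg, _ = integrate.quad(integrand, -1.0, 1.0, limit=200,
                             epsabs=1e-12, epsrel=1e-10)
    bf = marg / _corr_kernel(0.0, r, n)
    return BayesFactorResult(bf10=float(bf), test="correlation", n=n,
                             prior_scale=prior_scale)


def bf_sensitivity(
    x, y=None, paired: bool = False, scale_grid=(0.1, 0.3, 0.5, 0.707, 1.0, 1.41)
) -> list[BayesFactorResult]:
    """Bayes factors across a grid of prior scales (no interpolation)."""
    grid = [float(s) for s in scale_grid]
    if len(grid) == 0 or any(s <= 0 for s in grid):
        raise ValueError("scale grid must contain positive scales")
    return [bf_ttest(x, y, paired=paired, prior_scale=s) for s in grid]


def within_subject_sem(values: np.ndarray) -> np.ndarray:
    """Loftus-Masson within-subject SEM per condition.

    ``values`` is a complete (subjects x conditions) matrix.  Each subject's
    row mean is subtracted and the grand mean added back before computing the
    per-condition standard error of the mean.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("need a (subjects x conditions) matrix with >= 2 subjects")
    if not np.all(np.isfinite(v)):
        raise ValueError("incomplete design: missing cells")
    normalized = v - v.mean(axis=1, keepdims=True) + v.mean()
    return normalized.std(axis=0, ddof=1) / math.sqrt(v.shape[0])
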