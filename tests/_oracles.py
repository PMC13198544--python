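"""Independent reference implementations used as test oracles.

Everything here is deliberately written in a different style from the package
(naive nested loops, scipy densities, direct formulas) so that agreement is
evidence of correctness rather than shared code.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate, stats
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# brute-force trial likelihood
# ---------------------------------------------------------------------------

def _vm_pdf_deg(x_deg, mu_deg, kappa):
    """von Mises density per radian at angle x about mu (degrees in)."""
    return stats.vonmises.pdf(math.radians(x_deg), kappa, loc=math.radians(mu_deg))


def _object_guess_configs(g_feat, g_obj, dims):
    """All (flags, probability) guess outcomes for one object.

    ``dims`` are the guessable dimensions (0 colour, 1 location).  The object
    route sets every guessable flag at once; otherwise each guessable
    dimension is an independent feature-guess Bernoulli.
    """
    configs = []
    obj_flags = [d in dims for d in (0, 1)]
    configs.append((tuple(obj_flags), g_obj))
    for feat_flags in itertools.product([False, True], repeat=len(dims)):
        flags = [False, False]
        prob = 1.0 - g_obj
        for d, f in zip(dims, feat_flags):
            flags[d] = f
            prob *= g_feat if f else (1.0 - g_feat)
        configs.append((tuple(flags), prob))
    return configs


def brute_trial_loglik(trial, params) -> float:
    """Exhaustive enumeration of the marginal response likelihood."""
    cond = trial.condition
    stim_c = trial.stimuli.colours
    stim_l = trial.stimuli.locations
    if cond.probe == "cued_by_colour":
        dims = (1,)
        err_dim = 1
    elif cond.probe == "cued_by_location":
        dims = (0,)
        err_dim = 0
    else:
        dims = (0, 1)
        err_dim = 0

    # precompute densities: response slot s against stimulus feature k
    vm_c = [[_vm_pdf_deg(trial.response_colours[s], stim_c[k], params.kappa_colour)
             for k in range(3)] for s in range(3)]
    vm_l = [[_vm_pdf_deg(trial.response_locations[s], stim_l[k], params.kappa_location)
             for k in range(3)] for s in range(3)]
    uniform = 1.0 / (2.0 * math.pi)

    if cond.is_cued:
        orders = [(tuple(trial.cue_selection), 1.0)]
    else:
        orders = [
            (perm, params.order_weights[i])
            for i, perm in enumerate(itertools.permutations((0, 1, 2)))
        ]

    structures = [("none", None, [0, 1, 2], 1 - params.p_swap - params.p_cyclic_swap)]
    for pair in ((0, 1), (0, 2), (1, 2)):
        src = [0, 1, 2]
        src[pair[0]], src[pair[1]] = src[pair[1]], src[pair[0]]
        structures.append(("swap", pair, src, params.p_swap / 3.0))
    for d in (1, 2):
        structures.append(
            ("cyclic", None, [(o + d) % 3 for o in range(3)], params.p_cyclic_swap / 2.0)
        )

    total = 0.0
    for order, w_order in orders:
        if w_order == 0.0:
            continue
        slot_of = {o: s for s, o in enumerate(order)}
        for kind, pair, err_src, p_err in structures:
            if p_err <= 0.0:
                continue
            per_object = []
            for o in range(3):
                if kind == "none":
                    g_feat, g_obj = params.g_feature, params.g_object
                elif kind == "cyclic":
                    g_feat, g_obj = params.g_feat_cyclic, params.g_obj_cyclic
                elif o in pair:
                    g_feat, g_obj = params.g_feat_swap_swp, params.g_obj_swap_swp
                else:
                    g_feat, g_obj = params.g_feat_swap_non, params.g_obj_swap_non
                s = slot_of[o]
                acc = 0.0
                for flags, p_cfg in _object_guess_configs(g_feat, g_obj, dims):
                    if p_cfg == 0.0:
                        continue
                    dens = 1.0
                    if 0 in dims:
                        src = err_src[o] if err_dim == 0 else o
                        dens *= uniform if flags[0] else vm_c[s][src]
                    if 1 in dims:
                        src = err_src[o] if err_dim == 1 else o
                        dens *= uniform if flags[1] else vm_l[s][src]
                    acc += p_cfg * dens
                per_object.append(acc)
            total += w_order * p_err * per_object[0] * per_object[1] * per_object[2]
    return math.log(total)


# ---------------------------------------------------------------------------
# WAIC
# ---------------------------------------------------------------------------

def waic_oracle(ll: np.ndarray) -> float:
    """Two-line WAIC: -2 (lppd - p) with the variance penalty."""
    lppd = np.sum(np.log(np.mean(np.exp(ll), axis=1)))
    return float(-2.0 * (lppd - np.sum(np.var(ll, axis=1))))


# ---------------------------------------------------------------------------
# JZS Bayes factor via Rouder's g-integral (distinct from the package's
# noncentral-t x Cauchy quadrature)
# ---------------------------------------------------------------------------

def jzs_bf_oracle(t: float, n_eff: float, nu: int, r: float) -> float:
    def integrand(g):
        return (
            (1.0 + n_eff * g) ** -0.5
            * (1.0 + t**2 / ((1.0 + n_eff * g) * nu)) ** (-(nu + 1) / 2.0)
            * (r**2 / 2.0) ** 0.5
            / math.gamma(0.5)
            * g ** (-1.5)
            * math.exp(-(r**2) / (2.0 * g))
        )

    num, _ = integrate.quad(integrand, 0.0, np.inf, limit=300)
    den = (1.0 + t**2 / nu) ** (-(nu + 1) / 2.0)
    return num / den


# ---------------------------------------------------------------------------
# correlation Bayes factor by dense trapezoid over the full r-density
# ---------------------------------------------------------------------------

def _log_r_density(r: float, rho: np.ndarray, n: int) -> np.ndarray:
    from scipy.special import hyp2f1

    return (
        math.log(n - 2)
        + gammaln(n - 1)
        - 0.5 * math.log(2 * math.pi)
        - gammaln(n - 0.5)
        + ((n - 1) / 2.0) * np.log1p(-np.square(rho))
        + ((n - 4) / 2.0) * math.log1p(-(r**2))
        + (1.5 - n) * np.log1p(-rho * r)
        + np.log(hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0))
    )


def corr_bf_oracle(r: float, n: int, width: float, m: int = 200001) -> float:
    from scipy.special import betaln

    rho = np.linspace(-1.0 + 1e-9, 1.0 - 1e-9, m)
    a = 1.0 / width
    log_prior = (
        (a - 1.0) * np.log1p(-np.square(rho))
        - (2.0 * a - 1.0) * math.log(2.0)
        - betaln(a, a)
    )
    dens = np.exp(_log_r_density(r, rho, n) + log_prior)
    marg = np.trapezoid(dens, rho)
    return float(marg / math.exp(_log_r_density(r, np.array([0.0]), n)[0]))
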