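"""Exact marginal likelihood of the six-dimensional response vector.

For a whole-report trial the observed data are three (colour, location)
response pairs.  The likelihood marginalizes over every latent state of the
generative model: the report-order permutation (six orders, categorical), the
error structure (veridical, one of three symmetric swaps, one of two cyclic
rotations) and the per-object guess configuration.  Discrete states are summed
out exactly; nothing is approximated.

Two routes are provided:

* :func:`enumerate_latents` + :func:`state_loglik` — the explicit enumeration,
  a few thousand states, used for trial classification and as a transparent
  reference.
* :func:`trial_loglik` / :class:`DatasetLikelihood` — an algebraically
  identical factorized evaluation.  Conditional on permutation and error
  structure the six response features are independent across objects, so the
  guess layer is summed per object (four flag configurations) instead of
  enumerating the cross product; this reduces the work per trial to
  6 x 6 outer states times a 3 x 4 inner mixture and vectorizes over trials.

In cued trials the observer's cue selections are data: they fix the
slot-to-object mapping, so no permutation is marginalized, and the cue
dimension is a forced choice among the displayed features contributing a
constant (log 1) when consistent with the state and ``-inf`` otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import i0e

from misbind.core import (
    IDENTITY_PERMUTATION,
    PERMUTATIONS,
    Condition,
    deg2rad,
)
from misbind.forward import (
    LatentTrialState,
    ModelParams,
    TrialRecord,
    _CYCLIC_DIRECTIONS,
    _SWAP_PAIRS,
    _error_dim_for,
    _guessable_dims,
    latent_to_assignment,
)

__all__ = [
    "von_mises_logpdf",
    "enumerate_latents",
    "state_loglik",
    "trial_loglik",
    "pointwise_loglik",
    "response_loglik_grid",
    "DatasetLikelihood",
]

_LOG_2PI = math.log(2.0 * math.pi)
_LOG_UNIFORM = -_LOG_2PI  # uniform density on the circle, per radian


def von_mises_logpdf(x, mu, kappa):
    """Log von Mises density (per radian) of angle ``x`` (degrees) about ``mu``.

    ``kappa = 0`` gives the uniform density ``1/2pi``.  Uses the
    exponentially scaled Bessel function for stability at large ``kappa``.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    cos_d = np.cos(deg2rad(x) - deg2rad(mu))
    out = kappa * (cos_d - 1.0) - _LOG_2PI - np.log(i0e(kappa))
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# explicit enumeration
# ---------------------------------------------------------------------------

# per-object guess categories: (colour flag, location flag, via object guess)
_GUESS_CATEGORIES = (
    (False, False, False),
    (True, False, False),
    (False, True, False),
    (True, True, False),   # two independent feature guesses
    (True, True, True),    # one object-level guess
)

# with a single guessable dimension (cued trials) the object guess can only
# mark the reported dimension
_GUESS_CATEGORIES_COLOUR_ONLY = (
    (False, False, False),
    (True, False, False),
    (True, False, True),
)
_GUESS_CATEGORIES_LOCATION_ONLY = (
    (False, False, False),
    (False, True, False),
    (False, True, True),
)


def _categories_for(dims) -> tuple:
    if dims == (0, 1):
        return _GUESS_CATEGORIES
    return _GUESS_CATEGORIES_COLOUR_ONLY if dims == (0,) else _GUESS_CATEGORIES_LOCATION_ONLY


def _category_logprob(cat, g_feat: float, g_obj: float, dims) -> float:
    """Log prior of one per-object guess category, restricted to guessable dims."""
    fc, fl, via_obj = cat
    flags = {0: fc, 1: fl}
    # categories that set a flag on a non-guessable dimension do not exist
    for d in (0, 1):
        if d not in dims and flags[d]:
            return -np.inf
    if via_obj:
        if not all(flags[d] for d in dims):
            return -np.inf
        return math.log(g_obj) if g_obj > 0 else -np.inf
    logp = math.log1p(-g_obj) if g_obj < 1 else -np.inf
    for d in dims:
        p = g_feat if flags[d] else 1.0 - g_feat
        logp += math.log(p) if p > 0 else -np.inf
    return logp


def _error_structures(params: ModelParams):
    """(kind, pair, direction, log prior) over the 6 error structures."""
    p_none = 1.0 - params.p_swap - params.p_cyclic_swap
    out = [("none", None, None, math.log(p_none) if p_none > 0 else -np.inf)]
    lp_swap = math.log(params.p_swap / 3.0) if params.p_swap > 0 else -np.inf
    for pair in _SWAP_PAIRS:
        out.append(("swap", pair, None, lp_swap))
    lp_cyc = math.log(params.p_cyclic_swap / 2.0) if params.p_cyclic_swap > 0 else -np.inf
    for d in _CYCLIC_DIRECTIONS:
        out.append(("cyclic", None, d, lp_cyc))
    return out


def enumerate_latents(
    params: ModelParams, condition: Condition
) -> list[tuple[LatentTrialState, float]]:
    """Full latent support with prior probabilities (summing to one).

    Uncued conditions enumerate all six report permutations; cued conditions
    carry the identity permutation as a placeholder for the observed
    cue-selection mapping.  States whose prior is zero are omitted.
    """
    dims = _guessable_dims(condition)
    err_dim = _error_dim_for(condition)
    if condition.is_cued:
        perms = [(IDENTITY_PERMUTATION, 0.0)]
    else:
        w = np.asarray(params.order_weights, dtype=float)
        perms = [
            (PERMUTATIONS[i], math.log(w[i]))
            for i in range(6)
            if w[i] > 0
        ]

    states = []
    for kind, pair, direction, lp_err in _error_structures(params):
        if not np.isfinite(lp_err):
            continue
        categories = _categories_for(dims)
        for cats in itertools.product(range(len(categories)), repeat=3):
            lp_guess = 0.0
            flags, via_obj = [], []
            for o in range(3):
                cat = categories[cats[o]]
                g_feat, g_obj = params.guess_rates(kind, pair, o)
                lp = _category_logprob(cat, g_feat, g_obj, dims)
                lp_guess += lp
                flags.append((cat[0], cat[1]))
                via_obj.append(cat[2])
            if not np.isfinite(lp_guess):
                continue
            for perm, lp_perm in perms:
                states.append(
                    (
                        LatentTrialState(
                            permutation=perm,
                            error_kind=kind,
                            swap_pair=pair,
                            cyclic_direction=direction,
                            guess_flags=tuple(flags),
                            object_guess=tuple(via_obj),
                            error_dim=err_dim,
                        ),
                        math.exp(lp_perm + lp_err + lp_guess),
                    )
                )
    return states


def state_loglik(
    trial: TrialRecord, state: LatentTrialState, params: ModelParams
) -> float:
    """Log density of the trial's responses under one fixed latent state."""
    cond = trial.condition
    assignment = latent_to_assignment(state)
    if cond.is_cued:
        # the observed cue selections fix the slot->object mapping; a state
        # claiming a different mapping is inconsistent with the data.
        if state.permutation != IDENTITY_PERMUTATION:
            return -np.inf
        slot_of = {o: s for s, o in enumerate(trial.cue_selection)}
    else:
        slot_of = {o: state.permutation.slot_of(o) for o in range(3)}

    total = 0.0
    for o in range(3):
        s = slot_of[o]
        if cond.report_dim in ("both", "colour"):
            src = assignment.colour_src[o]
            if src == 0:
                total += _LOG_UNIFORM
            else:
                total += von_mises_logpdf(
                    trial.response_colours[s],
                    trial.stimuli.colours[src - 1],
                    params.kappa_colour,
                )
        if cond.report_dim in ("both", "location"):
            src = assignment.location_src[o]
            if src == 0:
                total += _LOG_UNIFORM
            else:
                total += von_mises_logpdf(
                    trial.response_locations[s],
                    trial.stimuli.locations[src - 1],
                    params.kappa_location,
                )
    return float(total)


# ---------------------------------------------------------------------------
# factorized fast path
# ---------------------------------------------------------------------------

# error-structure tables (indices into guess classes 0=none,1=swap member,
# 2=swap bystander, 3=cyclic), and 0-based source of each object's feature on
# the error dimension.
_ERR_SRC = np.empty((6, 3), dtype=np.intp)
_ERR_CLS = np.empty((6, 3), dtype=np.intp)
_ERR_SRC[0] = (0, 1, 2)
_ERR_CLS[0] = 0
for _i, _pair in enumerate(_SWAP_PAIRS):
    src = [0, 1, 2]
    src[_pair[0]], src[_pair[1]] = src[_pair[1]], src[_pair[0]]
    _ERR_SRC[1 + _i] = src
    _ERR_CLS[1 + _i] = [1 if _o in _pair else 2 for _o in range(3)]
for _i, _d in enumerate(_CYCLIC_DIRECTIONS):
    _ERR_SRC[4 + _i] = [(_o + _d) % 3 for _o in range(3)]
    _ERR_CLS[4 + _i] = 3


def _class_rates(params: ModelParams) -> list[tuple[float, float]]:
    return [
        (params.g_feature, params.g_object),
        (params.g_feat_swap_swp, params.g_obj_swap_swp),
        (params.g_feat_swap_non, params.g_obj_swap_non),
        (params.g_feat_cyclic, params.g_obj_cyclic),
    ]


def _err_priors(params: ModelParams) -> np.ndarray:
    """Prior of the 6 error structures (veridical, 3 swaps, 2 rotations)."""
    p_none = 1.0 - params.p_swap - params.p_cyclic_swap
    return np.array(
        [max(p_none, 0.0)]
        + [params.p_swap / 3.0] * 3
        + [params.p_cyclic_swap / 2.0] * 2
    )


def _log_vm_norm(kappa: float) -> float:
    return _LOG_2PI + math.log(i0e(kappa)) + kappa


# precomputed gather indices for the 36 (permutation x error) outer states
_PERM_INV = np.array([p.inverse().mapping for p in PERMUTATIONS], dtype=np.intp)
_OUTER_PERM, _OUTER_ERR = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
_OUTER_PERM = _OUTER_PERM.ravel()  # (36,)
_OUTER_ERR = _OUTER_ERR.ravel()
_OBJ = np.arange(3)
_G_SLOT = _PERM_INV[_OUTER_PERM]          # (36, 3) slot of object o
_G_SRC = _ERR_SRC[_OUTER_ERR]             # (36, 3) colour source of object o
_G_CLS = _ERR_CLS[_OUTER_ERR]             # (36, 3) guess class of object o


class _ScaledVmCache:
    """Scaled von Mises emission factors for one deviation matrix.

    For a matrix of cosines, returns ``exp(log_vm - m)`` together with the
    per-trial offset ``m`` and the uniform density scaled by the same offset,
    so downstream products of three such factors stay inside float range.
    The last few kappa values are memoized: most sampler updates touch only
    mixture weights, not concentrations.
    """

    def __init__(self, cos_mat: np.ndarray, max_entries: int = 4):
        self._cos = cos_mat  # (n, a, b)
        self._cache: dict[float, tuple] = {}
        self._max = max_entries

    def get(self, kappa: float):
        hit = self._cache.get(kappa)
        if hit is not None:
            return hit
        lvm = kappa * self._cos - _log_vm_norm(kappa)
        m = lvm.max(axis=(1, 2))
        np.maximum(m, _LOG_UNIFORM, out=m)  # keep scaled factors <= 1
        e = np.exp(lvm - m[:, None, None])
        u = np.exp(_LOG_UNIFORM - m)
        if len(self._cache) >= self._max:
            self._cache.pop(next(iter(self._cache)))
        self._cache[kappa] = (e, u, m)
        return e, u, m


class _UncuedBlock:
    """Vectorized likelihood of a set of whole-report trials.

    Works in scaled linear space: conditional on permutation and error
    structure, the per-object guess mixture is a 4-term sum of products of
    one colour factor and one location factor; the per-trial log offsets are
    added back at the end.
    """

    def __init__(self, resp_c, resp_l, stim_c, stim_l):
        # cos deviation: response slot s vs stimulus k / (location: object o
        # first so the o axis lines up with the mixture)
        cos_c = np.cos(deg2rad(resp_c[:, :, None] - stim_c[:, None, :]))  # (n,s,k)
        cos_l = np.cos(deg2rad(resp_l[:, :, None] - stim_l[:, None, :]))
        self._col = _ScaledVmCache(cos_c)
        self._loc = _ScaledVmCache(np.transpose(cos_l, (0, 2, 1)))       # (n,o,s)
        self.n = resp_c.shape[0]

    @classmethod
    def from_trials(cls, trials: list[TrialRecord]) -> "_UncuedBlock":
        return cls(
            np.array([t.response_colours for t in trials]),
            np.array([t.response_locations for t in trials]),
            np.array([t.stimuli.colours for t in trials]),
            np.array([t.stimuli.locations for t in trials]),
        )

    def loglik(self, params: ModelParams) -> np.ndarray:
        ec, uc, mc = self._col.get(params.kappa_colour)   # ec: (n, s, k)
        el, ul, ml = self._loc.get(params.kappa_location) # el: (n, o, s)
        ecb = ec[:, None, :, :]                           # (n, 1, s, k)
        elb = el[:, :, :, None]                           # (n, o, s, 1)
        ucb = uc[:, None, None, None]
        ulb = ul[:, None, None, None]
        F = np.empty((4, self.n, 3, 3, 3))
        for cls, (g_feat, g_obj) in enumerate(_class_rates(params)):
            p00 = (1 - g_obj) * (1 - g_feat) ** 2
            p10 = (1 - g_obj) * g_feat * (1 - g_feat)
            p11 = g_obj + (1 - g_obj) * g_feat**2
            # colour factor (vm source k or guess) x location factor
            F[cls] = elb * (p00 * ecb + p10 * ucb) + ulb * (p10 * ecb + p11 * ucb)
        # gather the 36 outer states: (36, 3) advanced indexing -> (36, 3, n)
        contrib = F[_G_CLS, :, _OBJ[None, :], _G_SLOT, _G_SRC]
        per_state = contrib.prod(axis=1)                  # (36, n)
        w = np.asarray(params.order_weights, dtype=float)
        prior = w[_OUTER_PERM] * _err_priors(params)[_OUTER_ERR]
        total = prior @ per_state
        with np.errstate(divide="ignore"):
            return np.log(total) + 3.0 * (mc + ml)


class _CuedBlock:
    """Vectorized likelihood of cued trials sharing one probe type."""

    def __init__(self, resp_by_obj, stim, report_is_colour: bool):
        self.report_is_colour = report_is_colour
        # report response for object o vs stimulus feature k
        self._rep = _ScaledVmCache(
            np.cos(deg2rad(resp_by_obj[:, :, None] - stim[:, None, :]))
        )
        self.n = resp_by_obj.shape[0]

    @classmethod
    def from_trials(cls, trials: list[TrialRecord], probe: str) -> "_CuedBlock":
        report_is_colour = probe == "cued_by_location"
        resp = np.array(
            [
                t.response_colours if report_is_colour else t.response_locations
                for t in trials
            ]
        )
        stim = np.array(
            [
                t.stimuli.colours if report_is_colour else t.stimuli.locations
                for t in trials
            ]
        )
        slot_of = np.array(
            [[t.cue_selection.index(o) for o in range(3)] for t in trials],
            dtype=np.intp,
        )
        return cls(np.take_along_axis(resp, slot_of, axis=1), stim, report_is_colour)

    def loglik(self, params: ModelParams) -> np.ndarray:
        kappa = params.kappa_colour if self.report_is_colour else params.kappa_location
        er, ur, mr = self._rep.get(kappa)                 # (n, o, k)
        F = np.empty((4, self.n, 3, 3))
        for cls, (g_feat, g_obj) in enumerate(_class_rates(params)):
            pg = g_obj + (1 - g_obj) * g_feat
            F[cls] = (1.0 - pg) * er + pg * ur[:, None, None]
        contrib = F[_ERR_CLS, :, _OBJ[None, :], _ERR_SRC]          # (6, 3, n)
        per_state = contrib.prod(axis=1)
        total = _err_priors(params) @ per_state
        with np.errstate(divide="ignore"):
            return np.log(total) + 3.0 * mr


class DatasetLikelihood:
    """Precomputed fast likelihood for the trials of one subject x group.

    Splits trials into whole-report and cued blocks and returns, via
    :meth:`loglik`, the per-trial log marginal likelihoods in the original
    trial order.
    """

    def __init__(self, trials: list[TrialRecord]):
        self.n = len(trials)
        self._blocks: list[tuple[np.ndarray, object]] = []
        by_kind: dict[str, list[int]] = {}
        for i, t in enumerate(trials):
            key = t.condition.probe if t.condition.is_cued else "uncued"
            by_kind.setdefault(key, []).append(i)
        for key, idx in by_kind.items():
            sub = [trials[i] for i in idx]
            block = (
                _UncuedBlock.from_trials(sub)
                if key == "uncued"
                else _CuedBlock.from_trials(sub, key)
            )
            self._blocks.append((np.asarray(idx, dtype=np.intp), block))

    def loglik(self, params: ModelParams) -> np.ndarray:
        out = np.empty(self.n)
        for idx, block in self._blocks:
            out[idx] = block.loglik(params)
        return out


def response_loglik_grid(
    stimuli,
    params: ModelParams,
    condition: Condition,
    resp_colours: np.ndarray,
    resp_locations: np.ndarray,
) -> np.ndarray:
    """Log marginal likelihood of many candidate response vectors (degrees)
    to one whole-report stimulus array.

    Useful for plotting the modeled six-dimensional response surface and for
    numerically integrating it.  ``resp_colours`` and ``resp_locations`` are
    (n, 3) arrays of response angles in report-slot order.
    """
    if condition.is_cued:
        raise ValueError("grid evaluation is defined for whole-report trials")
    resp_colours = np.asarray(resp_colours, dtype=float)
    resp_locations = np.asarray(resp_locations, dtype=float)
    n = resp_colours.shape[0]
    stim_c = np.broadcast_to(np.asarray(stimuli.colours, dtype=float), (n, 3))
    stim_l = np.broadcast_to(np.asarray(stimuli.locations, dtype=float), (n, 3))
    return _UncuedBlock(resp_colours, resp_locations, stim_c, stim_l).loglik(params)


def trial_loglik(trial: TrialRecord, params: ModelParams) -> float:
    """Log marginal likelihood of one trial (all latent states summed out)."""
    return float(DatasetLikelihood([trial]).loglik(params)[0])


def pointwise_loglik(
    dataset: list[TrialRecord],
    draws: dict[tuple[int, str], list[ModelParams]],
) -> np.ndarray:
    """Matrix (trials x draws) of log marginal likelihoods.

    ``draws[(subject, param_group)]`` is the sequence of posterior parameter
    draws for that subject and condition group; all sequences must have the
    same length and cover every subject/group present in the data.
    """
    groups: dict[tuple[int, str], list[int]] = {}
    for i, t in enumerate(dataset):
        groups.setdefault((t.subject, t.condition.param_group), []).append(i)
    missing = [k for k in groups if k not in draws]
    if missing:
        raise KeyError(f"no posterior draws for subject/group(s) {missing}")
    n_draws = {len(v) for v in draws.values()}
    if len(n_draws) != 1:
        raise ValueError("all draw sequences must have equal length")
    S = n_draws.pop()
    out = np.empty((len(dataset), S))
    for key, idx in groups.items():
        dl = DatasetLikelihood([dataset[i] for i in idx])
        for s, params in enumerate(draws[key]):
            out[np.asarray(idx), s] = dl.loglik(params)
    return out
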