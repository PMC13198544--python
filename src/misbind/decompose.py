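"""Headline quantities: swap rates, error composition, per-trial error types.

A "swap trial" covers three observationally distinct outcomes depending on the
guess layer within the swapped pair:

* *symmetric misbinding* — the exchange survives on both sides: neither
  swapped object has an object guess or a feature guess on the swapped
  dimension;
* *asymmetric misattribution (object guess)* — at least one swapped object is
  guessed wholesale;
* *asymmetric misattribution (feature guess)* — no object guess, but the
  swapped-dimension feature of at least one swapped object is guessed.

Guesses on the bystander object do not change a swap's label.  The closed-form
composition follows from total probability over the two swapped objects; it is
checked elsewhere against Monte Carlo simulation of the latent layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from misbind.core import circ_dist, deg2rad
from misbind.forward import ModelParams, TrialRecord, latent_to_assignment
from misbind.likelihood import _log_vm_norm, enumerate_latents

__all__ = [
    "ErrorComposition",
    "CLASS_NAMES",
    "swap_composition",
    "classify_trials",
    "classify_state",
    "absolute_error",
    "report_order_bias",
]

#: Trial error classes, mutually exclusive and exhaustive.
CLASS_NAMES = (
    "correct",
    "symmetric_swap",
    "asym_feature",
    "asym_object",
    "cyclic",
    "guess",
)

_LOG_UNIFORM = -math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ErrorComposition:
    """Overall error rates and the composition of swap trials."""

    p_swap_overall: float
    frac_symmetric: float
    frac_asym_feature: float
    frac_asym_object: float
    p_cyclic: float


def swap_composition(params: ModelParams) -> ErrorComposition:
    """Closed-form symmetric/asymmetric decomposition of swap trials.

    Conditional on a swap, each swapped object independently escapes both the
    object guess (rate ``g_obj_swap_swp``) and the swapped-dimension feature
    guess (rate ``g_feat_swap_swp``) with probability ``(1-Go)(1-Gf)``; the
    swap stays symmetric only if both escape.
    """
    g_f = params.g_feat_swap_swp
    g_o = params.g_obj_swap_swp
    sym = ((1.0 - g_o) * (1.0 - g_f)) ** 2
    asym_obj = 1.0 - (1.0 - g_o) ** 2
    asym_feat = (1.0 - g_o) ** 2 * (1.0 - (1.0 - g_f) ** 2)
    return ErrorComposition(
        p_swap_overall=params.p_swap,
        frac_symmetric=sym,
        frac_asym_feature=asym_feat,
        frac_asym_object=asym_obj,
        p_cyclic=params.p_cyclic_swap,
    )


def classify_state(state) -> str:
    """Error-type label of one latent state (object guess dominates)."""
    if state.error_kind == "cyclic":
        return "cyclic"
    if state.error_kind == "swap":
        dim = 0 if state.error_dim == "colour" else 1
        pair = state.swap_pair
        if any(state.object_guess[o] for o in pair):
            return "asym_object"
        if any(state.guess_flags[o][dim] for o in pair):
            return "asym_feature"
        return "symmetric_swap"
    if any(any(f) for f in state.guess_flags):
        return "guess"
    return "correct"


def _resolve_params(fit, subject: int, group: str) -> ModelParams:
    if isinstance(fit, ModelParams):
        return fit
    if hasattr(fit, "subject_mean_params"):
        return fit.subject_mean_params(subject, group)
    try:
        return fit[(subject, group)]
    except (TypeError, KeyError) as exc:
        raise KeyError(
            f"cannot resolve parameters for subject {subject}, group {group}"
        ) from exc


def _classify_block(trials: list[TrialRecord], params: ModelParams) -> np.ndarray:
    """Posterior class probabilities, vectorized over trials of one condition."""
    cond = trials[0].condition
    states = enumerate_latents(params, cond)

    resp_c = np.array([t.response_colours for t in trials])
    resp_l = np.array([t.response_locations for t in trials])
    stim_c = np.array([t.stimuli.colours for t in trials])
    stim_l = np.array([t.stimuli.locations for t in trials])
    lvm_c = params.kappa_colour * np.cos(
        deg2rad(resp_c[:, :, None] - stim_c[:, None, :])
    ) - _log_vm_norm(params.kappa_colour)
    lvm_l = params.kappa_location * np.cos(
        deg2rad(resp_l[:, :, None] - stim_l[:, None, :])
    ) - _log_vm_norm(params.kappa_location)

    if cond.is_cued:
        slot_of = np.array(
            [[t.cue_selection.index(o) for o in range(3)] for t in trials],
            dtype=np.intp,
        )
    else:
        slot_of = None

    n = len(trials)
    per_class: dict[str, list[np.ndarray]] = {c: [] for c in CLASS_NAMES}
    rows = np.arange(n)
    for state, prior in states:
        assignment = latent_to_assignment(state)
        ll = np.full(n, math.log(prior))
        for o in range(3):
            s = (
                slot_of[:, o]
                if slot_of is not None
                else state.permutation.slot_of(o)
            )
            if cond.report_dim in ("both", "colour"):
                src = assignment.colour_src[o]
                ll += _LOG_UNIFORM if src == 0 else lvm_c[rows, s, src - 1]
            if cond.report_dim in ("both", "location"):
                src = assignment.location_src[o]
                ll += _LOG_UNIFORM if src == 0 else lvm_l[rows, s, src - 1]
        per_class[classify_state(state)].append(ll)

    out = np.full((n, len(CLASS_NAMES)), -np.inf)
    for j, cname in enumerate(CLASS_NAMES):
        if per_class[cname]:
            out[:, j] = logsumexp(np.stack(per_class[cname]), axis=0)
    out -= logsumexp(out, axis=1, keepdims=True)
    return np.exp(out)


def classify_trials(dataset: list[TrialRecord], fit) -> pd.DataFrame:
    """Posterior probability of each error class for every trial.

    ``fit`` may be a fit result (parameters evaluated at per-subject posterior
    means — flagged in ``df.attrs['evaluated_at']``), a mapping
    ``(subject, param_group) -> ModelParams``, or a single ``ModelParams``
    applied to every trial.  Rows sum to one.
    """
    groups: dict[tuple[int, str, str], list[int]] = {}
    for i, t in enumerate(dataset):
        key = (t.subject, t.condition.param_group, t.condition.probe)
        groups.setdefault(key, []).append(i)

    probs = np.empty((len(dataset), len(CLASS_NAMES)))
    for (subject, group, _probe), idx in groups.items():
        params = _resolve_params(fit, subject, group)
        probs[np.asarray(idx)] = _classify_block([dataset[i] for i in idx], params)

    df = pd.DataFrame(probs, columns=list(CLASS_NAMES))
    df.insert(0, "trial", [t.trial_id if t.trial_id is not None else i
                           for i, t in enumerate(dataset)])
    df.insert(1, "subject", [t.subject for t in dataset])
    df.insert(2, "condition", [t.condition.probe for t in dataset])
    df.attrs["evaluated_at"] = (
        "posterior_means" if hasattr(fit, "subject_mean_params") else "fixed_params"
    )
    return df


def absolute_error(dataset: list[TrialRecord]) -> pd.DataFrame:
    """Unsigned angular error per trial, slot and dimension (identity mapping).

    The raw recall error: each response slot is compared with the same-slot
    stimulus feature, ignoring report order and latent structure.  Values are
    in [0, 180] degrees.
    """
    rows = []
    for i, t in enumerate(dataset):
        tid = t.trial_id if t.trial_id is not None else i
        for s in range(3):
            rows.append(
                (tid, t.subject, t.condition.probe, s, "colour",
                 abs(circ_dist(t.response_colours[s], t.stimuli.colours[s])))
            )
            rows.append(
                (tid, t.subject, t.condition.probe, s, "location",
                 abs(circ_dist(t.response_locations[s], t.stimuli.locations[s])))
            )
    return pd.DataFrame(
        rows, columns=["trial", "subject", "condition", "slot", "dimension", "error"]
    )


def _first_reported_object(trial: TrialRecord) -> int:
    """Object reported at slot 0: ground truth if present, else the object
    whose features are jointly nearest to the slot-0 responses (ties to the
    lowest object index)."""
    if trial.latent is not None:
        return trial.latent.permutation.mapping[0]
    d2 = [
        circ_dist(trial.response_colours[0], trial.stimuli.colours[o]) ** 2
        + circ_dist(trial.response_locations[0], trial.stimuli.locations[o]) ** 2
        for o in range(3)
    ]
    return int(np.argmin(d2))


def report_order_bias(
    dataset: list[TrialRecord], up_angle: float = 90.0
) -> dict[str, float]:
    """Fraction of uncued trials whose first-reported object is the topmost
    (location nearest ``up_angle``) or leftmost (nearest ``up_angle + 90``).

    The screen convention is that 90 degrees points up (mathematical angles,
    counter-clockwise from the positive x-axis), configurable via
    ``up_angle``.
    """
    uncued = [t for t in dataset if not t.condition.is_cued]
    if not uncued:
        raise ValueError("no uncued trials in dataset")
    top_hits = left_hits = 0
    for t in uncued:
        first = _first_reported_object(t)
        locs = t.stimuli.locations
        topmost = int(np.argmin([abs(circ_dist(l, up_angle)) for l in locs]))
        leftmost = int(np.argmin([abs(circ_dist(l, up_angle + 90.0)) for l in locs]))
        top_hits += first == topmost
        left_hits += first == leftmost
    n = len(uncued)
    return {
        "frac_topmost_first": top_hits / n,
        "frac_leftmost_first": left_hits / n,
    }
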