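"""Generative model of whole-report responses; doubles as the data simulator.

A trial unfolds in three stages (all latent except the final responses):

1. *Report order.*  In uncued (whole-report) trials the three response slots
   map onto the three objects through a permutation drawn from a categorical
   distribution over all six orders (``order_weights``).  In cued trials the
   observer's cue selections fix the mapping, so the order is uniform and is
   observed as data.
2. *Error structure.*  With probability ``p_swap`` two objects reciprocally
   exchange their feature on one dimension (a symmetric swap); with
   probability ``p_cyclic_swap`` all three features on that dimension rotate
   (a cyclic swap); otherwise the mapping is veridical.  Swaps are represented
   canonically as exchanges on the colour dimension in whole report (a colour
   swap and the mirror-image location swap are observationally equivalent for
   two-feature objects) and on the freely reported dimension in cued trials.
3. *Guessing.*  Each object may lose both features jointly (an object guess,
   one Bernoulli draw) or individual features (independent feature-guess
   Bernoullis).  The rates depend on the error structure: baseline
   ``g_feature``/``g_object`` on veridical trials, separate rates for the
   swapped pair (``*_swap_swp``) versus the unaffected object (``*_swap_non``)
   on swap trials, and ``*_cyclic`` rates on cyclic trials.  A guessed feature
   is reported uniformly on the circle; everything else is reported with von
   Mises noise around the assigned source feature (concentration
   ``kappa_colour`` / ``kappa_location``).

A swap accompanied by a guess within the swapped pair is an *asymmetric
misattribution*: the exchange survives on one side only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from misbind.core import (
    PERMUTATIONS,
    Condition,
    Permutation,
    wrap_angle,
)
from misbind.taskgen import DesignSpec, StimulusArray, make_design

__all__ = [
    "ModelParams",
    "LatentTrialState",
    "AssignmentVector",
    "TrialRecord",
    "PARAM_NAMES",
    "sample_latent_state",
    "latent_to_assignment",
    "emit_responses",
    "simulate_trial",
    "simulate_dataset",
]

#: The 13 free parameters, in their canonical order.
PARAM_NAMES = (
    "kappa_colour",
    "kappa_location",
    "p_swap",
    "p_cyclic_swap",
    "g_feature",
    "g_object",
    "g_feat_swap_non",
    "g_feat_swap_swp",
    "g_obj_swap_non",
    "g_obj_swap_swp",
    "g_feat_cyclic",
    "g_obj_cyclic",
    "order_weights",
)

_SWAP_PAIRS = ((0, 1), (0, 2), (1, 2))
_CYCLIC_DIRECTIONS = (1, 2)  # colour_src[o] = (o + d) % 3


@dataclass(frozen=True)
class ModelParams:
    """The 13 free parameters of one subject in one condition group."""

    kappa_colour: float
    kappa_location: float
    p_swap: float
    p_cyclic_swap: float
    g_feature: float
    g_object: float
    g_feat_swap_non: float
    g_feat_swap_swp: float
    g_obj_swap_non: float
    g_obj_swap_swp: float
    g_feat_cyclic: float
    g_obj_cyclic: float
    order_weights: tuple[float, ...] = (1 / 6,) * 6

    def __post_init__(self) -> None:
        if self.kappa_colour < 0 or self.kappa_location < 0:
            raise ValueError("concentrations must be >= 0")
        for name in PARAM_NAMES[2:-1]:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_swap + self.p_cyclic_swap > 1.0 + 1e-12:
            raise ValueError("p_swap + p_cyclic_swap exceeds 1")
        w = np.asarray(self.order_weights, dtype=float)
        if w.shape != (6,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("order_weights must be a 6-vector on the simplex")

    @classmethod
    def default(cls) -> "ModelParams":
        """Plausible whole-report parameters for simulation studies.

        Rates are in the range typical of three-item continuous report:
        a few percent of swaps, ~10% feature guessing, ~5% object guessing,
        colour less precisely remembered than location, and a report-order
        preference for the first-encoded object.
        """
        return cls(
            kappa_colour=10.0,
            kappa_location=15.0,
            p_swap=0.06,
            p_cyclic_swap=0.01,
            g_feature=0.12,
            g_object=0.05,
            g_feat_swap_non=0.12,
            g_feat_swap_swp=0.20,
            g_obj_swap_non=0.05,
            g_obj_swap_swp=0.15,
            g_feat_cyclic=0.12,
            g_obj_cyclic=0.05,
            order_weights=(0.40, 0.15, 0.15, 0.10, 0.10, 0.10),
        )

    def guess_rates(self, error_kind: str, swap_pair, obj: int) -> tuple[float, float]:
        """(feature, object) guess rates for ``obj`` given the error structure."""
        if error_kind == "none":
            return self.g_feature, self.g_object
        if error_kind == "cyclic":
            return self.g_feat_cyclic, self.g_obj_cyclic
        if error_kind == "swap":
            if obj in swap_pair:
                return self.g_feat_swap_swp, self.g_obj_swap_swp
            return self.g_feat_swap_non, self.g_obj_swap_non
        raise ValueError(f"unknown error kind {error_kind!r}")


@dataclass(frozen=True)
class LatentTrialState:
    """The hidden error structure of one trial.

    ``guess_flags[o][d]`` marks feature ``d`` (0 = colour, 1 = location) of
    object ``o`` as guessed; ``object_guess[o]`` records whether both flags
    were set jointly by an object-level guess (this distinction carries a
    different prior and a different error-type label, but the same emission).
    ``error_dim`` is the dimension the swap/cyclic structure acts on.
    """

    permutation: Permutation
    error_kind: str  # none | swap | cyclic
    swap_pair: tuple[int, int] | None = None
    cyclic_direction: int | None = None
    guess_flags: tuple[tuple[bool, bool], ...] = ((False, False),) * 3
    object_guess: tuple[bool, bool, bool] = (False, False, False)
    error_dim: str = "colour"

    def __post_init__(self) -> None:
        if self.error_kind not in ("none", "swap", "cyclic"):
            raise ValueError(f"unknown error kind {self.error_kind!r}")
        if (self.swap_pair is not None) != (self.error_kind == "swap"):
            raise ValueError("swap_pair defined iff error_kind == 'swap'")
        if (self.cyclic_direction is not None) != (self.error_kind == "cyclic"):
            raise ValueError("cyclic_direction defined iff error_kind == 'cyclic'")
        if self.error_dim not in ("colour", "location"):
            raise ValueError(f"unknown error dim {self.error_dim!r}")


@dataclass(frozen=True)
class AssignmentVector:
    """Per object, the source of each reported feature (Table-style code).

    Entries are 1-based object indices; 0 means the report is a uniform guess.
    """

    colour_src: tuple[int, int, int]
    location_src: tuple[int, int, int]

    def __post_init__(self) -> None:
        for srcs in (self.colour_src, self.location_src):
            if any(s not in (0, 1, 2, 3) for s in srcs):
                raise ValueError("sources must be in {0, 1, 2, 3}")
            nonzero = [s for s in srcs if s != 0]
            if len(set(nonzero)) != len(nonzero):
                raise ValueError("non-guessed sources must be distinct")


@dataclass(frozen=True)
class TrialRecord:
    """One observed trial: stimuli plus the three (colour, location) reports.

    Response slots are in report order (slot 0 was reported first).  For cued
    trials ``cue_selection[s]`` is the 0-based object whose cue feature was
    chosen at slot ``s``; the cue-dimension response equals that object's
    original feature exactly.
    """

    subject: int
    condition: Condition
    stimuli: StimulusArray
    response_colours: tuple[float, float, float]
    response_locations: tuple[float, float, float]
    cue_selection: tuple[int, int, int] | None = None
    latent: LatentTrialState | None = None
    trial_id: int | None = None

    def __post_init__(self) -> None:
        if self.condition.is_cued:
            if self.cue_selection is None or sorted(self.cue_selection) != [0, 1, 2]:
                raise ValueError("cued trials need a cue_selection permutation")
        elif self.cue_selection is not None:
            raise ValueError("uncued trials carry no cue_selection")


def _error_dim_for(condition: Condition) -> str:
    return "colour" if condition.report_dim in ("both", "colour") else "location"


def _guessable_dims(condition: Condition) -> tuple[int, ...]:
    if condition.report_dim == "both":
        return (0, 1)
    return (0,) if condition.report_dim == "colour" else (1,)


def sample_latent_state(
    params: ModelParams, condition: Condition, rng: np.random.Generator
) -> LatentTrialState:
    """Draw the latent error structure of one trial."""
    if condition.is_cued:
        # the report order is revealed by the cue selections; uniform.
        perm = PERMUTATIONS[rng.integers(6)]
    else:
        perm = PERMUTATIONS[rng.choice(6, p=np.asarray(params.order_weights))]

    u = rng.random()
    if u < params.p_swap:
        kind, pair, direction = "swap", _SWAP_PAIRS[rng.integers(3)], None
    elif u < params.p_swap + params.p_cyclic_swap:
        kind, pair, direction = "cyclic", None, int(_CYCLIC_DIRECTIONS[rng.integers(2)])
    else:
        kind, pair, direction = "none", None, None

    dims = _guessable_dims(condition)
    flags = [[False, False] for _ in range(3)]
    obj_guess = [False, False, False]
    for o in range(3):
        g_feat, g_obj = params.guess_rates(kind, pair, o)
        if rng.random() < g_obj:
            obj_guess[o] = True
            for d in dims:
                flags[o][d] = True
        else:
            for d in dims:
                if rng.random() < g_feat:
                    flags[o][d] = True

    return LatentTrialState(
        permutation=perm,
        error_kind=kind,
        swap_pair=pair,
        cyclic_direction=direction,
        guess_flags=tuple(tuple(f) for f in flags),
        object_guess=tuple(obj_guess),
        error_dim=_error_dim_for(condition),
    )


def _apply_error_structure(latent: LatentTrialState) -> list[int]:
    """1-based source map on the error dimension before guessing."""
    src = [1, 2, 3]
    if latent.error_kind == "swap":
        i, j = latent.swap_pair
        src[i], src[j] = src[j], src[i]
    elif latent.error_kind == "cyclic":
        d = latent.cyclic_direction
        src = [((o + d) % 3) + 1 for o in range(3)]
    return src


def latent_to_assignment(latent: LatentTrialState) -> AssignmentVector:
    """Resolve a latent state to per-feature sources (0 = uniform guess)."""
    err_src = _apply_error_structure(latent)
    identity = [1, 2, 3]
    if latent.error_dim == "colour":
        colour, location = err_src, identity
    else:
        colour, location = identity, err_src
    colour = [0 if latent.guess_flags[o][0] else colour[o] for o in range(3)]
    location = [0 if latent.guess_flags[o][1] else location[o] for o in range(3)]
    return AssignmentVector(tuple(colour), tuple(location))


def _emit_feature(
    stim_angles, src: int, kappa: float, rng: np.random.Generator
) -> float:
    if src == 0:
        return float(rng.uniform(0.0, 360.0))
    mu = math.radians(stim_angles[src - 1])
    return wrap_angle(math.degrees(rng.vonmises(mu, kappa)))


def emit_responses(
    stimuli: StimulusArray,
    assignment: AssignmentVector,
    permutation: Permutation,
    params: ModelParams,
    condition: Condition,
    rng: np.random.Generator,
    *,
    subject: int = 0,
    latent: LatentTrialState | None = None,
    trial_id: int | None = None,
) -> TrialRecord:
    """Emit the six observed angles for one trial.

    Slot ``s`` reports object ``permutation.mapping[s]``.  In cued trials the
    cue dimension is copied exactly from the selected object's original
    feature (it is a forced choice among the displayed features, so it
    carries no memory noise); the other dimension is recalled from memory.
    """
    colours, locations = [], []
    for s in range(3):
        o = permutation.mapping[s]
        if condition.probe == "cued_by_colour":
            colours.append(float(stimuli.colours[o]))
            locations.append(
                _emit_feature(stimuli.locations, assignment.location_src[o],
                              params.kappa_location, rng)
            )
        elif condition.probe == "cued_by_location":
            locations.append(float(stimuli.locations[o]))
            colours.append(
                _emit_feature(stimuli.colours, assignment.colour_src[o],
                              params.kappa_colour, rng)
            )
        else:
            colours.append(
                _emit_feature(stimuli.colours, assignment.colour_src[o],
                              params.kappa_colour, rng)
            )
            locations.append(
                _emit_feature(stimuli.locations, assignment.location_src[o],
                              params.kappa_location, rng)
            )
    cue_sel = tuple(permutation.mapping) if condition.is_cued else None
    return TrialRecord(
        subject=subject,
        condition=condition,
        stimuli=stimuli,
        response_colours=tuple(colours),
        response_locations=tuple(locations),
        cue_selection=cue_sel,
        latent=latent,
        trial_id=trial_id,
    )


def simulate_trial(
    params: ModelParams,
    condition: Condition,
    stimuli: StimulusArray,
    rng: np.random.Generator,
    *,
    subject: int = 0,
    trial_id: int | None = None,
) -> TrialRecord:
    latent = sample_latent_state(params, condition, rng)
    assignment = latent_to_assignment(latent)
    return emit_responses(
        stimuli, assignment, latent.permutation, params, condition, rng,
        subject=subject, latent=latent, trial_id=trial_id,
    )


def simulate_dataset(
    subject_params: dict[int, dict[str, ModelParams]],
    design: DesignSpec,
    seed: int | np.random.SeedSequence = 0,
) -> list[TrialRecord]:
    """Simulate a full experiment with ground-truth latent states retained.

    ``subject_params[subject][param_group]`` must cover every condition in the
    design; both cued probes resolve to the ``"cued"`` group.
    """
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    design_ss, trial_ss = ss.spawn(2)
    shells = make_design(design, np.random.default_rng(design_ss))
    rng = np.random.default_rng(trial_ss)
    records = []
    for trial_id, (subject, condition, stimuli) in enumerate(shells):
        groups = subject_params.get(subject)
        if groups is None or condition.param_group not in groups:
            raise KeyError(
                f"no parameters for subject {subject}, group {condition.param_group}"
            )
        params = groups[condition.param_group]
        records.append(
            simulate_trial(params, condition, stimuli, rng,
                           subject=subject, trial_id=trial_id)
        )
    return records
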