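"""Hierarchical Bayesian estimation of the 13-parameter response model.

Each subject holds one parameter set per condition group (cued, uncued L->C,
uncued C->L, possibly merged by a model variant).  Concentrations are sampled
on the log scale and probabilities on the logit scale; the swap/cyclic rates
use a stick-breaking pair (logit of ``p_swap``, logit of
``p_cyclic / (1 - p_swap)``) so their sum can never exceed one.  On each
transformed coordinate, subject values are Normal around a population mean
with a population standard deviation; the means carry Normal(0, 1.5)
hyperpriors (log-concentrations are centred at log 5) and the SDs
half-Normal(1).  Report-order weights receive a fixed Dirichlet(1) prior per
subject.

Sampling is Metropolis-within-Gibbs: per-coordinate Gaussian random-walk
updates of the subject parameters (discrete latent states are summed out
exactly in the likelihood), a 5-dimensional random-walk block for the order
weights in additive-log-ratio space, a conjugate Gibbs draw for each
population mean and a random-walk step on each log population SD.  Proposal
scales adapt during warm-up (Robbins-Monro towards 44% acceptance for scalars,
25% for the order block) and are frozen afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from misbind.core import PARAM_GROUPS
from misbind.forward import ModelParams, TrialRecord
from misbind.likelihood import DatasetLikelihood
from misbind.likelihood import pointwise_loglik as _pointwise

__all__ = [
    "ModelSpec",
    "PopulationPrior",
    "McmcConfig",
    "FitResult",
    "build_variant",
    "fit_hierarchical",
    "posterior_subject_means",
    "sample_population",
    "theta_from_params",
    "params_from_theta",
]

#: transformed scalar coordinates in canonical order (order weights separate)
SCALAR_PARAMS = (
    ("kappa_colour", "log"),
    ("kappa_location", "log"),
    ("p_swap", "logit"),
    ("p_cyclic_rel", "logit"),
    ("g_feature", "logit"),
    ("g_object", "logit"),
    ("g_feat_swap_non", "logit"),
    ("g_feat_swap_swp", "logit"),
    ("g_obj_swap_non", "logit"),
    ("g_obj_swap_swp", "logit"),
    ("g_feat_cyclic", "logit"),
    ("g_obj_cyclic", "logit"),
)

_GUESS_PARAMS = (
    "g_feature", "g_object",
    "g_feat_swap_non", "g_feat_swap_swp",
    "g_obj_swap_non", "g_obj_swap_swp",
    "g_feat_cyclic", "g_obj_cyclic",
)

_SWAP_CONDITIONED = (
    "g_feat_swap_non", "g_feat_swap_swp",
    "g_obj_swap_non", "g_obj_swap_swp",
    "g_feat_cyclic", "g_obj_cyclic",
)

VARIANTS = ("full", "null", "no_asymmetric", "collapse_cue_uncued", "collapse_order")


@dataclass(frozen=True)
class ModelSpec:
    """A model variant: parameter sharing across groups and frozen rates."""

    variant: str
    group_map: dict[str, str]
    frozen: frozenset[str]

    @property
    def free_scalars(self) -> tuple[str, ...]:
        return tuple(n for n, _ in SCALAR_PARAMS if n not in self.frozen)

    def n_free_parameters(self) -> int:
        """Free parameters per condition group, counting the six order
        weights as the single report-order parameter."""
        return len(self.free_scalars) + 1

    def effective_group(self, param_group: str) -> str:
        return self.group_map[param_group]


def build_variant(name: str) -> ModelSpec:
    """The named model variants compared by WAIC.

    ``full`` — all 13 parameters per group; ``null`` — no swaps or guessing
    (precision and report order only); ``no_asymmetric`` — no guessing inside
    swap or cyclic trials, hence no asymmetric misattribution;
    ``collapse_cue_uncued`` — one shared parameter set for cued and uncued
    trials; ``collapse_order`` — the two uncued conditions share parameters.
    """
    identity = {g: g for g in PARAM_GROUPS}
    if name == "full":
        return ModelSpec(name, identity, frozenset())
    if name == "null":
        frozen = frozenset(("p_swap", "p_cyclic_rel") + _GUESS_PARAMS)
        return ModelSpec(name, identity, frozen)
    if name == "no_asymmetric":
        return ModelSpec(name, identity, frozenset(_SWAP_CONDITIONED))
    if name == "collapse_cue_uncued":
        return ModelSpec(name, {g: "all" for g in PARAM_GROUPS}, frozenset())
    if name == "collapse_order":
        return ModelSpec(
            name,
            {"cued": "cued", "uncued_LC": "uncued", "uncued_CL": "uncued"},
            frozenset(),
        )
    raise ValueError(f"unknown model variant {name!r}")


@dataclass(frozen=True)
class PopulationPrior:
    """Hyperpriors of the hierarchy, on the transformed scales."""

    mean_loc: float = 0.0
    mean_loc_kappa: float = math.log(5.0)
    mean_scale: float = 1.5
    sd_scale: float = 1.0
    order_concentration: tuple[float, ...] = (1.0,) * 6

    def mean_loc_for(self, name: str) -> float:
        return self.mean_loc_kappa if name.startswith("kappa") else self.mean_loc


@dataclass(frozen=True)
class McmcConfig:
    n_adapt: int = 5000
    n_iter: int = 10000
    n_chains: int = 4
    seed: int = 0
    target_accept: float = 0.44
    target_accept_block: float = 0.25

    def __post_init__(self) -> None:
        if self.n_adapt < 0 or self.n_iter <= 0 or self.n_chains <= 0:
            raise ValueError("MCMC sizes must be positive")

    @classmethod
    def quick(cls, seed: int = 0) -> "McmcConfig":
        """Scaled-down configuration for tests and desk-scale studies."""
        return cls(n_adapt=500, n_iter=1000, n_chains=2, seed=seed)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def params_from_theta(
    theta: np.ndarray, order_w: np.ndarray, free_names: tuple[str, ...]
) -> ModelParams:
    """Natural-scale parameters from a free transformed vector."""
    vals = dict(zip(free_names, theta))
    kc = math.exp(vals["kappa_colour"])
    kl = math.exp(vals["kappa_location"])
    p_swap = expit(vals["p_swap"]) if "p_swap" in vals else 0.0
    rel = expit(vals["p_cyclic_rel"]) if "p_cyclic_rel" in vals else 0.0
    p_cyclic = (1.0 - p_swap) * rel
    g = {n: (expit(vals[n]) if n in vals else 0.0) for n in _GUESS_PARAMS}
    return ModelParams(
        kappa_colour=kc,
        kappa_location=kl,
        p_swap=float(p_swap),
        p_cyclic_swap=float(p_cyclic),
        order_weights=tuple(np.asarray(order_w, dtype=float)),
        **g,
    )


def theta_from_params(params: ModelParams, free_names: tuple[str, ...]) -> np.ndarray:
    """Transformed free vector from natural parameters (inverse of
    :func:`params_from_theta`)."""
    rel = params.p_cyclic_swap / (1.0 - params.p_swap) if params.p_swap < 1 else 0.0
    natural = {
        "kappa_colour": math.log(params.kappa_colour),
        "kappa_location": math.log(params.kappa_location),
        "p_swap": logit(params.p_swap),
        "p_cyclic_rel": logit(rel),
        **{n: logit(getattr(params, n)) for n in _GUESS_PARAMS},
    }
    return np.array([natural[n] for n in free_names], dtype=float)


def _order_from_alr(z: np.ndarray) -> np.ndarray:
    e = np.exp(np.concatenate([z, [0.0]]))
    return e / e.sum()


def _alr_log_prior(z: np.ndarray, concentration: np.ndarray) -> float:
    # Dirichlet density on the simplex plus the ALR Jacobian (prod of weights)
    w = _order_from_alr(z)
    return float(np.dot(concentration, np.log(w)))


def sample_population(
    pop_means: ModelParams,
    n_subjects: int,
    rng: np.random.Generator,
    sd_transformed: float = 0.3,
    order_concentration_scale: float = 30.0,
) -> list[ModelParams]:
    """Draw subject parameter sets around population means.

    Scalar parameters get Normal(transform(mean), ``sd_transformed``) draws on
    their transformed scales; order weights are Dirichlet around the
    population weights with total concentration
    ``order_concentration_scale``.
    """
    names = tuple(n for n, _ in SCALAR_PARAMS)
    centre = theta_from_params(pop_means, names)
    out = []
    for _ in range(n_subjects):
        theta = centre + sd_transformed * rng.standard_normal(len(names))
        w = rng.dirichlet(
            np.asarray(pop_means.order_weights) * order_concentration_scale
        )
        out.append(params_from_theta(theta, w, names))
    return out


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Posterior draws and bookkeeping of one hierarchical fit."""

    spec: ModelSpec
    mcmc: McmcConfig
    subjects: list[int]
    groups: list[str]                 # effective groups, sorted
    param_groups_present: list[str]   # probe-level groups seen in the data
    free_names: tuple[str, ...]
    theta: np.ndarray                 # (chains, draws, subjects, groups, P)
    order: np.ndarray                 # (chains, draws, subjects, groups, 6)
    pop_mean: np.ndarray              # (chains, draws, groups, P)
    pop_sd: np.ndarray                # (chains, draws, groups, P)
    diagnostics: dict = field(default_factory=dict)

    # -- accessors ---------------------------------------------------------
    @property
    def n_draws(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    def _flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape((-1,) + arr.shape[2:])

    def subject_natural_draws(self, subject: int, group: str) -> dict[str, np.ndarray]:
        """Natural-scale draws of every free parameter for one subject/group."""
        si = self.subjects.index(subject)
        gi = self.groups.index(self.spec.effective_group(group))
        th = self._flat(self.theta)[:, si, gi, :]
        w = self._flat(self.order)[:, si, gi, :]
        out: dict[str, np.ndarray] = {}
        vals = {n: th[:, j] for j, n in enumerate(self.free_names)}
        out["kappa_colour"] = np.exp(vals["kappa_colour"])
        out["kappa_location"] = np.exp(vals["kappa_location"])
        p_swap = expit(vals["p_swap"]) if "p_swap" in vals else np.zeros(th.shape[0])
        rel = expit(vals["p_cyclic_rel"]) if "p_cyclic_rel" in vals else np.zeros(th.shape[0])
        out["p_swap"] = p_swap
        out["p_cyclic_swap"] = (1.0 - p_swap) * rel
        for n in _GUESS_PARAMS:
            out[n] = expit(vals[n]) if n in vals else np.zeros(th.shape[0])
        out["order_weights"] = w
        return out

    def subject_mean_params(self, subject: int, group: str) -> ModelParams:
        """Posterior means on the natural scale, as a parameter set."""
        d = self.subject_natural_draws(subject, group)
        w = d.pop("order_weights").mean(axis=0)
        return ModelParams(order_weights=tuple(w / w.sum()),
                           **{k: float(v.mean()) for k, v in d.items()})

    def population_natural_draws(self, group: str, name: str) -> np.ndarray:
        """Draws of the population location, mapped to the natural scale."""
        gi = self.groups.index(group)
        mu = self._flat(self.pop_mean)[:, gi, :]
        vals = {n: mu[:, j] for j, n in enumerate(self.free_names)}
        if name in ("kappa_colour", "kappa_location"):
            return np.exp(vals[name])
        if name == "p_swap":
            return expit(vals["p_swap"])
        if name == "p_cyclic_swap":
            return (1.0 - expit(vals["p_swap"])) * expit(vals["p_cyclic_rel"])
        if name in _GUESS_PARAMS:
            return expit(vals[name])
        raise KeyError(name)

    def param_draws(
        self, thin: int = 1
    ) -> dict[tuple[int, str], list[ModelParams]]:
        """Per-(subject, probe group) parameter draws for pointwise likelihoods."""
        th = self._flat(self.theta)[::thin]
        w = self._flat(self.order)[::thin]
        out: dict[tuple[int, str], list[ModelParams]] = {}
        for pg in self.param_groups_present:
            gi = self.groups.index(self.spec.effective_group(pg))
            for si, subject in enumerate(self.subjects):
                out[(subject, pg)] = [
                    params_from_theta(th[s, si, gi], w[s, si, gi], self.free_names)
                    for s in range(th.shape[0])
                ]
        return out

    def pointwise(self, dataset: list[TrialRecord], thin: int = 1) -> np.ndarray:
        """(trials x draws) log-likelihood matrix for WAIC."""
        return _pointwise(dataset, self.param_draws(thin=thin))


def posterior_subject_means(fit: FitResult):
    """Tidy table of per-subject posterior means (natural scale)."""
    import pandas as pd

    rows = []
    for subject in fit.subjects:
        for pg in fit.param_groups_present:
            p = fit.subject_mean_params(subject, pg)
            for name in [n for n, _ in SCALAR_PARAMS if n != "p_cyclic_rel"]:
                rows.append((subject, pg, name, getattr(p, name)))
            rows.append((subject, pg, "p_cyclic_swap", p.p_cyclic_swap))
            for j, w in enumerate(p.order_weights):
                rows.append((subject, pg, f"order_weight_{j + 1}", w))
    return pd.DataFrame(rows, columns=["subject", "param_group", "parameter", "value"])


class _ChainState:
    """Mutable state of one chain."""

    def __init__(self, S, G, P, prior, free_names, rng):
        self.theta = np.zeros((S, G, P))
        for j, n in enumerate(free_names):
            self.theta[:, :, j] = prior.mean_loc_for(n)
        self.z = np.zeros((S, G, 5))  # ALR order weights -> uniform
        self.mu = self.theta[0, :, :].copy()
        self.sd = np.full((G, P), 0.5)
        self.scale_theta = np.full((S, G, P), 0.3)
        self.scale_z = np.full((S, G), 0.3)
        self.scale_logsd = np.full((G, P), 0.3)
        self.rng = rng


def _run_chain(
    blocks, uses_order, subjects, groups, free_names, prior, mcmc, rng, store
):
    S, G, P = len(subjects), len(groups), len(free_names)
    st = _ChainState(S, G, P, prior, free_names, rng)
    conc = np.asarray(prior.order_concentration, dtype=float)

    def block_loglik(si, gi, params):
        dl = blocks.get((si, gi))
        return 0.0 if dl is None else float(dl.loglik(params).sum())

    cur_params = {}
    cur_ll = {}
    for si in range(S):
        for gi in range(G):
            p = params_from_theta(st.theta[si, gi], _order_from_alr(st.z[si, gi]),
                                  free_names)
            cur_params[(si, gi)] = p
            ll = block_loglik(si, gi, p)
            if not np.isfinite(ll):
                raise FloatingPointError(
                    "non-finite likelihood at initialization"
                )
            cur_ll[(si, gi)] = ll

    total_steps = mcmc.n_adapt + mcmc.n_iter
    for it in range(total_steps):
        adapting = it < mcmc.n_adapt
        gamma = min(0.25, 2.0 / math.sqrt(it + 10)) if adapting else 0.0

        # -- subject-level scalar parameters -------------------------------
        for si in range(S):
            for gi in range(G):
                theta = st.theta[si, gi]
                for j in range(P):
                    prop = theta.copy()
                    prop[j] += st.scale_theta[si, gi, j] * st.rng.standard_normal()
                    cand = params_from_theta(prop, cur_params[(si, gi)].order_weights,
                                             free_names)
                    ll = block_loglik(si, gi, cand)
                    mu, sd = st.mu[gi, j], st.sd[gi, j]
                    dprior = (
                        (theta[j] - mu) ** 2 - (prop[j] - mu) ** 2
                    ) / (2.0 * sd**2)
                    log_acc = ll - cur_ll[(si, gi)] + dprior
                    accept = math.log(st.rng.random()) < log_acc
                    if accept:
                        theta[j] = prop[j]
                        cur_params[(si, gi)] = cand
                        cur_ll[(si, gi)] = ll
                    if adapting:
                        st.scale_theta[si, gi, j] *= math.exp(
                            gamma * ((1.0 if accept else 0.0) - mcmc.target_accept)
                        )

                # -- order-weight block (ALR space) ------------------------
                z = st.z[si, gi]
                prop_z = z + st.scale_z[si, gi] * st.rng.standard_normal(5)
                w_prop = _order_from_alr(prop_z)
                cand = replace(cur_params[(si, gi)], order_weights=tuple(w_prop))
                if uses_order[(si, gi)]:
                    ll = block_loglik(si, gi, cand)
                else:
                    ll = cur_ll[(si, gi)]
                dprior = _alr_log_prior(prop_z, conc) - _alr_log_prior(z, conc)
                log_acc = ll - cur_ll[(si, gi)] + dprior
                accept = math.log(st.rng.random()) < log_acc
                if accept:
                    st.z[si, gi] = prop_z
                    cur_params[(si, gi)] = cand
                    cur_ll[(si, gi)] = ll
                if adapting:
                    st.scale_z[si, gi] *= math.exp(
                        gamma * ((1.0 if accept else 0.0) - mcmc.target_accept_block)
                    )

        # -- population level ----------------------------------------------
        for gi in range(G):
            for j, name in enumerate(free_names):
                vals = st.theta[:, gi, j]
                sd = st.sd[gi, j]
                prior_loc = prior.mean_loc_for(name)
                prec = S / sd**2 + 1.0 / prior.mean_scale**2
                mean = (vals.sum() / sd**2 + prior_loc / prior.mean_scale**2) / prec
                st.mu[gi, j] = mean + st.rng.standard_normal() / math.sqrt(prec)

                # log-sd random walk; half-Normal(sd_scale) prior
                log_sd = math.log(sd)
                prop = log_sd + st.scale_logsd[gi, j] * st.rng.standard_normal()
                sd_p = math.exp(prop)
                mu = st.mu[gi, j]
                ssq = float(np.sum((vals - mu) ** 2))

                def _lp(s, log_s):
                    return (
                        -S * log_s
                        - ssq / (2.0 * s**2)
                        - s**2 / (2.0 * prior.sd_scale**2)
                        + log_s  # Jacobian of the log transform
                    )

                log_acc = _lp(sd_p, prop) - _lp(sd, log_sd)
                accept = math.log(st.rng.random()) < log_acc
                if accept:
                    st.sd[gi, j] = sd_p
                if adapting:
                    st.scale_logsd[gi, j] *= math.exp(
                        gamma * ((1.0 if accept else 0.0) - mcmc.target_accept)
                    )

        if not adapting:
            k = it - mcmc.n_adapt
            store["theta"][k] = st.theta
            store["order"][k] = np.stack(
                [
                    [_order_from_alr(st.z[si, gi]) for gi in range(G)]
                    for si in range(S)
                ]
            )
            store["pop_mean"][k] = st.mu
            store["pop_sd"][k] = st.sd


def fit_hierarchical(
    dataset: list[TrialRecord],
    spec: ModelSpec,
    prior: PopulationPrior | None = None,
    mcmc: McmcConfig | None = None,
) -> FitResult:
    """Fit the hierarchical model to a trial dataset by MCMC.

    Chains run sequentially from seeds spawned off ``mcmc.seed``; the result
    is reproducible.  Chain diagnostics (split R-hat, effective sample size of
    the population means) are computed with arviz and stored in
    ``result.diagnostics``.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    prior = prior or PopulationPrior()
    mcmc = mcmc or McmcConfig()
    free_names = spec.free_scalars

    subjects = sorted({t.subject for t in dataset})
    pg_present = sorted({t.condition.param_group for t in dataset})
    groups = sorted({spec.effective_group(pg) for pg in pg_present})
    s_index = {s: i for i, s in enumerate(subjects)}
    g_index = {g: i for i, g in enumerate(groups)}

    trials_by_block: dict[tuple[int, int], list[TrialRecord]] = {}
    for t in dataset:
        key = (s_index[t.subject], g_index[spec.effective_group(t.condition.param_group)])
        trials_by_block.setdefault(key, []).append(t)
    blocks = {k: DatasetLikelihood(v) for k, v in trials_by_block.items()}
    uses_order = {
        (si, gi): any(not t.condition.is_cued for t in trials_by_block.get((si, gi), []))
        for si in range(len(subjects))
        for gi in range(len(groups))
    }

    S, G, P = len(subjects), len(groups), len(free_names)
    shape = (mcmc.n_chains, mcmc.n_iter)
    theta = np.empty(shape + (S, G, P))
    order = np.empty(shape + (S, G, 6))
    pop_mean = np.empty(shape + (G, P))
    pop_sd = np.empty(shape + (G, P))

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    for c in range(mcmc.n_chains):
        store = {
            "theta": theta[c],
            "order": order[c],
            "pop_mean": pop_mean[c],
            "pop_sd": pop_sd[c],
        }
        _run_chain(
            blocks, uses_order, subjects, groups, free_names, prior, mcmc,
            np.random.default_rng(seeds[c]), store,
        )

    result = FitResult(
        spec=spec,
        mcmc=mcmc,
        subjects=subjects,
        groups=groups,
        param_groups_present=pg_present,
        free_names=free_names,
        theta=theta,
        order=order,
        pop_mean=pop_mean,
        pop_sd=pop_sd,
    )
    result.diagnostics = _diagnostics(result)
    return result


def _diagnostics(fit: FitResult) -> dict:
    import arviz as az

    rhat = {}
    ess = {}
    for gi, g in enumerate(fit.groups):
        for j, name in enumerate(fit.free_names):
            draws = fit.pop_mean[:, :, gi, j]
            key = f"{g}.{name}"
            rhat[key] = float(az.rhat(az.convert_to_dataset(draws))["x"])
            ess[key] = float(az.ess(az.convert_to_dataset(draws))["x"])
    flagged = sorted(k for k, v in rhat.items() if v > 1.1)
    return {"rhat": rhat, "ess": ess, "rhat_above_1.1": flagged}
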