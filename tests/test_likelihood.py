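import math

import numpy as np
import pytest
from dataclasses import replace
from scipy.special import i0, logsumexp

from _oracles import brute_trial_loglik
from conftest import random_params
from misbind.core import Condition, PERMUTATIONS
from misbind.forward import (
    LatentTrialState,
    ModelParams,
    TrialRecord,
    simulate_trial,
)
from misbind.likelihood import (
    DatasetLikelihood,
    enumerate_latents,
    pointwise_loglik,
    state_loglik,
    trial_loglik,
    von_mises_logpdf,
)
from misbind.taskgen import StimulusArray

STIM = StimulusArray((10.0, 140.0, 250.0), (80.0, 200.0, 330.0))
UNCUED = Condition("uncued_LC")
LOG_U = -math.log(2 * math.pi)


class TestVonMises:
    def test_zero_kappa_is_uniform(self, rng):
        for x, mu in rng.uniform(0, 360, size=(20, 2)):
            assert von_mises_logpdf(x, mu, 0.0) == pytest.approx(LOG_U)

    def test_mode_value_against_bessel(self):
        # density at the mean for kappa=2: e^2 / (2 pi I0(2))
        expected = math.log(math.exp(2.0) / (2 * math.pi * i0(2.0)))
        assert von_mises_logpdf(100.0, 100.0, 2.0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("kappa", [0.5, 5.0, 50.0])
    def test_integrates_to_one(self, kappa):
        grid = np.linspace(0.0, 360.0, 3600, endpoint=False) + 0.05
        dens = np.exp(von_mises_logpdf(grid, 77.0, kappa))
        assert dens.sum() * (2 * math.pi / 3600) == pytest.approx(1.0, abs=1e-6)

    def test_symmetry_and_negative_kappa(self):
        assert von_mises_logpdf(110.0, 100.0, 3.0) == pytest.approx(
            von_mises_logpdf(90.0, 100.0, 3.0)
        )
        with pytest.raises(ValueError):
            von_mises_logpdf(0.0, 0.0, -1.0)


class TestEnumeration:
    def test_order_only_support_when_no_errors(self):
        p = ModelParams(
            kappa_colour=5, kappa_location=5, p_swap=0, p_cyclic_swap=0,
            g_feature=0, g_object=0, g_feat_swap_non=0, g_feat_swap_swp=0,
            g_obj_swap_non=0, g_obj_swap_swp=0, g_feat_cyclic=0, g_obj_cyclic=0,
            order_weights=(0.3, 0.2, 0.15, 0.15, 0.1, 0.1),
        )
        states = enumerate_latents(p, UNCUED)
        assert len(states) == 6
        assert np.allclose(
            sorted(pr for _, pr in states), sorted(p.order_weights), atol=1e-12
        )

    def test_priors_sum_to_one_for_random_parameters(self, rng):
        for _ in range(100):
            p = random_params(rng)
            for cond in (UNCUED, Condition("cued_by_colour")):
                total = sum(pr for _, pr in enumerate_latents(p, cond))
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_certain_swap_splits_prior_across_pairs(self, rich_params):
        p = replace(rich_params, p_swap=1.0, p_cyclic_swap=0.0)
        states = enumerate_latents(p, UNCUED)
        for pair in ((0, 1), (0, 2), (1, 2)):
            mass = sum(pr for s, pr in states if s.swap_pair == pair)
            assert mass == pytest.approx(1.0 / 3.0, abs=1e-12)


class TestStateLoglik:
    def test_all_guessed_is_uniform_to_the_sixth(self, rich_params):
        tr = TrialRecord(0, UNCUED, STIM, (1.0, 2.0, 3.0), (4.0, 5.0, 6.0))
        state = LatentTrialState(
            PERMUTATIONS[0], "none",
            guess_flags=((True, True),) * 3, object_guess=(True,) * 3,
        )
        assert state_loglik(tr, state, rich_params) == pytest.approx(6 * LOG_U)

    def test_identity_state_at_targets(self):
        p = ModelParams.default()
        p = replace(p, kappa_colour=2.0, kappa_location=2.0)
        tr = TrialRecord(0, UNCUED, STIM, STIM.colours, STIM.locations)
        state = LatentTrialState(PERMUTATIONS[0], "none")
        assert state_loglik(tr, state, p) == pytest.approx(
            6 * von_mises_logpdf(0.0, 0.0, 2.0)
        )

    def test_cued_state_contradicting_selection_is_impossible(self, rich_params):
        cond = Condition("cued_by_location")
        tr = simulate_trial(rich_params, cond, STIM, np.random.default_rng(0))
        bad = LatentTrialState(PERMUTATIONS[1], "none", error_dim="colour")
        assert state_loglik(tr, bad, rich_params) == -np.inf


class TestTrialLoglik:
    def test_matches_bruteforce_oracle(self, rng):
        conds = [UNCUED, Condition("uncued_CL"), Condition("cued_by_colour"),
                 Condition("cued_by_location")]
        for i in range(40):
            p = random_params(rng)
            tr = simulate_trial(p, conds[i % 4], STIM, rng)
            assert trial_loglik(tr, p) == pytest.approx(
                brute_trial_loglik(tr, p), abs=1e-9
            )

    def test_matches_explicit_enumeration(self, rng, rich_params):
        for cond in (UNCUED, Condition("cued_by_colour")):
            tr = simulate_trial(rich_params, cond, STIM, rng)
            states = enumerate_latents(rich_params, cond)
            by_enum = logsumexp(
                [math.log(pr) + state_loglik(tr, s, rich_params) for s, pr in states]
            )
            assert trial_loglik(tr, rich_params) == pytest.approx(by_enum, abs=1e-10)

    def test_zero_kappa_collapses_to_uniform(self, rich_params):
        p = replace(rich_params, kappa_colour=0.0, kappa_location=0.0)
        tr = TrialRecord(0, UNCUED, STIM, (0.0, 10.0, 20.0), (30.0, 40.0, 50.0))
        assert trial_loglik(tr, p) == pytest.approx(6 * LOG_U, abs=1e-12)

    def test_swap_probability_raises_swapped_pattern_likelihood(self):
        # responses showing a clean reciprocal colour exchange of objects 1,2
        swapped_colours = (STIM.colours[1], STIM.colours[0], STIM.colours[2])
        tr = TrialRecord(0, UNCUED, STIM, swapped_colours, STIM.locations)
        base = dict(
            kappa_colour=20.0, kappa_location=20.0, p_cyclic_swap=0.0,
            g_feature=0.0, g_object=0.0, g_feat_swap_non=0.0, g_feat_swap_swp=0.0,
            g_obj_swap_non=0.0, g_obj_swap_swp=0.0, g_feat_cyclic=0.0,
            g_obj_cyclic=0.0,
        )
        lls = [
            trial_loglik(tr, ModelParams(p_swap=ps, **base))
            for ps in (0.01, 0.1, 0.3, 0.6)
        ]
        assert np.all(np.diff(lls) > 0)

    def test_canonical_swaps_not_double_counted(self):
        """The swapped-pattern likelihood contains exactly one swap state's
        mass: P(pattern | p_swap) scales like p_swap/3, not 2 p_swap/3."""
        swapped_colours = (STIM.colours[1], STIM.colours[0], STIM.colours[2])
        tr = TrialRecord(0, UNCUED, STIM, swapped_colours, STIM.locations)
        base = dict(
            kappa_colour=200.0, kappa_location=200.0, p_cyclic_swap=0.0,
            g_feature=0.0, g_object=0.0, g_feat_swap_non=0.0, g_feat_swap_swp=0.0,
            g_obj_swap_non=0.0, g_obj_swap_swp=0.0, g_feat_cyclic=0.0,
            g_obj_cyclic=0.0,
        )
        p_swap = 0.3
        ll = trial_loglik(tr, ModelParams(p_swap=p_swap, **base))
        # at this concentration only the matching swap state has mass: the
        # density is (p_swap/3) x (order weight) x 6 von Mises mode densities
        mode = von_mises_logpdf(0.0, 0.0, 200.0)
        expected = math.log(p_swap / 3.0) + math.log(1.0 / 6.0) + 6 * mode
        assert ll == pytest.approx(expected, abs=1e-6)


class TestPointwise:
    def test_single_draw_equals_per_trial_loglik(self, mixed_dataset, rich_params):
        draws = {
            (s, g): [rich_params]
            for s in range(3)
            for g in ("cued", "uncued_LC", "uncued_CL")
        }
        mat = pointwise_loglik(mixed_dataset, draws)
        assert mat.shape == (len(mixed_dataset), 1)
        for i, t in enumerate(mixed_dataset):
            assert mat[i, 0] == pytest.approx(trial_loglik(t, rich_params), abs=1e-10)

    def test_matches_naive_double_loop(self, rng, mixed_dataset):
        toy = mixed_dataset[:10]
        draw_list = [random_params(rng) for _ in range(5)]
        draws = {
            (s, g): draw_list
            for s in range(3)
            for g in ("cued", "uncued_LC", "uncued_CL")
        }
        mat = pointwise_loglik(toy, draws)
        for i, t in enumerate(toy):
            for j, p in enumerate(draw_list):
                assert mat[i, j] == pytest.approx(trial_loglik(t, p), abs=1e-10)

    def test_missing_draws_raise(self, mixed_dataset, rich_params):
        with pytest.raises(KeyError):
            pointwise_loglik(mixed_dataset, {(0, "cued"): [rich_params]})


def test_batch_evaluator_matches_scalar_path(rng, rich_params, mixed_dataset):
    dl = DatasetLikelihood(mixed_dataset)
    batch = dl.loglik(rich_params)
    scalar = np.array([trial_loglik(t, rich_params) for t in mixed_dataset])
    assert np.allclose(batch, scalar, atol=1e-10)
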