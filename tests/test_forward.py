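import numpy as np
import pytest
from scipy import stats

from misbind.core import Condition, PERMUTATIONS
from misbind.forward import (
    LatentTrialState,
    ModelParams,
    emit_responses,
    latent_to_assignment,
    sample_latent_state,
    simulate_dataset,
    simulate_trial,
)
from misbind.taskgen import DesignSpec, StimulusArray

STIM = StimulusArray((10.0, 140.0, 250.0), (80.0, 200.0, 330.0))


def zero_error(**over):
    base = dict(
        kappa_colour=100.0, kappa_location=100.0, p_swap=0.0, p_cyclic_swap=0.0,
        g_feature=0.0, g_object=0.0, g_feat_swap_non=0.0, g_feat_swap_swp=0.0,
        g_obj_swap_non=0.0, g_obj_swap_swp=0.0, g_feat_cyclic=0.0, g_obj_cyclic=0.0,
    )
    base.update(over)
    return ModelParams(**base)


class TestLatentSampling:
    def test_no_errors_when_rates_zero(self, rng, uncued_condition):
        p = zero_error()
        for _ in range(50):
            lat = sample_latent_state(p, uncued_condition, rng)
            assert lat.error_kind == "none"
            assert not any(any(f) for f in lat.guess_flags)

    def test_certain_swap_with_object_guess(self, rng, uncued_condition):
        # every draw is a swap whose swapped objects are object-guessed:
        # an asymmetric misattribution by object guessing
        p = zero_error(p_swap=1.0, g_obj_swap_swp=1.0)
        for _ in range(30):
            lat = sample_latent_state(p, uncued_condition, rng)
            assert lat.error_kind == "swap"
            for o in lat.swap_pair:
                assert lat.object_guess[o]
                assert lat.guess_flags[o] == (True, True)

    def test_swap_frequency_binomial(self, rng, uncued_condition):
        p = zero_error(p_swap=0.3)
        n = 10_000
        swaps = sum(
            sample_latent_state(p, uncued_condition, rng).error_kind == "swap"
            for _ in range(n)
        )
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(swaps / n - 0.3) < 3 * se

    def test_permutation_follows_order_weights(self, rng, uncued_condition):
        w = (0.7, 0.06, 0.06, 0.06, 0.06, 0.06)
        p = zero_error(order_weights=w)
        n = 4000
        first = sum(
            sample_latent_state(p, uncued_condition, rng).permutation == PERMUTATIONS[0]
            for _ in range(n)
        )
        assert abs(first / n - 0.7) < 3 * np.sqrt(0.7 * 0.3 / n)

    def test_cued_guesses_restricted_to_report_dimension(self, rng):
        p = zero_error(g_object=1.0)
        lat = sample_latent_state(p, Condition("cued_by_colour"), rng)
        # colour is the cue: only location can be guessed
        assert all(f == (False, True) for f in lat.guess_flags)


class TestAssignment:
    def test_identity(self):
        lat = LatentTrialState(PERMUTATIONS[0], "none")
        a = latent_to_assignment(lat)
        assert a.colour_src == (1, 2, 3)
        assert a.location_src == (1, 2, 3)

    def test_swap_exchanges_one_dimension(self):
        lat = LatentTrialState(PERMUTATIONS[0], "swap", swap_pair=(0, 1))
        a = latent_to_assignment(lat)
        assert a.colour_src == (2, 1, 3)
        assert a.location_src == (1, 2, 3)

    def test_swap_with_feature_guess_is_asymmetric(self):
        lat = LatentTrialState(
            PERMUTATIONS[0], "swap", swap_pair=(0, 1),
            guess_flags=((True, False), (False, False), (False, False)),
        )
        a = latent_to_assignment(lat)
        assert a.colour_src == (0, 1, 3)
        assert a.location_src == (1, 2, 3)

    def test_double_swap_is_identity(self):
        for pair in ((0, 1), (0, 2), (1, 2)):
            lat = LatentTrialState(PERMUTATIONS[0], "swap", swap_pair=pair)
            src = latent_to_assignment(lat).colour_src
            twice = tuple(src[src[o] - 1] for o in range(3))
            assert twice == (1, 2, 3)

    def test_triple_cyclic_is_identity(self):
        for d in (1, 2):
            lat = LatentTrialState(PERMUTATIONS[0], "cyclic", cyclic_direction=d)
            src = latent_to_assignment(lat).colour_src
            out = (1, 2, 3)
            for _ in range(3):
                out = tuple(src[out[o] - 1] for o in range(3))
            assert out == (1, 2, 3)

    def test_malformed_states_rejected(self):
        with pytest.raises(ValueError):
            LatentTrialState(PERMUTATIONS[0], "swap")  # missing pair
        with pytest.raises(ValueError):
            LatentTrialState(PERMUTATIONS[0], "none", swap_pair=(0, 1))


class TestEmission:
    def test_noise_free_limit_reproduces_stimuli(self, rng, uncued_condition):
        p = zero_error(kappa_colour=1e8, kappa_location=1e8)
        lat = LatentTrialState(PERMUTATIONS[3], "none")
        tr = emit_responses(
            STIM, latent_to_assignment(lat), lat.permutation, p, uncued_condition, rng
        )
        for s in range(3):
            o = lat.permutation.mapping[s]
            assert tr.response_colours[s] == pytest.approx(STIM.colours[o], abs=0.01)
            assert tr.response_locations[s] == pytest.approx(STIM.locations[o], abs=0.01)

    def test_guessed_features_are_uniform(self, rng, uncued_condition):
        p = zero_error(g_feature=1.0, kappa_colour=50.0)
        draws = np.array(
            [
                simulate_trial(p, uncued_condition, STIM, rng).response_colours[0]
                for _ in range(10_000)
            ]
        )
        assert stats.kstest(draws / 360.0, "uniform").pvalue > 0.01

    def test_cued_dimension_copied_exactly(self, rng):
        p = ModelParams.default()
        tr = simulate_trial(p, Condition("cued_by_location"), STIM, rng)
        for s in range(3):
            assert tr.response_locations[s] == STIM.locations[tr.cue_selection[s]]
        tr = simulate_trial(p, Condition("cued_by_colour"), STIM, rng)
        for s in range(3):
            assert tr.response_colours[s] == STIM.colours[tr.cue_selection[s]]


class TestSimulateDataset:
    def _params(self, p):
        return {s: {g: p for g in ("cued", "uncued_LC", "uncued_CL")} for s in range(2)}

    def test_error_free_dataset_is_exact(self):
        p = zero_error(kappa_colour=1e9, kappa_location=1e9)
        design = DesignSpec(n_subjects=2, trials_per_condition=5)
        for tr in simulate_dataset(self._params(p), design, seed=1):
            perm = tr.latent.permutation.mapping
            for s in range(3):
                assert tr.response_colours[s] == pytest.approx(
                    tr.stimuli.colours[perm[s]], abs=0.02
                )

    def test_seed_determinism(self, default_params):
        design = DesignSpec(n_subjects=2, trials_per_condition=5)
        a = simulate_dataset(self._params(default_params), design, seed=3)
        b = simulate_dataset(self._params(default_params), design, seed=3)
        assert a == b

    def test_ground_truth_swap_count_within_3se(self):
        p = zero_error(p_swap=0.1)
        params = {0: {"uncued_LC": p}}
        design = DesignSpec(n_subjects=1, trials_per_condition=5000,
                            conditions=("uncued_LC",))
        data = simulate_dataset(params, design, seed=4)
        swaps = sum(t.latent.error_kind == "swap" for t in data)
        assert abs(swaps - 500) < 3 * np.sqrt(5000 * 0.1 * 0.9)

    def test_missing_group_raises(self, default_params):
        design = DesignSpec(n_subjects=1, trials_per_condition=2)
        with pytest.raises(KeyError):
            simulate_dataset({0: {"cued": default_params}}, design, seed=0)


def test_colour_and_location_swaps_observationally_equivalent(rng):
    """A reciprocal colour exchange equals the mirror location exchange once
    slot pairings are compared; the canonical representation stores one."""
    lat_c = LatentTrialState(PERMUTATIONS[0], "swap", swap_pair=(0, 1))
    a = latent_to_assignment(lat_c)
    pairings_colour_swap = {
        (a.colour_src[o], a.location_src[o]) for o in range(3)
    }
    # location-dimension swap of the same pair, expressed by hand
    pairings_location_swap = {(2, 1), (1, 2), (3, 3)}
    # the (colour, location) feature pairings coincide up to relabelling of
    # which member of the pair is listed first
    assert {frozenset(p) for p in pairings_colour_swap} == {
        frozenset(p) for p in pairings_location_swap
    }
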