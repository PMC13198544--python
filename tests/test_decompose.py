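import numpy as np
import pytest
from dataclasses import replace

from conftest import random_params
from misbind.core import Condition, PERMUTATIONS
from misbind.decompose import (
    CLASS_NAMES,
    absolute_error,
    classify_state,
    classify_trials,
    report_order_bias,
    swap_composition,
)
from misbind.forward import (
    LatentTrialState,
    ModelParams,
    TrialRecord,
    sample_latent_state,
    simulate_trial,
)
from misbind.taskgen import StimulusArray

STIM = StimulusArray((10.0, 140.0, 250.0), (80.0, 200.0, 330.0))
UNCUED = Condition("uncued_LC")


class TestSwapComposition:
    def test_fractions_sum_to_one(self, rng):
        for _ in range(50):
            c = swap_composition(random_params(rng))
            assert c.frac_symmetric + c.frac_asym_feature + c.frac_asym_object == (
                pytest.approx(1.0, abs=1e-10)
            )

    def test_no_guessing_means_pure_symmetric(self, default_params):
        p = replace(default_params, g_feat_swap_swp=0.0, g_obj_swap_swp=0.0)
        c = swap_composition(p)
        assert c.frac_symmetric == 1.0
        assert c.p_swap_overall == p.p_swap

    def test_certain_object_guess_is_all_asymmetric(self, default_params):
        c = swap_composition(replace(default_params, g_obj_swap_swp=1.0))
        assert c.frac_asym_object == 1.0

    def test_closed_form_matches_latent_monte_carlo(self, rng, rich_params):
        p = replace(rich_params, p_swap=1.0, p_cyclic_swap=0.0)
        counts = {"symmetric_swap": 0, "asym_feature": 0, "asym_object": 0}
        n = 100_000
        for _ in range(n):
            counts[classify_state(sample_latent_state(p, UNCUED, rng))] += 1
        c = swap_composition(p)
        for key, frac in (
            ("symmetric_swap", c.frac_symmetric),
            ("asym_feature", c.frac_asym_feature),
            ("asym_object", c.frac_asym_object),
        ):
            se = np.sqrt(frac * (1 - frac) / n)
            assert abs(counts[key] / n - frac) < 3 * se, key


class TestClassifyTrials:
    def test_rows_sum_to_one(self, mixed_dataset, rich_params):
        df = classify_trials(mixed_dataset, rich_params)
        assert np.allclose(df[list(CLASS_NAMES)].sum(axis=1), 1.0, atol=1e-8)

    def test_clean_trial_classified_correct(self):
        p = replace(ModelParams.default(), kappa_colour=5000.0, kappa_location=5000.0)
        tr = TrialRecord(0, UNCUED, STIM, STIM.colours, STIM.locations)
        df = classify_trials([tr], p)
        assert df["correct"].iloc[0] > 0.99

    def test_reciprocal_exchange_classified_symmetric(self):
        p = replace(ModelParams.default(), kappa_colour=50.0, kappa_location=50.0)
        swapped = (STIM.colours[1], STIM.colours[0], STIM.colours[2])
        tr = TrialRecord(0, UNCUED, STIM, swapped, STIM.locations)
        df = classify_trials([tr], p)
        probs = df[list(CLASS_NAMES)].iloc[0]
        assert probs.idxmax() == "symmetric_swap"

    def test_composition_recovered_from_ground_truth_swaps(self, rng, rich_params):
        """Aggregated posterior class mass over true swap trials approximates
        the generating composition."""
        p = replace(rich_params, p_swap=0.5, p_cyclic_swap=0.0,
                    kappa_colour=12.0, kappa_location=12.0)
        trials = [simulate_trial(p, UNCUED, STIM, rng, trial_id=i) for i in range(4000)]
        swap_trials = [t for t in trials if t.latent.error_kind == "swap"]
        df = classify_trials(swap_trials, p)
        mass = df[["symmetric_swap", "asym_feature", "asym_object"]].to_numpy()
        observed = mass.sum(axis=0) / mass.sum()
        c = swap_composition(p)
        expected = np.array([c.frac_symmetric, c.frac_asym_feature, c.frac_asym_object])
        assert np.all(np.abs(observed - expected) < 0.05)


class TestAbsoluteError:
    def test_exact_response_and_wraparound(self):
        tr = TrialRecord(0, UNCUED, STIM,
                         (STIM.colours[0], 330.0, STIM.colours[2]),
                         STIM.locations)
        df = absolute_error([tr])
        colour = df[df.dimension == "colour"].sort_values("slot")["error"].to_numpy()
        assert colour[0] == 0.0
        assert colour[1] == pytest.approx(170.0)  # 330 vs 140 wraps to 170
        assert np.all((0 <= df["error"]) & (df["error"] <= 180))

    def test_wrap_example(self):
        stim = StimulusArray((0.0, 100.0, 200.0), (10.0, 120.0, 240.0))
        tr = TrialRecord(0, UNCUED, stim, (190.0, 100.0, 200.0),
                         (10.0, 120.0, 240.0))
        df = absolute_error([tr])
        first = df[(df.dimension == "colour") & (df.slot == 0)]["error"].iloc[0]
        assert first == pytest.approx(170.0)

    def test_uniform_responses_average_90_degrees(self, rng):
        trials = []
        for i in range(2000):
            trials.append(
                TrialRecord(0, UNCUED, STIM,
                            tuple(rng.uniform(0, 360, 3)),
                            tuple(rng.uniform(0, 360, 3)), trial_id=i)
            )
        df = absolute_error(trials)
        assert df["error"].mean() == pytest.approx(90.0, abs=2.0)


class TestReportOrderBias:
    def _trial(self, first_obj, locations, latent_perm=None):
        perm = latent_perm or next(
            p for p in PERMUTATIONS if p.mapping[0] == first_obj
        )
        stim = StimulusArray((10.0, 140.0, 250.0), locations)
        lat = LatentTrialState(perm, "none")
        return TrialRecord(
            0, UNCUED, stim,
            tuple(stim.colours[o] for o in perm.mapping),
            tuple(stim.locations[o] for o in perm.mapping),
            latent=lat,
        )

    def test_always_topmost_first(self):
        # object 1 sits at 92 degrees: nearest to screen-up
        trials = [self._trial(1, (10.0, 92.0, 200.0)) for _ in range(20)]
        assert report_order_bias(trials)["frac_topmost_first"] == 1.0

    def test_random_order_near_one_third(self, rng):
        trials = []
        for _ in range(10_000):
            first = int(rng.integers(3))
            locs = tuple(rng.uniform(0, 360, 3))
            trials.append(self._trial(first, locs))
        frac = report_order_bias(trials)["frac_topmost_first"]
        assert abs(frac - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 10_000)

    def test_inferred_first_object_without_ground_truth(self):
        stim = StimulusArray((10.0, 140.0, 250.0), (10.0, 92.0, 200.0))
        tr = TrialRecord(
            0, UNCUED, stim,
            (stim.colours[1], stim.colours[0], stim.colours[2]),
            (stim.locations[1], stim.locations[0], stim.locations[2]),
        )
        assert report_order_bias([tr])["frac_topmost_first"] == 1.0

    def test_requires_uncued_trials(self, rng, rich_params):
        cued = [simulate_trial(rich_params, Condition("cued_by_colour"), STIM, rng)]
        with pytest.raises(ValueError):
            report_order_bias(cued)
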