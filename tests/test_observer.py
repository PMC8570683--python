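"""Spiking observer population, rank AUC and neurometric curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsecode import (
    ObserverPopulation,
    PulseSpec,
    TrainSpec,
    auc,
    build_isoline,
    discriminability,
    neurometric_curve,
    simulate_ensemble,
)
from pulsecode.stimuli import RANGE_I, RANGE_II, RATE_CHANGE_LEVELS
from tests.conftest import ANCHOR_I, ANCHOR_II

REF_TRAIN = TrainSpec(PulseSpec(*ANCHOR_I), 90.0)


def auc_bruteforce(ref, comp) -> float:
    """Independent pairwise oracle: count comp>ref pairs, half-credit ties."""
    total = 0.0
    for r in ref:
        for c in comp:
            total += 1.0 if c > r else 0.5 if c == r else 0.0
    return total / (len(ref) * len(comp))


class TestAuc:
    def test_worked_example(self):
        assert auc([0, 0, 1], [1, 1, 2]) == pytest.approx(8 / 9)
        assert discriminability([0, 0, 1], [1, 1, 2]) == pytest.approx(7 / 9)

    def test_identical_samples_are_chance(self):
        assert auc([3, 3, 3], [3, 3, 3]) == 0.5
        assert discriminability([1, 2, 3], [1, 2, 3]) == 0.0

    def test_fully_separated_samples(self):
        assert auc([0, 1, 2], [5, 6, 7]) == 1.0
        assert discriminability([5, 6], [0, 1]) == 1.0  # either ordering

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            auc([], [1, 2])

    @given(
        ref=st.lists(st.integers(0, 10), min_size=1, max_size=50),
        comp=st.lists(st.integers(0, 10), min_size=1, max_size=50),
    )
    @settings(max_examples=200, deadline=None)
    def test_rank_auc_equals_pairwise_oracle(self, ref, comp):
        assert auc(ref, comp) == pytest.approx(auc_bruteforce(ref, comp), abs=1e-12)

    @given(ref=st.lists(st.integers(0, 20), min_size=2, max_size=30),
           comp=st.lists(st.integers(0, 20), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_d_invariant_under_monotone_transform_and_swap(self, ref, comp):
        r, c = np.array(ref, float), np.array(comp, float)
        d0 = discriminability(r, c)
        assert discriminability(np.exp(r / 5), np.exp(c / 5)) == pytest.approx(d0)
        assert discriminability(c, r) == pytest.approx(d0)


class TestSimulateEnsemble:
    def test_determinism_under_seed(self):
        pop = ObserverPopulation()
        e1 = simulate_ensemble(pop, REF_TRAIN, n_trials=20, seed=9)
        e2 = simulate_ensemble(pop, REF_TRAIN, n_trials=20, seed=9)
        np.testing.assert_array_equal(e1.per_pulse, e2.per_pulse)

    def test_subthreshold_stimulus_is_silent(self):
        pop = ObserverPopulation()
        quiet = TrainSpec(PulseSpec(0.01, ANCHOR_I[1]), 90.0)
        ens = simulate_ensemble(pop, quiet, n_trials=10, seed=0)
        assert ens.per_pulse.sum() == 0

    def test_saturated_stimulus_fires_every_unit(self):
        pop = ObserverPopulation()
        loud = TrainSpec(PulseSpec(1e6, ANCHOR_I[1]), 90.0)
        ens = simulate_ensemble(pop, loud, n_trials=10, seed=0)
        assert np.all(ens.per_pulse == pop.n_units)

    def test_per_trial_counts_are_column_sums(self):
        ens = simulate_ensemble(ObserverPopulation(), REF_TRAIN, n_trials=5, seed=1)
        np.testing.assert_array_equal(ens.per_trial, ens.per_pulse.sum(axis=0))
        assert ens.per_pulse.shape == (45, 5)

    def test_invalid_population_rejected(self):
        with pytest.raises(ValueError):
            ObserverPopulation(n_units=0)


class TestNeurometricCurve:
    def test_self_comparison_is_chance(self):
        pop = ObserverPopulation()
        il = build_isoline("d", ANCHOR_I, [ANCHOR_I[1] * 0.9999999], 90.0)
        d = neurometric_curve(pop, il, "local", n_trials=100, seed=2)
        assert abs(d[0]) < 0.1

    def test_rate_change_local_mode_is_blind(self):
        # identical pulse shapes: per-pulse count distributions cannot differ
        pop = ObserverPopulation()
        il = build_isoline("d", ANCHOR_I, RANGE_I.change_widths, 90.0)
        d = neurometric_curve(
            pop, il, "local", n_trials=100, seed=3, rate_levels=RATE_CHANGE_LEVELS
        )
        assert np.all(d < 0.1)

    def test_rate_change_global_mode_is_error_free(self):
        # integrating across pulses separates the 500-ms counts completely
        pop = ObserverPopulation()
        il = build_isoline("d", ANCHOR_I, RANGE_I.change_widths, 90.0)
        d = neurometric_curve(
            pop, il, "global", n_trials=100, seed=3, rate_levels=RATE_CHANGE_LEVELS
        )
        assert np.all(d >= 0.95)

    def test_collinear_line_is_indiscriminable(self):
        # observer slope equal to the line exponent → zero drive change
        pop = ObserverPopulation(iso_slope=1.0)
        il = build_isoline("d", ANCHOR_I, RANGE_I.change_widths, 90.0)
        d = neurometric_curve(pop, il, "local", n_trials=100, seed=4)
        assert np.all(d < 0.1)

    def test_distant_exponent_grows_with_level(self):
        pop = ObserverPopulation(iso_slope=1.0)
        il = build_isoline("g", ANCHOR_I, RANGE_I.change_widths, 90.0)
        d = neurometric_curve(pop, il, "local", n_trials=100, seed=4)
        assert d[-1] > 0.8
        assert d[-1] > d[0]

    def test_worst_line_flips_between_ranges(self):
        # slope between 1 and 2: nearest-exponent line performs worst, and the
        # nearest line differs between the two stimulus-range geometries
        for rng_, slope, worst in ((RANGE_I, 1.2, "d"), (RANGE_II, 1.8, "g")):
            anchor = (rng_.ref_amplitude, rng_.ref_width)
            pop = ObserverPopulation(iso_slope=slope, anchor=anchor)
            mean_d = {}
            for line in "adg":
                il = build_isoline(line, anchor, rng_.change_widths, rng_.ref_rate)
                mean_d[line] = neurometric_curve(pop, il, "local", 100, seed=5).mean()
            assert min(mean_d, key=mean_d.get) == worst

    def test_invalid_mode_rejected(self):
        il = build_isoline("d", ANCHOR_I, [5.0], 90.0)
        with pytest.raises(ValueError):
            neurometric_curve(ObserverPopulation(), il, "spectral")
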