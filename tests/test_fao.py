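"""13CO2 breath-trace analysis: baseline excess, slope-to-max, normalization."""

import numpy as np
import pytest

from tracequant.fao import (
    CO2Trace,
    SubstrateEnrichmentTrace,
    excess_co2,
    normalize_oxidation,
    slope_to_max,
)
from tracequant.synthetic import co2_excess_curve, simulate_co2_traces


def make_trace(times, excess, baseline=0.011, animal="m1"):
    return CO2Trace(
        animal_id=animal,
        times=np.asarray(times, float),
        ratios=baseline + np.asarray(excess, float),
        baseline_fraction=baseline,
    )


class TestExcess:
    def test_subtraction(self):
        trace = make_trace([0, 40], [0.0015, 0.002])
        np.testing.assert_allclose(excess_co2(trace), [0.0015, 0.002])

    def test_baseline_trace_is_zero(self):
        trace = make_trace([0, 40, 80], [0, 0, 0])
        assert excess_co2(trace).tolist() == [0, 0, 0]

    def test_below_baseline_floored(self):
        trace = make_trace([0, 40], [0.001, -0.0005])
        np.testing.assert_allclose(excess_co2(trace), [0.001, 0.0])


class TestSlopeToMax:
    def test_three_point_ols(self):
        trace = make_trace([0, 40, 80, 120], [0, 0.002, 0.004, 0.003])
        res = slope_to_max(trace)
        assert res.time_of_max == 80
        assert res.slope == pytest.approx(5.0e-5)
        assert res.n_points == 3

    def test_exact_linear_rise(self):
        a = 3e-5
        times = np.arange(0, 201, 40.0)
        trace = make_trace(times, a * times)
        assert slope_to_max(trace).slope == pytest.approx(a)

    def test_plateau_tie_breaks_to_earliest(self):
        trace = make_trace([0, 40, 80, 120], [0, 0.004, 0.004, 0.001])
        assert slope_to_max(trace).time_of_max == 40

    def test_flat_trace_has_no_rise(self):
        trace = make_trace([0, 40, 80], [0, 0, 0])
        with pytest.raises(ValueError, match="no rise"):
            slope_to_max(trace)

    def test_recovers_secant_slope_on_rise_decay_curve(self):
        """Noise-free rise-then-decay: OLS slope within 5% of the brute-force secant."""
        times = np.arange(0, 481, 40.0)
        excess = co2_excess_curve(times, amplitude=0.004, rise_rate=0.02, decay_rate=0.004)
        trace = make_trace(times, excess)
        res = slope_to_max(trace)
        i_max = int(np.argmax(excess))
        secant = (excess[i_max] - excess[0]) / (times[i_max] - times[0])
        assert res.slope == pytest.approx(secant, rel=0.05)


class TestNormalize:
    def test_pointwise_division(self):
        trace = make_trace([30, 60, 90], [0.002, 0.004, 0.003])
        sub = SubstrateEnrichmentTrace("m1", np.array([30.0, 90.0]), np.array([0.08, 0.12]))
        times, norm = normalize_oxidation(trace, sub)
        # divisor at t=60 interpolates to 0.10
        assert norm[1] == pytest.approx(0.004 / 0.10)

    def test_constant_unity_substrate_is_identity(self):
        trace = make_trace([0, 40, 80], [0.001, 0.002, 0.003])
        sub = SubstrateEnrichmentTrace("m1", np.array([0.0, 80.0]), np.array([1.0, 1.0]))
        _, norm = normalize_oxidation(trace, sub)
        np.testing.assert_allclose(norm, excess_co2(trace))

    def test_extrapolation_refused(self):
        trace = make_trace([0, 40, 80], [0.001, 0.002, 0.003])
        sub = SubstrateEnrichmentTrace("m1", np.array([30.0, 90.0]), np.array([0.08, 0.12]))
        with pytest.raises(ValueError, match="covers only"):
            normalize_oxidation(trace, sub)

    def test_joint_scaling_invariance(self):
        times = [0, 40, 80]
        sub_t = np.array([0.0, 80.0])
        trace1 = make_trace(times, [0.001, 0.002, 0.003])
        sub1 = SubstrateEnrichmentTrace("m1", sub_t, np.array([0.1, 0.2]))
        trace2 = make_trace(times, [0.002, 0.004, 0.006])
        sub2 = SubstrateEnrichmentTrace("m1", sub_t, np.array([0.2, 0.4]))
        _, n1 = normalize_oxidation(trace1, sub1)
        _, n2 = normalize_oxidation(trace2, sub2)
        np.testing.assert_allclose(n1, n2)

    def test_low_enrichment_points_dropped(self):
        trace = make_trace([0, 40, 80], [0.001, 0.002, 0.003])
        sub = SubstrateEnrichmentTrace(
            "m1", np.array([0.0, 40.0, 80.0]), np.array([0.0005, 0.1, 0.1])
        )
        times, norm = normalize_oxidation(trace, sub)
        assert times.tolist() == [40, 80]


class TestGroupOrdering:
    def test_amplitude_contrast_preserved_under_noise(self):
        """1.5x amplitude contrast survives 10% noise in group means (seeded)."""
        slope_wins = norm_wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            traces, subs, truth = simulate_co2_traces(
                n_per_group=8, noise_cv=0.10, seed=seed
            )
            sub_by_id = {s.animal_id: s for s in subs}
            slopes = {"CF": [], "IF": []}
            norms = {"CF": [], "IF": []}
            for t in traces:
                group = t.animal_id.rsplit("_", 1)[0]
                slopes[group].append(slope_to_max(t).slope)
                _, nv = normalize_oxidation(t, sub_by_id[t.animal_id])
                norms[group].append(np.mean(nv))
            if np.mean(slopes["CF"]) > np.mean(slopes["IF"]):
                slope_wins += 1
            if np.mean(norms["CF"]) > np.mean(norms["IF"]):
                norm_wins += 1
        assert slope_wins >= 0.95 * n_seeds
        assert norm_wins >= 0.95 * n_seeds


def test_trace_validation():
    with pytest.raises(ValueError, match="increasing"):
        CO2Trace("m1", np.array([0.0, 0.0]), np.array([0.01, 0.01]))
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        CO2Trace("m1", np.array([0.0, 40.0]), np.array([0.01, 1.5]))
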