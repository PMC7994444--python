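import numpy as np
import pytest

import beetox as bt
from conftest import arm_records, make_group


def step_curve(pairs, n0=10):
    """SurvivalCurve from explicit (time, survival) steps for testing."""
    times = tuple(t for t, _ in pairs)
    surv = tuple(s for _, s in pairs)
    return bt.SurvivalCurve(
        times=times,
        survival=surv,
        at_risk=(n0,) * len(times),
        events=(0,) * len(times),
        n0=n0,
    )


class TestExpectedBlissCurve:
    def test_unit_factor_is_identity(self):
        sul = step_curve([(24.0, 0.5), (96.0, 0.3)])
        flu = step_curve([(96.0, 1.0)])
        prod = bt.expected_bliss_curve(sul, flu)
        for t in (3.0, 24.0, 48.0, 96.0):
            assert prod.probability_at(t) == pytest.approx(sul.probability_at(t))

    def test_pointwise_product(self):
        sul = step_curve([(24.0, 0.5)])
        flu = step_curve([(24.0, 0.9)])
        prod = bt.expected_bliss_curve(sul, flu)
        assert prod.probability_at(24.0) == pytest.approx(0.45)

    def test_merged_grid_matches_pointwise_evaluation(self):
        sul = step_curve([(3.0, 0.9), (24.0, 0.6), (72.0, 0.4)])
        flu = step_curve([(24.0, 0.95), (48.0, 0.8), (96.0, 0.7)])
        prod = bt.expected_bliss_curve(sul, flu)
        # independent oracle: evaluate each factor at a dense grid
        for t in np.linspace(0.5, 100, 200):
            assert prod.probability_at(t) == pytest.approx(
                sul.probability_at(t) * flu.probability_at(t), abs=1e-12
            )

    def test_commutativity(self):
        a = step_curve([(3.0, 0.8), (48.0, 0.5)])
        b = step_curve([(24.0, 0.7), (96.0, 0.6)])
        ab = bt.expected_bliss_curve(a, b)
        ba = bt.expected_bliss_curve(b, a)
        assert ab.times == ba.times
        assert ab.survival == pytest.approx(ba.survival)

    def test_product_below_each_factor(self, osmia_dataset):
        _, records = osmia_dataset
        sul = bt.kaplan_meier(arm_records(records, "SUL", 44.0))
        flu = bt.kaplan_meier(arm_records(records, "FLU"))
        prod = bt.expected_bliss_curve(sul, flu)
        for t in (3.0, 24.0, 48.0, 72.0, 96.0):
            assert prod.probability_at(t) <= sul.probability_at(t) + 1e-12
            assert prod.probability_at(t) <= flu.probability_at(t) + 1e-12


class TestMinConvolutionPseudoSample:
    def test_fully_censored_arms_give_censored_pseudo_bees(self):
        sul = make_group([(96.0, 0)] * 5)
        flu = make_group([(96.0, 0)] * 5, arm="FLU", sul_dose=0.0, flu_dose=1.2)
        pseudo = bt.min_convolution_pseudo_sample(sul, flu, 50, seed=1)
        assert all(r.last_time == 96.0 and r.event == 0 for r in pseudo)

    def test_death_beats_later_censoring(self):
        sul = make_group([(24.0, 1)])
        flu = make_group([(96.0, 0)], arm="FLU", sul_dose=0.0, flu_dose=1.2)
        pseudo = bt.min_convolution_pseudo_sample(sul, flu, 10, seed=1)
        assert all(r.last_time == 24.0 and r.event == 1 for r in pseudo)

    def test_censoring_before_death_censors(self):
        sul = make_group([(72.0, 1)])
        flu = make_group([(3.0, 0)], arm="FLU", sul_dose=0.0, flu_dose=1.2)
        pseudo = bt.min_convolution_pseudo_sample(sul, flu, 10, seed=1)
        assert all(r.last_time == 3.0 and r.event == 0 for r in pseudo)

    def test_pseudo_km_converges_to_product_curve(self, osmia_dataset):
        _, records = osmia_dataset
        sul = arm_records(records, "SUL", 11.0)
        flu = arm_records(records, "FLU")
        pseudo = bt.min_convolution_pseudo_sample(sul, flu, 10_000, seed=3)
        km_pseudo = bt.kaplan_meier(pseudo)
        product = bt.expected_bliss_curve(
            bt.kaplan_meier(sul), bt.kaplan_meier(flu)
        )
        sup = max(
            abs(km_pseudo.probability_at(t) - product.probability_at(t))
            for t in (3.0, 24.0, 48.0, 72.0, 96.0)
        )
        assert sup < 0.02

    def test_invalid_inputs(self):
        sul = make_group([(96.0, 0)])
        flu = make_group([(96.0, 0)], arm="FLU", sul_dose=0.0, flu_dose=1.2)
        with pytest.raises(ValueError):
            bt.min_convolution_pseudo_sample(sul, flu, 0)
        with pytest.raises(ValueError):
            bt.min_convolution_pseudo_sample([], flu, 10)


class TestBlissTest:
    def test_direction_convention(self):
        """A mixture arm strictly below the expected curve yields a
        one-sided p < 0.5 and a positive statistic."""
        sul = make_group([(96.0, 1)] * 5 + [(96.0, 0)] * 15)
        flu = make_group(
            [(96.0, 0)] * 20, arm="FLU", sul_dose=0.0, flu_dose=1.2
        )
        mix = make_group(
            [(3.0, 1)] * 15 + [(96.0, 0)] * 5,
            arm="SUL_FLU",
            flu_dose=1.2,
        )
        comp = bt.bliss_test(mix, sul, flu, seed=0)
        assert comp.test.statistic > 0
        assert comp.test.p_value < 0.5
        assert comp.test.alternative == "observed_less"

    def test_null_mixture_not_systematically_rejected(self):
        """Mixture arm equal in distribution to the SUL arm with an inert
        fungicide arm: no synergism signal."""
        ps = []
        for i in range(20):
            scenario = bt.reference_scenario("osmia", seed=70000 + i)
            records = bt.simulate_bioassay(scenario)
            sul = arm_records(records, "SUL", 11.0)
            flu = make_group(
                [(96.0, 0)] * 30, arm="FLU", sul_dose=0.0, flu_dose=1.2
            )
            half = len(sul) // 2
            mix = [
                bt.BeeRecord(
                    bee_id=r.bee_id,
                    species=r.species,
                    arm="SUL_FLU",
                    sul_dose=r.sul_dose,
                    flu_dose=1.2,
                    last_time=r.last_time,
                    event=r.event,
                )
                for r in sul[:half]
            ]
            comp = bt.bliss_test(mix, sul[half:], flu, seed=i)
            ps.append(comp.test.p_value)
        assert np.mean(np.asarray(ps) < 0.05) <= 0.2
        assert np.mean(ps) > 0.2

    def test_bootstrap_calibration_returns_valid_p(self, osmia_dataset):
        _, records = osmia_dataset
        comp = bt.bliss_test(
            arm_records(records, "SUL_FLU", 11.0),
            arm_records(records, "SUL", 11.0),
            arm_records(records, "FLU"),
            seed=5,
            calibration="bootstrap",
            n_boot=99,
        )
        assert 0 < comp.test.p_value <= 1
        assert comp.calibration == "bootstrap"

    def test_empty_arm_rejected(self):
        g = make_group([(96.0, 0)])
        with pytest.raises(ValueError):
            bt.bliss_test([], g, g)

    def test_comparison_carries_curves_and_dose(self, osmia_dataset):
        _, records = osmia_dataset
        comp = bt.bliss_test(
            arm_records(records, "SUL_FLU", 44.0),
            arm_records(records, "SUL", 44.0),
            arm_records(records, "FLU"),
            seed=9,
        )
        assert comp.sul_dose == 44.0
        surv = np.asarray(comp.expected_curve.survival)
        assert np.all(np.diff(surv) <= 1e-12)
        assert comp.observed_curve.n0 == 30
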