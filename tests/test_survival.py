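import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

import beetox as bt
from conftest import arm_records, make_group


def textbook_weighted_logrank(t1, e1, t2, e2, rho):
    """Independent plain-loop G^rho statistic (O-E with hypergeometric
    variance, weights = pooled product-limit left limit ** rho)."""
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    grp = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    score, var, s_pool = 0.0, 0.0, 1.0
    for ut in sorted(set(t)):
        at = t >= ut
        n = at.sum()
        n1 = (at & (grp == 0)).sum()
        d = ((t == ut) & (e == 1)).sum()
        d1 = ((t == ut) & (e == 1) & (grp == 0)).sum()
        w = s_pool**rho
        if d > 0:
            score += w * (d1 - n1 * d / n)
            if n > 1:
                var += w**2 * d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        s_pool *= 1 - d / n
    return score / np.sqrt(var) if var > 0 else 0.0


class TestKaplanMeier:
    def test_all_censored_curve_is_flat_one(self):
        curve = bt.kaplan_meier(make_group([(96.0, 0)] * 10))
        assert curve.probability_at(96.0) == 1.0
        assert curve.n0 == 10

    def test_single_event_time(self):
        curve = bt.kaplan_meier(make_group([(24.0, 1)] * 2 + [(96.0, 0)] * 8))
        assert curve.probability_at(24.0) == pytest.approx(0.8)
        assert curve.probability_at(96.0) == pytest.approx(0.8)

    def test_hand_computed_product_limit(self):
        # deaths at 3, 24, 48 h with censorings at 24 and 96 h:
        # 4/5 * 3/4 * 1/2 ... constructed so S(48) = 4/5 * 3/4 * 2/3 = 0.4
        records = make_group([(3.0, 1), (24.0, 1), (48.0, 1), (48.0, 0), (96.0, 0)])
        curve = bt.kaplan_meier(records)
        assert curve.probability_at(3.0) == pytest.approx(4 / 5)
        assert curve.probability_at(24.0) == pytest.approx(4 / 5 * 3 / 4)
        assert curve.probability_at(96.0) == pytest.approx(4 / 5 * 3 / 4 * 2 / 3)

    def test_matches_lifelines(self, osmia_dataset):
        _, records = osmia_dataset
        group = arm_records(records, "SUL", 44.0)
        curve = bt.kaplan_meier(group)
        kmf = KaplanMeierFitter().fit(
            [r.last_time for r in group], [r.event for r in group]
        )
        for t in (3.0, 24.0, 48.0, 72.0, 96.0):
            assert curve.probability_at(t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-12
            )

    def test_no_censoring_equals_empirical_survival(self):
        times = [3.0, 3.0, 24.0, 48.0, 72.0, 96.0]
        records = make_group([(t, 1) for t in times])
        curve = bt.kaplan_meier(records)
        for t in (3.0, 24.0, 96.0):
            empirical = np.mean([x > t for x in times])
            assert curve.probability_at(t) == pytest.approx(empirical)

    def test_curve_invariants(self, osmia_dataset):
        _, records = osmia_dataset
        curve = bt.kaplan_meier(arm_records(records, "SUL_FLU", 44.0))
        surv = np.asarray(curve.survival)
        assert np.all(np.diff(surv) <= 0)
        assert np.all((surv >= 0) & (surv <= 1))
        assert np.all(np.diff(curve.at_risk) <= 0)
        assert all(d <= n for d, n in zip(curve.events, curve.at_risk))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bt.kaplan_meier([])


class TestFHWeightedLogrank:
    def test_identical_groups_give_zero_statistic(self):
        group = make_group([(3.0, 1), (24.0, 1), (96.0, 0), (96.0, 0)])
        res = bt.fh_weighted_logrank(group, list(group), rho=1.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("rho", [0.0, 1.0])
    def test_matches_textbook_oracle_on_random_fixtures(self, rho):
        rng = np.random.default_rng(7)
        grid = np.array([3.0, 24.0, 48.0, 72.0, 96.0])
        for _ in range(20):
            n1, n2 = rng.integers(5, 30, size=2)
            t1, t2 = rng.choice(grid, n1), rng.choice(grid, n2)
            e1, e2 = rng.integers(0, 2, n1), rng.integers(0, 2, n2)
            if e1.sum() + e2.sum() == 0:
                continue
            a = make_group(zip(t1, e1))
            b = make_group(zip(t2, e2))
            z = bt.fh_weighted_logrank(a, b, rho=rho).statistic
            z_oracle = textbook_weighted_logrank(t1, e1, t2, e2, rho)
            assert z == pytest.approx(z_oracle, abs=1e-10)

    def test_rho0_chi2_matches_lifelines(self):
        rng = np.random.default_rng(11)
        grid = np.array([3.0, 24.0, 48.0, 72.0, 96.0])
        t1, t2 = rng.choice(grid, 15), rng.choice(grid, 20)
        e1, e2 = rng.integers(0, 2, 15), rng.integers(0, 2, 20)
        res = bt.fh_weighted_logrank(make_group(zip(t1, e1)), make_group(zip(t2, e2)))
        ref = logrank_test(t1, t2, e1, e2)
        assert res.statistic**2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert res.p_value == pytest.approx(ref.p_value, abs=1e-8)

    def test_label_symmetry(self, osmia_dataset):
        _, records = osmia_dataset
        a = arm_records(records, "SUL", 11.0)
        b = arm_records(records, "SUL", 44.0)
        fwd = bt.fh_weighted_logrank(a, b, rho=1.0)
        back = bt.fh_weighted_logrank(b, a, rho=1.0)
        assert fwd.statistic == pytest.approx(-back.statistic, abs=1e-12)
        assert fwd.p_value == pytest.approx(back.p_value, abs=1e-12)

    def test_one_sided_alternative_direction(self):
        # group a dies strictly earlier: one-sided p (observed_less) is
        # smaller than the two-sided p
        early = make_group([(3.0, 1)] * 8 + [(96.0, 0)] * 2)
        late = make_group([(72.0, 1)] * 2 + [(96.0, 0)] * 8)
        one = bt.fh_weighted_logrank(early, late, alternative="observed_less")
        two = bt.fh_weighted_logrank(early, late)
        assert one.statistic > 0
        assert one.p_value < two.p_value

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bt.fh_weighted_logrank([], make_group([(96.0, 0)]))

    @pytest.mark.parametrize("rho", [0.0, 1.0])
    def test_type_i_error_under_exchangeability(self, rho):
        """Two groups drawn from one scenario arm reject at ~5%."""
        rejections = 0
        n_rep = 500
        for i in range(n_rep):
            scenario = bt.reference_scenario("osmia", seed=60000 + i)
            records = bt.simulate_bioassay(scenario)
            arm = arm_records(records, "SUL", 11.0)
            half = len(arm) // 2
            res = bt.fh_weighted_logrank(arm[:half], arm[half:], rho=rho)
            rejections += res.p_value < 0.05
        assert abs(rejections / n_rep - 0.05) <= 0.02


class TestOmnibusAndPairwise:
    def test_fourteen_groups_give_df_13(self, osmia_dataset):
        _, records = osmia_dataset
        groups = {}
        for arm in ("CONTROL", "SOLVENT", "FLU"):
            groups[arm] = arm_records(records, arm)
        for dose in (2.75, 5.5, 11.0, 22.0, 44.0, 88.0):
            groups[f"SUL_{dose:g}"] = arm_records(records, "SUL", dose)
        for dose in (2.75, 5.5, 11.0, 22.0, 44.0):
            groups[f"MIX_{dose:g}"] = arm_records(records, "SUL_FLU", dose)
        assert len(groups) == 14
        res = bt.omnibus_logrank(groups)
        assert res.df == 13
        assert res.p_value < 0.05  # dose-dependent mortality present

    def test_two_identical_groups_statistic_near_zero(self):
        group = make_group([(24.0, 1)] * 3 + [(96.0, 0)] * 7)
        res = bt.omnibus_logrank({"a": group, "b": list(group)})
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            bt.omnibus_logrank({"a": make_group([(96.0, 0)])})

    def test_omnibus_consistent_with_pairwise_on_separated_groups(self):
        """With clearly ordered groups the omnibus detects what every
        pairwise comparison detects."""
        g1 = make_group([(3.0, 1)] * 10)
        g2 = make_group([(48.0, 1)] * 10)
        g3 = make_group([(96.0, 0)] * 10)
        groups = {"early": g1, "mid": g2, "late": g3}
        omni = bt.omnibus_logrank(groups)
        mat = bt.pairwise_logrank_holm(groups)
        assert omni.p_value < 0.001
        assert mat.loc["early", "late"] < 0.05
        assert mat.loc["early", "mid"] < 0.05

    def test_two_groups_adjusted_equals_raw(self):
        a = make_group([(3.0, 1)] * 5 + [(96.0, 0)] * 5)
        b = make_group([(96.0, 0)] * 10)
        raw = bt.fh_weighted_logrank(a, b).p_value
        mat = bt.pairwise_logrank_holm({"a": a, "b": b})
        assert mat.loc["a", "b"] == pytest.approx(raw)

    def test_holm_step_down_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.04], method="holm")[1]
        assert adj == pytest.approx([0.03, 0.04, 0.04])

    def test_identical_groups_all_adjusted_p_one(self):
        g = make_group([(24.0, 1)] * 3 + [(96.0, 0)] * 7)
        mat = bt.pairwise_logrank_holm({"a": g, "b": list(g), "c": list(g)})
        off_diag = mat.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off_diag, 1.0)

    def test_adjusted_never_below_raw(self, osmia_dataset):
        _, records = osmia_dataset
        groups = {
            f"SUL_{d:g}": arm_records(records, "SUL", d)
            for d in (2.75, 11.0, 44.0, 176.0)
        }
        mat = bt.pairwise_logrank_holm(groups)
        for x in groups:
            for y in groups:
                if x == y:
                    continue
                raw = bt.fh_weighted_logrank(groups[x], groups[y]).p_value
                assert mat.loc[x, y] >= raw - 1e-12
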