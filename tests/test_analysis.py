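"""RT statistics: medians, paired t, Bonferroni, 2x2 interaction, Pearson."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from naplines.analysis import (
    accuracy_summary,
    bonferroni_flags,
    compute_medians,
    model_behavior_correlation,
    paired_t_one_tailed,
    rm_interaction_2x2,
    rt_diff_by_triplet,
    rt_summary,
)


def medians_frame(mp, nap, condition="c"):
    """MedianTable with given per-participant cell medians."""
    rows = []
    for p, (a, b) in enumerate(zip(mp, nap)):
        rows.append((p, condition, "metric", a, 1))
        rows.append((p, condition, "nonaccidental", b, 1))
    return pd.DataFrame(
        rows, columns=["participant", "condition", "variant_changed",
                       "median_rt", "n_trials_used"])


def responses_frame(cells):
    """cells: dict (participant, condition, variant) -> list of RT."""
    rows = []
    for (p, c, v), rts in cells.items():
        for rt in rts:
            rows.append((p, c, v, rt, True))
    return pd.DataFrame(rows, columns=["participant", "condition",
                                       "variant_changed", "rt", "correct"])


class TestComputeMedians:
    def test_odd_and_even_cell_conventions(self):
        resp = responses_frame({
            (0, "c", "metric"): [400.0, 500.0, 600.0],
            (0, "c", "nonaccidental"): [400.0, 600.0],
        })
        med = compute_medians(resp, correct_only=False)
        by_v = med.set_index("variant_changed")["median_rt"]
        assert by_v["metric"] == 500.0
        assert by_v["nonaccidental"] == 500.0  # midpoint convention

    def test_correct_only_filter(self):
        resp = responses_frame({(0, "c", "metric"): [100.0, 900.0, 900.0],
                                (0, "c", "nonaccidental"): [500.0]})
        resp.loc[resp["rt"] == 100.0, "correct"] = False
        med = compute_medians(resp, correct_only=True)
        assert med.set_index("variant_changed")["median_rt"]["metric"] == 900.0

    def test_empty_cell_names_the_cell(self):
        resp = responses_frame({(0, "c", "metric"): [500.0],
                                (0, "c", "nonaccidental"): [500.0]})
        resp.loc[resp["variant_changed"] == "metric", "correct"] = False
        with pytest.raises(ValueError, match="metric"):
            compute_medians(resp, correct_only=True)


class TestPairedT:
    def test_hand_computed_example(self):
        # differences (10, 20, 30): t = 20 / (10 / sqrt(3)) = 3.4641, df 2
        med = medians_frame(mp=[510, 620, 730], nap=[500, 600, 700])
        r = paired_t_one_tailed(med, "c")
        assert r.statistic == pytest.approx(20 / (10 / math.sqrt(3)), abs=1e-9)
        assert r.df == 2
        assert r.p == pytest.approx(float(stats.t.sf(r.statistic, 2)), abs=1e-12)

    def test_agrees_with_scipy_oracle_on_random_data(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(3, 15))
            mp = rng.normal(900, 80, n)
            nap = rng.normal(850, 80, n)
            r = paired_t_one_tailed(medians_frame(mp, nap), "c")
            t_ref, p_ref = stats.ttest_rel(mp, nap, alternative="greater")
            assert r.statistic == pytest.approx(float(t_ref), abs=1e-10)
            assert r.p == pytest.approx(float(p_ref), abs=1e-10)

    def test_degenerate_all_equal(self):
        med = medians_frame(mp=[500, 600, 700], nap=[500, 600, 700])
        r = paired_t_one_tailed(med, "c")
        assert (r.statistic, r.p) == (0.0, 0.5)

    def test_degenerate_zero_variance_nonzero_mean(self):
        med = medians_frame(mp=[510, 610, 710], nap=[500, 600, 700])
        r = paired_t_one_tailed(med, "c")
        assert math.isinf(r.statistic) and r.p == 0.0

    def test_too_few_participants(self):
        with pytest.raises(ValueError, match="2 participants"):
            paired_t_one_tailed(medians_frame([500], [400]), "c")

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=10),
           st.floats(-200, 200))
    def test_shift_invariance(self, diffs, shift):
        """Adding a constant to both cells leaves the paired t unchanged."""
        nap = np.linspace(500, 900, len(diffs))
        mp = nap + np.asarray(diffs)
        r1 = paired_t_one_tailed(medians_frame(mp, nap), "c")
        r2 = paired_t_one_tailed(medians_frame(mp + shift, nap + shift), "c")
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9, abs=1e-9)


class TestBonferroni:
    def _result(self, p):
        med = medians_frame([510, 621, 732], [500, 600, 700])
        r = paired_t_one_tailed(med, "c")
        return r.__class__(**{**r.__dict__, "p": p})

    def test_threshold_over_13_conditions(self):
        # p = .005 fails the 0.05/13 = 0.003846 criterion; p = .001 passes
        rs = bonferroni_flags([self._result(0.005), self._result(0.001)],
                              alpha=0.05, n_comparisons=13)
        assert rs[0].significant_bonferroni is False
        assert rs[1].significant_bonferroni is True

    def test_boundary_is_strict(self):
        rs = bonferroni_flags([self._result(0.05 / 13)], 0.05, 13)
        assert rs[0].significant_bonferroni is False

    def test_flag_count_never_exceeds_uncorrected(self, rng):
        ps = rng.random(13)
        rs = bonferroni_flags([self._result(p) for p in ps], 0.05, 13)
        n_corr = sum(r.significant_bonferroni for r in rs)
        n_unc = sum(r.p < 0.05 for r in rs)
        assert n_corr <= n_unc

    def test_too_many_results_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_flags([self._result(0.1)] * 5, n_comparisons=3)


def two_condition_medians(rng, n=10):
    frames = []
    for cond in ("a", "b"):
        mp = rng.normal(900, 60, n)
        nap = rng.normal(850, 60, n)
        frames.append(medians_frame(mp, nap, cond))
    return pd.concat(frames, ignore_index=True)


class TestInteraction:
    def test_equals_t_squared_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            med = two_condition_medians(rng)
            r = rm_interaction_2x2(med, "a", "b")
            wide = med.pivot_table(index="participant",
                                   columns=["condition", "variant_changed"],
                                   values="median_rt")
            dod = ((wide[("a", "metric")] - wide[("a", "nonaccidental")])
                   - (wide[("b", "metric")] - wide[("b", "nonaccidental")]))
            t_ref, p_ref = stats.ttest_rel(
                wide[("a", "metric")] - wide[("a", "nonaccidental")],
                wide[("b", "metric")] - wide[("b", "nonaccidental")])
            assert r.statistic == pytest.approx(float(t_ref) ** 2, abs=1e-9)
            assert r.p == pytest.approx(float(p_ref), abs=1e-9)
            assert r.df == (1, 9)

    def test_agrees_with_statsmodels_anova_rm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(99)
        med = two_condition_medians(rng, n=8)
        r = rm_interaction_2x2(med, "a", "b")
        long = med.rename(columns={"condition": "cond",
                                   "variant_changed": "distance"})
        res = AnovaRM(long, depvar="median_rt", subject="participant",
                      within=["cond", "distance"]).fit()
        row = res.anova_table.loc["cond:distance"]
        assert r.statistic == pytest.approx(row["F Value"], abs=1e-8)
        assert r.p == pytest.approx(row["Pr > F"], abs=1e-8)

    def test_zero_difference_of_differences(self):
        med = pd.concat([medians_frame([510, 620, 730], [500, 600, 700], "a"),
                         medians_frame([510, 620, 730], [500, 600, 700], "b")],
                        ignore_index=True)
        r = rm_interaction_2x2(med, "a", "b")
        assert r.statistic == 0.0 and r.p == 1.0

    def test_self_comparison_is_zero(self):
        med = medians_frame([510, 620, 730], [500, 580, 720], "a")
        r = rm_interaction_2x2(med, "a", "a")
        assert r.statistic == 0.0


class TestAccuracySummary:
    def test_all_correct(self):
        resp = responses_frame({(0, "a", "metric"): [1.0] * 4,
                                (0, "a", "nonaccidental"): [1.0] * 4})
        acc = accuracy_summary(resp)
        assert (acc["accuracy"] == 1.0).all()
        assert (acc["se"] == 0.0).all()

    def test_shape_with_margins(self, stimulus_set):
        import naplines.observer as obs
        from naplines.experiment import build_trial_table

        trials = build_trial_table(stimulus_set, rng=np.random.default_rng(0))
        resp = obs.simulate_responses(trials, obs.ObserverParams(seed=1),
                                      stimulus_set=stimulus_set)
        acc = accuracy_summary(resp)
        assert len(acc) == 2 * 13 + 2
        margins = acc[acc["condition"] == "(all)"]
        assert set(margins["variant_changed"]) == {"metric", "nonaccidental"}


class TestModelBehaviorCorrelation:
    def _tables(self, x, y):
        ids = [f"t{i}" for i in range(len(x))]
        audit = pd.DataFrame({"triplet_id": ids,
                              "sim_nap_base": 0.9 + np.asarray(x),
                              "sim_mp_base": 0.9})
        rt = pd.DataFrame({"triplet_id": ids,
                           "rt_diff_nap_minus_mp": np.asarray(y)})
        return rt, audit

    def test_perfect_correlation(self):
        x = np.linspace(-0.05, 0.05, 20)
        r, p = model_behavior_correlation(*self._tables(x, x))
        assert r == pytest.approx(1.0)

    def test_independent_near_zero(self, rng):
        x = rng.normal(0, 0.02, 4000)
        y = rng.normal(0, 30, 4000)
        r, _ = model_behavior_correlation(*self._tables(x, y))
        assert abs(r) < 0.05

    def test_covariance_formula_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(0, 0.02, 78)
            y = rng.normal(-20, 30, 78)
            r, p = model_behavior_correlation(*self._tables(x, y))
            xc, yc = x - x.mean(), y - y.mean()
            r_ref = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
            assert r == pytest.approx(r_ref, abs=1e-12)
            # two-tailed p from the exact t transform with df = n - 2
            t = r_ref * math.sqrt(76 / (1 - r_ref**2))
            assert p == pytest.approx(2 * float(stats.t.sf(abs(t), 76)),
                                      rel=1e-9)

    def test_sign_convention_flips_r(self):
        x = np.linspace(-0.05, 0.05, 20)
        rt, audit = self._tables(x, x)
        r1, _ = model_behavior_correlation(rt, audit, "nap_minus_mp")
        r2, _ = model_behavior_correlation(rt, audit, "mp_minus_nap")
        assert r1 == pytest.approx(-r2)

    def test_constant_vector_rejected(self):
        x = np.zeros(10)
        with pytest.raises(ValueError, match="constant"):
            model_behavior_correlation(*self._tables(x, x))


def test_rt_summary_and_diff_tables(stimulus_set):
    import naplines.observer as obs
    from naplines.experiment import build_trial_table

    trials = build_trial_table(stimulus_set, rng=np.random.default_rng(0))
    resp = obs.simulate_responses(trials, obs.ObserverParams(seed=2),
                                  stimulus_set=stimulus_set)
    med = compute_medians(resp)
    summ = rt_summary(med)
    assert len(summ) == 26  # 13 conditions x 2 variants
    assert (summ["n_participants"] == 10).all()
    diff = rt_diff_by_triplet(resp)
    assert len(diff) == 78
    # the generating advantage makes NAP trials faster on average
    assert diff["rt_diff_nap_minus_mp"].mean() < 0
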