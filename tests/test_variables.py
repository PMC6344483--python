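import itertools
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from goodspace import variables as V
from conftest import make_trial


FIT = SimpleNamespace(rho=2.5, xi=0.2)


class TestEvaluators:
    def test_offer_value_B_direct_substitution(self):
        t = make_trial(1, qA=1, qB=3, costA="high")  # B low cost
        assert V.evaluate_variable(2, t, FIT) == pytest.approx(3.2)

    def test_offer_value_A_uses_rho(self):
        t = make_trial(1, qA=2, qB=1, costA="low")
        assert V.evaluate_variable(1, t, FIT) == pytest.approx(2.5 * 2 + 0.2)

    def test_chosen_juice_binary(self):
        assert V.evaluate_variable(3, make_trial(1, chosen="B"), FIT) == 1.0
        assert V.evaluate_variable(3, make_trial(1, chosen="A"), FIT) == 0.0

    def test_cost_frame_values(self):
        t = make_trial(1, qA=1, qB=3, costA="low")  # A low cost, B high cost
        assert V.evaluate_variable(4, t, FIT) == pytest.approx(3.0)       # offer value -: B
        assert V.evaluate_variable(5, t, FIT) == pytest.approx(2.5 + 0.2)  # offer value +: A

    def test_spatial_congruence(self):
        congruent = make_trial(1, offerA_side="L", angleA=157.5)  # target A left
        incongruent = make_trial(1, offerA_side="R", angleA=157.5)
        assert V.evaluate_variable(18, congruent, FIT) == 1.0
        assert V.evaluate_variable(18, incongruent, FIT) == 0.0

    def test_chosen_value_follows_choice(self):
        t = make_trial(1, qA=1, qB=3, costA="high", chosen="B")
        assert V.evaluate_variable(19, t, FIT) == pytest.approx(3.2)
        t2 = make_trial(1, qA=1, qB=3, costA="high", chosen="A")
        assert V.evaluate_variable(19, t2, FIT) == pytest.approx(2.5)

    def test_cost_independent_variant_drops_xi(self):
        t = make_trial(1, qA=1, qB=3, costA="high")
        assert V.evaluate_variable(2, t, FIT, variant="independent") == pytest.approx(3.0)

    def test_variants_degenerate_when_xi_zero(self, small_session):
        fit0 = SimpleNamespace(rho=2.5, xi=0.0)
        for vid in (1, 2, 19):
            a = V.variable_values(vid, small_session, fit0, "affected")
            b = V.variable_values(vid, small_session, fit0, "independent")
            np.testing.assert_allclose(a, b)

    def test_catalog_covers_19_variables(self):
        assert len(V.CATALOG) == 19
        assert len(V.COLLAPSED) == 15  # four collapsed offer-value families


class TestRegression:
    def test_matches_closed_form_ols(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.9, 5.2, 6.8, 9.1, 10.9])
        res = V.regress_response(y, x, level="trial")
        # independent closed-form oracle
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        yhat = y.mean() + slope * (x - x.mean())
        sse = ((y - yhat) ** 2).sum()
        se = np.sqrt(sse / (len(x) - 2) / sxx)
        t = slope / se
        p = 2 * stats.t.sf(abs(t), len(x) - 2)
        r2 = 1 - sse / ((y - y.mean()) ** 2).sum()
        assert res.slope == pytest.approx(slope)
        assert res.p_slope == pytest.approx(p)
        assert res.r2_raw == pytest.approx(r2)

    def test_exact_linear_gives_unit_r2(self):
        x = np.arange(10.0)
        res = V.regress_response(2 * x + 1, x, level="trial")
        assert res.r2_effective == pytest.approx(1.0)

    def test_constant_variable_flagged(self):
        res = V.regress_response(np.arange(5.0), np.ones(5), level="trial")
        assert res.constant and res.r2_effective == 0.0

    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        hits = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            hits += V.regress_response(y, x, level="trial").explains
        frac = hits / reps
        assert 0.02 < frac < 0.09  # nominal 5%

    def test_type_level_grouping_averages_noise(self):
        rng = np.random.default_rng(1)
        keys = np.repeat(np.arange(10), 20)
        x = keys.astype(float)
        y = 2 * x + rng.normal(0, 5, size=x.size)
        trial_res = V.regress_response(y, x, level="trial")
        type_res = V.regress_response(y, x, group_keys=list(keys), level="type")
        assert type_res.n_points == 10
        assert type_res.r2_raw > trial_res.r2_raw


class TestCollapseAndBestFit:
    def _rr(self, r2, p=0.01):
        return V.RegressionResult(1.0, 0.0, p, r2, 10)

    def test_collapse_takes_max(self):
        r2, winner = V.collapse_r2({1: self._rr(0.3), 2: self._rr(0.6)})
        assert r2 == 0.6 and winner == 2

    def test_collapse_all_zero(self):
        r2, winner = V.collapse_r2({1: self._rr(0.3, p=0.5), 2: self._rr(0.0)})
        assert r2 == 0.0 and winner is None

    def test_single_component_identity(self):
        r2, winner = V.collapse_r2({3: self._rr(0.4)})
        assert r2 == 0.4 and winner == 3

    def test_best_fit_argmax(self):
        assert V.best_fit_assignment({"chosen juice": 0.4, "chosen value": 0.7}) == "chosen value"

    def test_best_fit_none_when_all_zero(self):
        assert V.best_fit_assignment({"chosen juice": 0.0}) is None


def random_instance(rng, n_resp=30, k=6, windows=("post_offer", "late_delay")):
    """Random collapsed-R2 table over k variables (zero-inflated R2 values)."""
    names = list(V.COLLAPSED_ORDER)[:k]
    rows = []
    for i in range(n_resp):
        w = windows[i % len(windows)]
        for name in names:
            r2 = 0.0 if rng.random() < 0.5 else float(rng.uniform(0.05, 0.9))
            rows.append({"neuron": f"n{i}", "window": w, "collapsed": name,
                         "variable_id": 1, "slope": 1.0, "p_slope": 0.01,
                         "r2_raw": r2, "r2_effective": r2})
    return pd.DataFrame(rows)


def brute_force_best_subset(df, windows, n, objective):
    """Independent enumeration oracle for the best-subset optimum."""
    piv = df[df.window.isin(windows)].pivot_table(
        index=["neuron", "window"], columns="collapsed", values="r2_effective",
        fill_value=0.0)
    cols = [c for c in V.COLLAPSED_ORDER if c in piv.columns]
    piv = piv[cols]
    best_key, best_set = None, None
    for combo in itertools.combinations(cols, n):
        sub = piv[list(combo)].to_numpy()
        best = sub.max(axis=1)
        power, count = float(best.sum()), int((best > 0).sum())
        key = (power, count) if objective == "total_r2" else (count, power)
        if best_key is None or key[0] > best_key[0] + 1e-12 or (
                abs(key[0] - best_key[0]) <= 1e-12 and key[1] > best_key[1] + 1e-12):
            best_key, best_set = key, set(combo)
    return best_key, best_set


class TestSelection:
    def test_single_dominant_variable(self):
        rng = np.random.default_rng(2)
        df = random_instance(rng, n_resp=20, k=5)
        # make one variable explain every response best
        df.loc[df.collapsed == "chosen juice", "r2_effective"] = 0.95
        df.loc[df.collapsed == "chosen juice", "r2_raw"] = 0.95
        sel = V.stepwise_selection(df, "pre_target", windows=("post_offer", "late_delay"))
        assert sel.selected[0] == "chosen juice"

    def test_stepwise_deterministic(self):
        rng = np.random.default_rng(3)
        df = random_instance(rng)
        a = V.stepwise_selection(df, "pre_target", windows=("post_offer", "late_delay"))
        b = V.stepwise_selection(df, "pre_target", windows=("post_offer", "late_delay"))
        assert a.selected == b.selected and a.trace == b.trace

    def test_stepwise_score_trace_monotone(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            df = random_instance(rng, n_resp=40, k=8)
            sel = V.stepwise_selection(df, "pre_target",
                                       windows=("post_offer", "late_delay"),
                                       stop_fraction=0.0)
            scores = [s["best_fits_max_window"] for s in sel.trace]
            assert scores == sorted(scores, reverse=True)

    def test_empty_selection(self):
        df = random_instance(np.random.default_rng(5), n_resp=0)
        sel = V.stepwise_selection(df, "pre_target")
        assert sel.selected == [] and sel.n_responses == 0

    @pytest.mark.parametrize("objective", ["total_r2", "count"])
    def test_best_subset_matches_enumeration_oracle(self, objective):
        rng = np.random.default_rng(6)
        windows = ("post_offer", "late_delay")
        for _ in range(15):
            k = int(rng.integers(3, 8))
            df = random_instance(rng, n_resp=int(rng.integers(10, 40)), k=k)
            sel = V.best_subset_selection(df, "pre_target", windows=windows,
                                          stop_fraction=0.0, objective=objective)
            for step in sel.trace:
                key, members = brute_force_best_subset(df, windows, step["n"], objective)
                metric = step["power"] if objective == "total_r2" else step["explained"]
                assert metric == pytest.approx(key[0])

    def test_best_subset_dominates_stepwise(self):
        # optimality: size-n best subset has power >= first n stepwise picks
        rng = np.random.default_rng(7)
        windows = ("post_offer", "late_delay")
        for _ in range(10):
            df = random_instance(rng, n_resp=30, k=7)
            sw = V.stepwise_selection(df, "pre_target", windows=windows, stop_fraction=0.0)
            bs = V.best_subset_selection(df, "pre_target", windows=windows, stop_fraction=0.0)
            piv = df.pivot_table(index=["neuron", "window"], columns="collapsed",
                                 values="r2_effective", fill_value=0.0)
            for step in bs.trace:
                n = step["n"]
                if n > len(sw.selected):
                    break
                sw_power = float(piv[sw.selected[:n]].max(axis=1).sum())
                assert step["power"] >= sw_power - 1e-9

    def test_full_catalog_explains_everything(self):
        rng = np.random.default_rng(8)
        df = random_instance(rng, n_resp=25, k=6)
        sel = V.best_subset_selection(df, "pre_target",
                                      windows=("post_offer", "late_delay"),
                                      stop_fraction=0.0)
        piv = df.pivot_table(index=["neuron", "window"], columns="collapsed",
                             values="r2_effective", fill_value=0.0)
        explainable = int((piv.to_numpy().max(axis=1) > 0).sum())
        assert sel.trace[-1]["explained"] == explainable


class TestClassification:
    def test_single_variable_cell(self):
        rows = [{"neuron": "c1", "window": w, "collapsed": "chosen cost",
                 "variable_id": 6, "slope": 2.0, "p_slope": 0.001,
                 "r2_raw": 0.5, "r2_effective": 0.5}
                for w in ("post_offer", "pre_go")]
        cls = V.classify_cells(pd.DataFrame(rows), ["chosen cost", "chosen juice"])
        row = cls.table.iloc[0]
        assert row.assigned == "chosen cost"
        assert row.encoded_level == "low"  # positive slope on 1[low-cost chosen]

    def test_negative_slope_flips_encoded_juice(self):
        rows = [{"neuron": "c1", "window": "post_offer", "collapsed": "chosen juice",
                 "variable_id": 3, "slope": -3.0, "p_slope": 0.001,
                 "r2_raw": 0.6, "r2_effective": 0.6}]
        cls = V.classify_cells(pd.DataFrame(rows), ["chosen juice"])
        assert cls.table.iloc[0].encoded_level == "A"

    def test_unclassified_when_all_zero(self):
        rows = [{"neuron": "c1", "window": "post_offer", "collapsed": "chosen juice",
                 "variable_id": 3, "slope": 0.0, "p_slope": 0.9,
                 "r2_raw": 0.1, "r2_effective": 0.0}]
        cls = V.classify_cells(pd.DataFrame(rows), ["chosen juice"])
        assert cls.table.iloc[0].assigned is None

    def test_tie_flagged_and_deterministic(self):
        rows = []
        for name in ("chosen juice", "chosen cost"):
            rows.append({"neuron": "c1", "window": "post_offer", "collapsed": name,
                         "variable_id": 3, "slope": 1.0, "p_slope": 0.001,
                         "r2_raw": 0.5, "r2_effective": 0.5})
        cls = V.classify_cells(pd.DataFrame(rows), ["chosen juice", "chosen cost"])
        row = cls.table.iloc[0]
        assert row.tie
        assert row.assigned == "chosen juice"  # catalog order
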