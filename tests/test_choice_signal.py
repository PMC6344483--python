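import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from goodspace import choice_signal as cs
from goodspace import synth
from conftest import make_session


def _pair_trials(qA, qB, choices_low, choices_high):
    """Trials for one quantity pair: lists of choices per cost configuration."""
    out = []
    for c in choices_low:
        out.append(dict(qA=qA, qB=qB, costA="low", chosen=c))
    for c in choices_high:
        out.append(dict(qA=qA, qB=qB, costA="high", chosen=c))
    return out


class TestCostOvertLabeling:
    def test_overt_rule(self):
        # pA_low = 8/10, pA_high = 5/10, both options chosen >= 2 times
        s = make_session(_pair_trials(1, 1, ["A"] * 8 + ["B"] * 2, ["A"] * 5 + ["B"] * 5))
        lab = cs.label_cost_overt(s)
        assert lab.iloc[0].label == "overt"

    def test_consistent_choice_is_covert(self):
        s = make_session(_pair_trials(4, 1, ["A"] * 10, ["A"] * 10))
        lab = cs.label_cost_overt(s)
        assert lab.iloc[0].label == "covert"

    def test_rare_option_insufficient(self):
        # shift > 10% but B chosen only once overall
        s = make_session(_pair_trials(1, 1, ["A"] * 10, ["A"] * 8 + ["B"]))
        lab = cs.label_cost_overt(s)
        assert lab.iloc[0].label == "insufficient"

    def test_single_configuration_insufficient(self):
        s = make_session(_pair_trials(1, 2, ["A", "B", "A", "B"], []))
        lab = cs.label_cost_overt(s)
        assert lab.iloc[0].label == "insufficient"

    def test_wrong_direction_shift_not_overt(self):
        # low-cost A chosen LESS often: shift is negative, cannot be overt
        s = make_session(_pair_trials(1, 1, ["A"] * 5 + ["B"] * 5, ["A"] * 8 + ["B"] * 2))
        lab = cs.label_cost_overt(s)
        assert lab.iloc[0].label != "overt"


class TestSDF:
    def test_no_spikes_zero_profile(self):
        _, rate = cs.sdf(np.empty(0), (0.0, 2.0))
        assert np.all(rate == 0)

    def test_single_spike_peak(self):
        # Gaussian kernel peak: 1/(sigma*sqrt(2*pi)) with sigma = 40 ms
        _, rate = cs.sdf(np.array([1.0]), (0.0, 2.0))
        assert rate.max() == pytest.approx(1 / (0.040 * np.sqrt(2 * np.pi)), rel=1e-3)

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0.3, 4.7, size=200))
        _, rate = cs.sdf(spikes, (0.0, 5.0))
        integral = rate.sum() * 0.001
        assert integral == pytest.approx(200, rel=1e-3)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            cs.sdf(np.empty(0), (1.0, 1.0))


class TestNormalization:
    def test_arithmetic(self):
        out = cs.normalize_profile(np.array([15.0]), 5.0, 10.0)
        assert out[0] == pytest.approx(1.0)

    def test_constant_profile_maps_to_zero(self):
        out = cs.normalize_profile(np.full(10, 5.0), 5.0, 10.0)
        assert np.all(out == 0)

    def test_zero_divisor_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cs.normalize_profile(np.array([1.0]), 0.0, 0.0)


class TestAUC:
    @pytest.mark.parametrize("g1,g2,expected", [
        ([3, 3, 3], [3, 3], 0.5),       # all ties
        ([5, 6, 7], [1, 2, 3], 1.0),    # complete separation
        ([2, 3], [2, 5], 0.375),        # enumerated cross pairs
    ])
    def test_examples(self, g1, g2, expected):
        assert cs.auc(g1, g2) == pytest.approx(expected)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cs.auc([], [1])

    @given(st.lists(st.integers(0, 12), min_size=1, max_size=15),
           st.lists(st.integers(0, 12), min_size=1, max_size=15))
    def test_equals_mann_whitney_u(self, g1, g2):
        u = stats.mannwhitneyu(g1, g2).statistic
        assert cs.auc(g1, g2) == pytest.approx(u / (len(g1) * len(g2)))

    @given(st.lists(st.integers(0, 12), min_size=1, max_size=15),
           st.lists(st.integers(0, 12), min_size=1, max_size=15))
    def test_antisymmetry(self, g1, g2):
        assert cs.auc(g1, g2) == pytest.approx(1 - cs.auc(g2, g1))

    def test_roc_windows_partition(self):
        bounds = sorted(cs.ROC_WINDOWS.values())
        assert bounds[0][0] == 0.0 and bounds[-1][1] == 0.75
        for (a, b), (c, d) in zip(bounds, bounds[1:]):
            assert b == c  # contiguous, non-overlapping


@pytest.fixture(scope="module")
def cj_session():
    """Session with chosen-juice neurons (preferring B) and untuned neurons."""
    cfg = synth.GeneratorConfig(seed=23, trials_per_condition=10)
    s = synth.generate_session(cfg)
    slope = synth.slope_for_snr(2.0, 20.0, 1.0)
    rng = np.random.default_rng(5)
    for k in range(6):
        spec = synth.NeuronSpec(f"cj{k}", "chosen juice", 20.0, slope, 1,
                                ("post_offer", "late_delay"))
        s.add_neuron(f"cj{k}", synth.generate_neuron(spec, s, cfg, rng.spawn(1)[0]))
    for k in range(6):
        spec = synth.NeuronSpec(f"u{k}", baseline_rate=20.0)
        s.add_neuron(f"u{k}", synth.generate_neuron(spec, s, cfg, rng.spawn(1)[0]))
    return s, cs.label_cost_overt(s)


class TestChoiceProbability:
    def test_tuned_cells_above_chance(self, cj_session):
        s, labels = cj_session
        aucs = [cs.cell_choice_probability(s, f"cj{k}", "post_offer_2", labels,
                                           "B", "chosen juice").mean_auc
                for k in range(6)]
        out = cs.population_auc_test(aucs)
        assert out["mean_auc"] > 0.5 and out["p_vs_half"] < 0.05

    def test_mean_is_mean_of_offer_types(self, cj_session):
        s, labels = cj_session
        res = cs.cell_choice_probability(s, "cj0", "post_offer_1", labels,
                                         "B", "chosen juice")
        assert res.mean_auc == pytest.approx(np.mean(list(res.per_offer_type.values())))
        assert res.n_offer_types == len(res.per_offer_type)

    def test_no_overt_pairs_returns_none(self, cj_session):
        s, _ = cj_session
        labels = cs.label_cost_overt(s)
        labels["label"] = "covert"
        assert cs.cell_choice_probability(s, "cj0", "post_offer_1", labels,
                                          "B", "chosen juice") is None

    def test_population_test_degenerate_inputs(self):
        out = cs.population_auc_test([0.5, 0.5, 0.5])
        assert out["mean_auc"] == 0.5 and out["p_vs_half"] == 1.0
        with pytest.raises(ValueError):
            cs.population_auc_test([0.5, 0.6])


class TestGroupTraces:
    def test_tuned_cell_trace_separation(self, cj_session):
        s, labels = cj_session
        gt = cs.group_traces(s, "cj0", "B", labels)
        assert gt.included
        grid = gt.grids["offer_on"]
        post = (grid > 0.1) & (grid < 1.0)
        tr = gt.traces["offer_on"]
        assert tr["Eo"][post].mean() > tr["Oo"][post].mean()
        assert tr["Ec"][post].mean() > tr["Oc"][post].mean()

    def test_insufficient_trials_excluded(self, cj_session):
        s, labels = cj_session
        # forcing every pair overt leaves the covert groups empty
        forced = labels.copy()
        forced["label"] = "overt"
        gt = cs.group_traces(s, "cj0", "B", forced)
        assert not gt.included

    def test_untuned_traces_flat(self, cj_session):
        s, labels = cj_session
        gt = cs.group_traces(s, "u0", "B", labels)
        assert gt.included
        tr = gt.traces["offer_on"]
        sep = abs(tr["Eo"].mean() - tr["Oo"].mean())
        assert sep < 0.2

    def test_population_average(self, cj_session):
        s, labels = cj_session
        cells = [cs.group_traces(s, f"cj{k}", "B", labels) for k in range(3)]
        pop = cs.population_traces(cells)
        assert set(pop) == {"offer_on", "target_on", "juice"}
        assert set(pop["offer_on"]) == set(cs.TRACE_GROUPS)
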