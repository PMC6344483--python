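from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from goodspace import behavior, integration as integ, screen as scr, synth
from goodspace import variables as V


@pytest.fixture(scope="module")
def cv_setup():
    """Session + fit + 12 chosen-value neurons per variant regime."""
    cfg = synth.GeneratorConfig(seed=31, trials_per_condition=25)
    base = synth.generate_session(cfg)
    fit = behavior.fit_choice_model(base)
    vr = float(np.ptp(V.variable_values(19, base, cfg)))
    slope = synth.slope_for_snr(2.0, 20.0, vr)
    return cfg, base, fit, slope


def _cv_cohort(cfg, slope, mode, n=12, seed=100):
    s = synth.generate_session(cfg)
    rng = np.random.default_rng(seed)
    ids = []
    for k in range(n):
        nid = f"cv{k}"
        if mode == "late":
            spec = synth.NeuronSpec(nid, "chosen value", 20.0, slope, 1, (),
                                    window_overrides={
                                        "post_offer": ("chosen value", "independent"),
                                        "post_target": ("chosen value", "affected")})
        else:
            spec = synth.NeuronSpec(nid, "chosen value", 20.0, slope, 1,
                                    ("post_offer", "post_target"), variant=mode)
        s.add_neuron(nid, synth.generate_neuron(spec, s, cfg, rng.spawn(1)[0]))
        ids.append(nid)
    return s, ids


class TestUnbiasedIdentification:
    def test_max_of_variants_assigned(self, cv_setup):
        cfg, base, fit, slope = cv_setup
        s, ids = _cv_cohort(cfg, slope, "affected", n=8)
        m = scr.build_response_matrix(s, ids)
        responses = [(i, "post_offer") for i in ids]
        vt = integ.variant_r2_table(s, m, fit, responses)
        cv = vt[vt.collapsed == "chosen value"]
        assert (cv.r2_unbiased >= cv[["r2_affected", "r2_independent"]].min(axis=1) - 1e-12).all()

    def test_recovers_family(self, cv_setup):
        cfg, base, fit, slope = cv_setup
        s, ids = _cv_cohort(cfg, slope, "affected", n=8)
        m = scr.build_response_matrix(s, ids)
        responses = [(i, "post_offer") for i in ids]
        vt = integ.variant_r2_table(s, m, fit, responses)
        ident = integ.unbiased_identify(vt, "chosen value", ("post_offer",))
        assert len(ident) >= 4  # most cells identified as chosen value


class TestDeltaR2:
    def test_zero_deltas_give_p_one(self):
        df = pd.DataFrame({"delta_r2": np.zeros(10)})
        out = integ.delta_r2_population(df)
        assert out["mean_delta_r2"] == 0.0 and out["p_signed_rank"] == 1.0

    def test_insufficient_n(self):
        with pytest.raises(ValueError):
            integ.delta_r2_population(pd.DataFrame({"delta_r2": [0.1] * 3}))

    def test_xi_zero_degeneracy(self, small_session):
        # with xi fixed to 0 the cost variants coincide, so dR2 vanishes
        fit0 = SimpleNamespace(rho=2.5, xi=0.0)
        cfg = synth.GeneratorConfig(seed=3, trials_per_condition=10)
        s = synth.generate_session(cfg)
        spec = synth.NeuronSpec("n", "chosen value", 20.0, 2.0, 1, ("post_offer",))
        s.add_neuron("n", synth.generate_neuron(spec, s, cfg, 1))
        m = scr.build_response_matrix(s, ["n"])
        vt = integ.variant_r2_table(s, m, fit0, [("n", "post_offer")])
        cv = vt[vt.collapsed.isin(["offer value (juice)", "chosen value"])]
        np.testing.assert_allclose(cv.r2_affected, cv.r2_independent, atol=1e-10)


class TestEpochContrast:
    def test_identical_epochs(self):
        d = np.array([0.01, -0.02, 0.005, 0.0, 0.03])
        out = integ.epoch_contrast(d, d)
        assert out["difference"] == 0.0 and out["p_ranksum"] > 0.9

    def test_single_response_rejected(self):
        with pytest.raises(ValueError):
            integ.epoch_contrast(np.array([0.1]), np.array([0.2]))


class TestAncova:
    def test_single_group_reduces_to_regression(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 5, 40)
        y = 2 * x + rng.normal(0, 1, 40)
        res = integ.ancova_parallel(y, x, np.repeat("g", 40))
        ref = V.regress_response(y, x, level="trial")
        assert res.slope == pytest.approx(ref.slope)
        assert res.slope_p == pytest.approx(ref.p_slope)
        assert np.isnan(res.group_p)

    def test_offset_groups_recovered(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 5, 40)
        g = np.array(["low", "high"] * 20)
        y = 1.0 * x + 2.0 * (g == "high") + rng.normal(0, 0.8, 40)
        res = integ.ancova_parallel(y, x, g)
        assert res.group_p < 0.05
        assert res.intercepts["high"] - res.intercepts["low"] == pytest.approx(2.0, abs=0.8)
        assert res.slope == pytest.approx(1.0, abs=0.3)

    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.uniform(0, 5, 40)
            g = np.array(["a", "b"] * 20)
            y = x + rng.normal(0, 1, 40)
            hits += integ.ancova_parallel(y, x, g).group_p < 0.05
        assert 0.01 < hits / reps < 0.11

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            integ.ancova_parallel(np.arange(5.0), np.arange(5.0),
                                  np.array(["a", "a", "a", "a", "b"]))


class TestVariantRegimes:
    """The dissociation logic on small cohorts (full sizes in acceptance)."""

    def test_always_integrated_positive_delta(self, cv_setup):
        cfg, base, fit, slope = cv_setup
        s, ids = _cv_cohort(cfg, slope, "affected", seed=200)
        m = scr.build_response_matrix(s, ids)
        responses = [(i, w) for i in ids for w in ("post_offer", "post_target")]
        vt = integ.variant_r2_table(s, m, fit, responses)
        ident = integ.unbiased_identify(vt, "chosen value", ("post_offer", "post_target"))
        assert ident.delta_r2.mean() > 0

    def test_never_integrated_nonpositive_delta(self, cv_setup):
        cfg, base, fit, slope = cv_setup
        s, ids = _cv_cohort(cfg, slope, "independent", seed=201)
        m = scr.build_response_matrix(s, ids)
        responses = [(i, w) for i in ids for w in ("post_offer", "post_target")]
        vt = integ.variant_r2_table(s, m, fit, responses)
        ident = integ.unbiased_identify(vt, "chosen value", ("post_offer", "post_target"))
        assert ident.delta_r2.mean() <= 0.005
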