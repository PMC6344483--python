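"""Seeded ground-truth recovery benchmarks for the whole pipeline.

Each function generates synthetic data at stated study conditions (generating
indices a0=2, rho=2.5, xi=0.25, eta=0.2; Poisson neurons at SNR
slope*range/sqrt(baseline) = 2 on a 20 spikes/s baseline), runs the relevant
stage of the analysis, and returns the recovery/calibration quantities.  All
randomness derives from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import behavior, choice_signal as cs, integration as integ
from . import screen as scr
from . import synth
from . import variables as V

__all__ = [
    "behavioral_recovery",
    "choice_pattern_direction",
    "anova_null_calibration",
    "selection_recovery",
    "roc_null_calibration",
    "roc_power",
    "delta_r2_regimes",
]

GEN = dict(a0=2.0, rho=2.5, xi=0.25, eta=0.2, phi=0.0, delta=0.0, eps=0.0)
TRUE_INDICES = dict(rho=2.5, xi=0.25, eta=0.2, phi=0.0, delta=0.0, eps=0.0)
BASELINE = 20.0
SNR = 2.0
PRE_TARGET_TUNING = ("post_offer", "late_delay", "mem_delay", "pre_target")


def _sessions(n_sessions: int, seed: int, trials_per_condition: int = 50):
    for k in range(n_sessions):
        cfg = synth.GeneratorConfig(**GEN, trials_per_condition=trials_per_condition,
                                    seed=seed + k, session_id=f"s{k}")
        yield synth.generate_session(cfg)


def behavioral_recovery(n_sessions: int = 50, seed: int = 1000) -> dict:
    """Fit the choice model on seeded 2000-trial sessions; score index recovery.

    Returns median bias per index and the population signed-rank summary.
    """
    fits = [behavior.fit_choice_model(s) for s in _sessions(n_sessions, seed)]
    biases = {}
    for name, truth in TRUE_INDICES.items():
        vals = np.array([f.indices()[name] for f in fits])
        biases[name] = float(np.median(vals) - truth)
    pop = behavior.population_summary(fits).set_index("index")
    return {"median_bias": biases,
            "population": {name: {"median": float(pop.loc[name, "median"]),
                                  "p": float(pop.loc[name, "p_signed_rank"])}
                           for name in behavior.INDEX_NAMES},
            "n_sessions": n_sessions}


def choice_pattern_direction(n_sessions: int = 50, seed: int = 1000) -> dict:
    """Fraction of sessions whose A-low-cost indifference point exceeds A-high-cost."""
    hits = 0
    for s in _sessions(n_sessions, seed):
        summ = behavior.summarize_choice_pattern(s)
        hits += summ.indifference_A_low > summ.indifference_A_high
    return {"fraction_positive_shift": hits / n_sessions, "n_sessions": n_sessions}


def anova_null_calibration(n_neurons: int = 200, seed: int = 2000,
                           trials_per_condition: int = 25, alpha: float = 0.001) -> dict:
    """Per-factor significant fraction of the ANOVA screen on untuned neurons."""
    cfg = synth.GeneratorConfig(**GEN, trials_per_condition=trials_per_condition,
                                seed=seed)
    s = synth.generate_session(cfg)
    rng = np.random.default_rng(seed + 1)
    ids = []
    for k in range(n_neurons):
        nid = f"u{k}"
        s.add_neuron(nid, synth.generate_neuron(
            synth.NeuronSpec(nid, baseline_rate=BASELINE), s, cfg, rng.spawn(1)[0]))
        ids.append(nid)
    matrix = scr.build_response_matrix(s, ids)
    relat = scr.anova_screen(matrix, s, alpha=alpha)
    n_responses = len(relat)
    out = {"n_responses": n_responses, "alpha": alpha, "factors": {}}
    for f in scr.FACTORS:
        n_sig = int((relat[f"p_{f}"] < alpha).sum())
        out["factors"][f] = {"n_significant": n_sig,
                             "fraction": n_sig / n_responses}
    out["task_related_fraction"] = float(relat["task_related"].mean())
    return out


SELECTION_VARIABLES = ("offer value A", "offer value -", "chosen value", "chosen juice")


def selection_cohort(seed: int = 11, n_per: int = 10,
                     trials_per_condition: int = 25):
    """The label-recovery cohort: n_per neurons per generating variable + untuned."""
    cfg = synth.GeneratorConfig(**GEN, trials_per_condition=trials_per_condition,
                                seed=seed)
    base = synth.generate_session(cfg)
    rng = np.random.default_rng(seed)
    specs = []
    for v in SELECTION_VARIABLES:
        vr = float(np.ptp(V.variable_values(V.VARIABLE_BY_NAME[v], base, cfg)))
        slope = synth.slope_for_snr(SNR, BASELINE, vr)
        for k in range(n_per):
            specs.append(synth.NeuronSpec(
                f"{v.replace(' ', '_')}_{k}", v, BASELINE, slope,
                1 if rng.random() < 0.5 else -1, PRE_TARGET_TUNING))
    for k in range(n_per):
        specs.append(synth.NeuronSpec(f"untuned_{k}", baseline_rate=BASELINE))
    return cfg, synth.generate_cohort(cfg, specs, seed=seed + 2)


def selection_recovery(seed: int = 11, n_per: int = 10) -> dict:
    """Run screen -> regressions -> selection -> classification; score recovery."""
    cfg, cohort = selection_cohort(seed, n_per)
    session = cohort.session
    fit = behavior.fit_choice_model(session)
    matrix = scr.build_response_matrix(session)
    relat = scr.anova_screen(matrix, session)
    responses, _ = scr.task_related_set(relat)
    reg = V.regress_catalog(session, matrix, fit, responses)
    collapsed = V.collapse_table(reg)
    sw = V.stepwise_selection(collapsed, "pre_target")
    bs = V.best_subset_selection(collapsed, "pre_target")
    cls = V.classify_cells(collapsed, sorted(set(sw.selected) | set(bs.selected)))
    # right-join on the truth table: neurons with no task-related response
    # never reach classification and count as unclassified
    merged = cls.table.merge(
        cohort.ground_truth.rename(columns={"neuron_id": "neuron"}),
        on="neuron", how="right")
    tuned = merged[merged["collapsed"] != "untuned"]
    untuned = merged[merged["collapsed"] == "untuned"]
    generating = sorted({V.VARIABLE_BY_NAME[v].collapsed_parent
                         for v in SELECTION_VARIABLES})
    return {
        "recovery_fraction": float((tuned["assigned"] == tuned["collapsed"]).mean()),
        "untuned_classified_fraction": float(untuned["assigned"].notna().mean()),
        "stepwise": sorted(sw.selected),
        "best_subset": sorted(bs.selected),
        "generating": generating,
        "sets_identical": sorted(sw.selected) == sorted(bs.selected),
        "contains_generating": set(generating) <= set(sw.selected),
        "n_task_related": len(responses),
    }


def _cj_session(seed: int, trials_per_condition: int = 10):
    cfg = synth.GeneratorConfig(**GEN, trials_per_condition=trials_per_condition,
                                seed=seed)
    s = synth.generate_session(cfg)
    return cfg, s, cs.label_cost_overt(s)


def roc_null_calibration(n_neurons: int = 500, seed: int = 3000,
                         window: str = "post_offer_2") -> dict:
    """Mean choice probability of untuned neurons (should center on 0.5)."""
    cfg, s, labels = _cj_session(seed)
    rng = np.random.default_rng(seed + 1)
    aucs = []
    for k in range(n_neurons):
        nid = f"u{k}"
        s.spikes[nid] = synth.generate_neuron(
            synth.NeuronSpec(nid, baseline_rate=BASELINE), s, cfg, rng.spawn(1)[0])
        res = cs.cell_choice_probability(s, nid, window, labels, "B", "chosen juice")
        del s.spikes[nid]
        if res is not None:
            aucs.append(res.mean_auc)
    aucs = np.asarray(aucs)
    se = float(aucs.std(ddof=1) / np.sqrt(aucs.size))
    return {"mean_auc": float(aucs.mean()), "se": se, "n": int(aucs.size),
            "window": window}


def roc_power(n_neurons: int = 20, seed: int = 3100) -> dict:
    """Population t-test vs 0.5 per ROC window for tuned chosen-juice neurons."""
    cfg, s, labels = _cj_session(seed)
    slope = synth.slope_for_snr(SNR, BASELINE, 1.0)
    rng = np.random.default_rng(seed + 1)
    ids = []
    for k in range(n_neurons):
        nid = f"cj{k}"
        spec = synth.NeuronSpec(nid, "chosen juice", BASELINE, slope, 1,
                                ("post_offer", "late_delay"))
        s.add_neuron(nid, synth.generate_neuron(spec, s, cfg, rng.spawn(1)[0]))
        ids.append(nid)
    out = {}
    for window in cs.ROC_WINDOWS:
        aucs = [cs.cell_choice_probability(s, nid, window, labels, "B",
                                           "chosen juice").mean_auc for nid in ids]
        out[window] = cs.population_auc_test(aucs)
    return out


def delta_r2_regimes(n_neurons: int = 40, seed: int = 4000,
                     trials_per_condition: int = 50) -> dict:
    """dR2 distributions for cohorts whose cost term enters never / always / late.

    'late' injects the cost-affected chosen value only after target onset,
    the cost-independent variant before it; its early-vs-late contrast is the
    dissociation readout.
    """
    cfg = synth.GeneratorConfig(**GEN, trials_per_condition=trials_per_condition,
                                seed=seed)
    base = synth.generate_session(cfg)
    fit = behavior.fit_choice_model(base)
    vr = float(np.ptp(V.variable_values(19, base, cfg)))
    slope = synth.slope_for_snr(SNR, BASELINE, vr)
    out = {}
    for mode_idx, mode in enumerate(("never", "always", "late")):
        s = synth.generate_session(cfg)
        rng = np.random.default_rng(seed + 10 + mode_idx)
        ids = []
        for k in range(n_neurons):
            nid = f"cv{k}"
            if mode == "late":
                spec = synth.NeuronSpec(nid, "chosen value", BASELINE, slope, 1, (),
                                        window_overrides={
                                            "post_offer": ("chosen value", "independent"),
                                            "post_target": ("chosen value", "affected")})
            else:
                variant = "independent" if mode == "never" else "affected"
                spec = synth.NeuronSpec(nid, "chosen value", BASELINE, slope, 1,
                                        ("post_offer", "post_target"), variant=variant)
            s.add_neuron(nid, synth.generate_neuron(spec, s, cfg, rng.spawn(1)[0]))
            ids.append(nid)
        matrix = scr.build_response_matrix(s, ids)
        responses = [(nid, w) for nid in ids for w in ("post_offer", "post_target")]
        vt = integ.variant_r2_table(s, matrix, fit, responses)
        early = integ.unbiased_identify(vt, "chosen value", ("post_offer",))
        late = integ.unbiased_identify(vt, "chosen value", ("post_target",))
        rec = {"n_early": int(len(early)), "n_late": int(len(late))}
        if len(early) >= 6:
            rec["early"] = integ.delta_r2_population(early)
        if len(late) >= 6:
            rec["late"] = integ.delta_r2_population(late)
        both = pd.concat([early, late], ignore_index=True)
        if len(both) >= 6:
            rec["pooled"] = integ.delta_r2_population(both)
        if len(early) >= 2 and len(late) >= 2:
            rec["contrast"] = integ.epoch_contrast(early, late)
        out[mode] = rec
    return out
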