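"""End-to-end pipeline: simulate -> fit behavior -> screen -> select -> ROC -> dR2.

A single config (YAML/JSON-friendly dataclass) carries every threshold the
analysis uses — ANOVA alpha 0.001, regression alpha 0.05, session-screen
alpha 0.01, stepwise stop 5%, cost-overt margin 10% — and one root seed that
is fanned out per stage.  Every output file embeds the config hash so runs
are reproducible and self-describing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, choice_signal as cs, integration as integ, screen as scr
from . import synth
from . import variables as V
from .task_core import Session, read_session, write_session

__all__ = ["PipelineConfig", "run_pipeline", "make_demo_specs", "load_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    # generator
    a0: float = 2.0
    rho: float = 2.5
    xi: float = 0.25
    eta: float = 0.2
    phi: float = 0.0
    delta: float = 0.0
    eps: float = 0.0
    trials_per_condition: int = 25
    n_neurons_per_variable: int = 3
    snr: float = 2.0
    baseline_rate: float = 20.0
    # thresholds (defaults are the analysis' canonical values)
    anova_alpha: float = 0.001
    regression_alpha: float = 0.05
    session_screen_alpha: float = 0.01
    stepwise_stop: float = 0.05
    overt_margin: float = 0.10
    regression_level: str = "type"

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)


DEMO_VARIABLES = ("offer value A", "offer value -", "chosen value",
                  "chosen juice", "chosen cost", "untuned")
PRE_TARGET_TUNING = ("post_offer", "late_delay", "mem_delay", "pre_target")


def _value_range(variable: str, cfg: PipelineConfig, session: Session) -> float:
    spec = V.VARIABLE_BY_NAME[variable]
    vals = V.variable_values(spec, session, cfg)
    return float(np.ptp(vals)) or 1.0


def make_demo_specs(cfg: PipelineConfig, session: Session,
                    variables: tuple[str, ...] = DEMO_VARIABLES,
                    n_per: int | None = None,
                    tuned_windows: tuple[str, ...] = PRE_TARGET_TUNING,
                    rng: np.random.Generator | None = None) -> list[synth.NeuronSpec]:
    """Neuron specs: n_per neurons per variable at the configured SNR."""
    n_per = n_per or cfg.n_neurons_per_variable
    rng = rng or np.random.default_rng(cfg.seed + 1)
    specs = []
    for variable in variables:
        for k in range(n_per):
            nid = f"{variable.replace(' ', '_')}_{k}"
            if variable == "untuned":
                specs.append(synth.NeuronSpec(neuron_id=nid, baseline_rate=cfg.baseline_rate))
                continue
            rng_val = _value_range(variable, cfg, session)
            slope = synth.slope_for_snr(cfg.snr, cfg.baseline_rate, rng_val)
            sign = 1 if rng.random() < 0.5 else -1
            specs.append(synth.NeuronSpec(
                neuron_id=nid, encoded_variable=variable,
                baseline_rate=cfg.baseline_rate, slope=slope, sign=sign,
                tuned_windows=tuned_windows))
    return specs


def _stamp(obj: dict, cfg: PipelineConfig) -> dict:
    obj["config_hash"] = cfg.hash()
    return obj


def _json_default(o):
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path,
                 session_dir: str | Path | None = None) -> dict:
    """Run every stage; write per-stage artifacts under ``out_dir``.

    If ``session_dir`` is given that session is analyzed; otherwise a demo
    cohort is simulated from the config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(cfg), "config_hash": cfg.hash()}

    # --- stage 1: data -------------------------------------------------------
    if session_dir is not None:
        session = read_session(session_dir)
        truth = None
    else:
        gcfg = synth.GeneratorConfig(
            a0=cfg.a0, rho=cfg.rho, xi=cfg.xi, eta=cfg.eta, phi=cfg.phi,
            delta=cfg.delta, eps=cfg.eps,
            trials_per_condition=cfg.trials_per_condition, seed=cfg.seed,
            session_id=f"demo-{cfg.seed}")
        base = synth.generate_session(gcfg)
        specs = make_demo_specs(cfg, base)
        cohort = synth.generate_cohort(gcfg, specs, seed=cfg.seed + 2)
        session = cohort.session
        truth = cohort.ground_truth
        synth.write_cohort(cohort, out / "session")
    report["n_trials"] = session.n_trials
    report["n_neurons"] = len(session.neuron_ids)

    # --- stage 2: behavior ---------------------------------------------------
    fit = behavior.fit_choice_model(session)
    simp = behavior.fit_simplified_model(session)
    screen_res = behavior.screen_session(fit, alpha=cfg.session_screen_alpha)
    pattern = behavior.summarize_choice_pattern(session, simp)
    (out / "behavior.json").write_text(json.dumps(_stamp({
        "fit": fit.to_dict(), "simplified": simp.to_dict(),
        "session_screen": screen_res,
        "indifference_A_low": pattern.indifference_A_low,
        "indifference_A_high": pattern.indifference_A_high,
    }, cfg), indent=2))
    pattern.table.to_csv(out / "choice_pattern.csv", index=False)
    report["behavior"] = {"indices": fit.indices(), "screen": screen_res}

    # --- stage 3: ANOVA screen ----------------------------------------------
    rmatrix = scr.build_response_matrix(session)
    relat = scr.anova_screen(rmatrix, session, alpha=cfg.anova_alpha)
    relat.to_csv(out / "screen.csv", index=False)
    scr.table1_tally(relat, alpha=cfg.anova_alpha).to_csv(out / "screen_tally.csv")
    responses, cells = scr.task_related_set(relat)
    report["screen"] = {"n_task_related_responses": len(responses),
                        "n_task_related_cells": len(cells)}

    # --- stage 4: variable selection ------------------------------------------
    reg = V.regress_catalog(session, rmatrix, fit, responses, level=cfg.regression_level)
    collapsed = V.collapse_table(reg)
    collapsed.to_csv(out / "regressions_collapsed.csv", index=False)
    selections = {}
    selected_union: list[str] = []
    for epoch in ("pre_target", "post_target"):
        sw = V.stepwise_selection(collapsed, epoch, stop_fraction=cfg.stepwise_stop)
        bs = V.best_subset_selection(collapsed, epoch, stop_fraction=cfg.stepwise_stop)
        selections[epoch] = {"stepwise": sw.selected, "best_subset": bs.selected,
                             "stepwise_trace": sw.trace, "best_subset_trace": bs.trace}
        for v in sw.selected + bs.selected:
            if v not in selected_union:
                selected_union.append(v)
    classification = V.classify_cells(collapsed, selected_union)
    classification.table.to_csv(out / "classification.csv", index=False)
    (out / "selection.json").write_text(json.dumps(_stamp(
        {"selections": selections, "selected_union": selected_union}, cfg),
        indent=2, default=_json_default))
    report["selection"] = selections
    if truth is not None:
        merged = classification.table.merge(
            truth.rename(columns={"neuron_id": "neuron"}), on="neuron")
        tuned = merged[merged["collapsed"] != "untuned"]
        if len(tuned):
            report["label_recovery"] = float(
                (tuned["assigned"] == tuned["collapsed"]).mean())

    # --- stage 5: choice signal ------------------------------------------------
    labels = cs.label_cost_overt(session, margin=cfg.overt_margin)
    labels.to_csv(out / "cost_overt_labels.csv", index=False)
    auc_rows = []
    for kind in ("chosen juice", "chosen cost"):
        for _, row in classification.table.iterrows():
            if row["assigned"] != kind or row["encoded_level"] is None:
                continue
            for window in cs.ROC_WINDOWS:
                res = cs.cell_choice_probability(session, row["neuron"], window,
                                                 labels, row["encoded_level"], kind)
                if res is not None:
                    auc_rows.append({"neuron": row["neuron"], "kind": kind,
                                     "window": window, "mean_auc": res.mean_auc,
                                     "n_offer_types": res.n_offer_types})
    auc_df = pd.DataFrame(auc_rows, columns=["neuron", "kind", "window",
                                             "mean_auc", "n_offer_types"])
    auc_df.to_csv(out / "choice_probability.csv", index=False)
    auc_tests = {}
    for (kind, window), grp in auc_df.groupby(["kind", "window"]):
        if len(grp) >= 3:
            auc_tests[f"{kind}|{window}"] = cs.population_auc_test(grp["mean_auc"])
    (out / "choice_probability_tests.json").write_text(
        json.dumps(_stamp(dict(auc_tests), cfg), indent=2, default=_json_default))
    report["choice_probability"] = auc_tests

    # --- stage 6: dimensional integration ---------------------------------------
    windows_needed = {w for ws in integ.VARIANT_FAMILIES.values() for w in ws}
    integ_responses = [r for r in responses if r[1] in windows_needed]
    integ_report = {}
    if integ_responses:
        vt = integ.variant_r2_table(session, rmatrix, fit, integ_responses,
                                    level=cfg.regression_level)
        vt.to_csv(out / "variant_r2.csv", index=False)
        for family, windows in integ.VARIANT_FAMILIES.items():
            for window in windows:
                ident = integ.unbiased_identify(vt, family, (window,))
                key = f"{family}|{window}"
                if len(ident) >= 6:
                    integ_report[key] = integ.delta_r2_population(ident)
                else:
                    integ_report[key] = {"n": int(len(ident))}
        (out / "integration.json").write_text(
            json.dumps(_stamp(dict(integ_report), cfg), indent=2, default=_json_default))
    report["integration"] = integ_report

    (out / "report.json").write_text(json.dumps(_stamp(report, cfg), indent=2, default=_json_default))
    return report
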