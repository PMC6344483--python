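#!/usr/bin/env python
"""ROC choice probability for choice-outcome cells of the demo cohort.

Labels each quantity pair cost-overt (choices shifted > 10% between the two
cost configurations) or cost-covert, then measures, for each chosen-juice and
chosen-cost cell, the AUC between the two choice outcomes' raw spike counts
in the three non-overlapping post-offer windows, averaged across cost-overt
offer types.  AUC > 0.5 means an ideal observer reading that single neuron
before target onset already predicts the upcoming choice.  Writes
results/choice_probability.csv and the population t-tests.
"""

import json
from pathlib import Path

import pandas as pd

from goodspace import choice_signal as cs
from goodspace.task_core import read_session

ROOT = Path(__file__).resolve().parent.parent / "results"
COHORT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"


def main() -> None:
    session = read_session(COHORT)
    cls = pd.read_csv(ROOT / "classification.csv")
    labels = cs.label_cost_overt(session)
    labels.to_csv(ROOT / "cost_overt_labels.csv", index=False)
    print("cost-overt labels per quantity pair:")
    print(labels[["qA", "qB", "pA_low", "pA_high", "label"]].to_string(index=False))

    rows = []
    for _, cell in cls.iterrows():
        if cell.assigned not in ("chosen juice", "chosen cost") or pd.isna(cell.encoded_level):
            continue
        for window in cs.ROC_WINDOWS:
            res = cs.cell_choice_probability(session, cell.neuron, window, labels,
                                             cell.encoded_level, cell.assigned)
            if res is not None:
                rows.append({"neuron": cell.neuron, "kind": cell.assigned,
                             "window": window, "mean_auc": res.mean_auc,
                             "n_offer_types": res.n_offer_types})
    auc = pd.DataFrame(rows)
    auc.to_csv(ROOT / "choice_probability.csv", index=False)
    tests = {}
    for (kind, window), grp in auc.groupby(["kind", "window"]):
        if len(grp) >= 3:
            tests[f"{kind}|{window}"] = cs.population_auc_test(grp.mean_auc)
    (ROOT / "choice_probability_tests.json").write_text(json.dumps(tests, indent=2))
    print("\npopulation mean AUC vs 0.5:")
    for key, t in tests.items():
        print(f"  {key}: mean {t['mean_auc']:.3f}, p = {t['p_vs_half']:.2g} (n={t['n']})")


if __name__ == "__main__":
    main()
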