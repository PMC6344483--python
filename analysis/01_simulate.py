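#!/usr/bin/env python
"""Generate the demo cohort every later analysis step reads.

One 1000-trial session (choices from the logistic model: a0=2, relative
value rho=2.5, action cost xi=0.25, hysteresis eta=0.2) with 36 Poisson
neurons — six each tuned to offer value A, offer value -, chosen value,
chosen juice, chosen cost, plus six untuned — at SNR 2 on a 20 spikes/s
baseline.  Writes the cohort CSVs plus the ground-truth table under
scratch/cohort/ (raw spike tables are bulky; only summary tables live in
results/).
"""

from pathlib import Path

from goodspace import synth
from goodspace.pipeline import PipelineConfig, make_demo_specs

OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"
SEED = 2024


def main() -> None:
    cfg = PipelineConfig(seed=SEED, trials_per_condition=25, n_neurons_per_variable=6)
    gcfg = synth.GeneratorConfig(a0=cfg.a0, rho=cfg.rho, xi=cfg.xi, eta=cfg.eta,
                                 trials_per_condition=cfg.trials_per_condition,
                                 seed=cfg.seed, session_id=f"demo-{cfg.seed}")
    base = synth.generate_session(gcfg)
    specs = make_demo_specs(cfg, base)
    cohort = synth.generate_cohort(gcfg, specs, seed=cfg.seed + 2)
    synth.write_cohort(cohort, OUT)
    n_tuned = (cohort.ground_truth.encoded_variable != "untuned").sum()
    print(f"wrote {base.n_trials}-trial session with {len(specs)} neurons "
          f"({n_tuned} tuned) to {OUT}")


if __name__ == "__main__":
    main()
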