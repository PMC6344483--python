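#!/usr/bin/env python
"""Screen every neuronal response of the demo cohort for task-relatedness.

Each response (one neuron in one of the nine peri-event windows) is submitted
to the two three-way ANOVAs — (trial type x offer A location x target A
location) and (trial type x chosen offer location x chosen target location) —
at p < 0.001.  Writes the per-response p-values (results/screen.csv) and the
window x factor tally (results/screen_tally.csv).
"""

from pathlib import Path

from goodspace import screen as scr
from goodspace.task_core import read_session

ROOT = Path(__file__).resolve().parent.parent / "results"
COHORT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"


def main() -> None:
    session = read_session(COHORT)
    matrix = scr.build_response_matrix(session)
    relat = scr.anova_screen(matrix, session)
    relat.to_csv(ROOT / "screen.csv", index=False)
    tally = scr.table1_tally(relat)
    tally.to_csv(ROOT / "screen_tally.csv")
    responses, cells = scr.task_related_set(relat)
    print(f"{len(responses)} of {len(relat)} responses task-related, "
          f"from {len(cells)} of {len(session.neuron_ids)} cells")
    print("\nsignificant responses per window x factor:")
    print(tally.to_string())


if __name__ == "__main__":
    main()
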