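"""Choice-outcome signals: cost-overt labeling, activity profiles, ROC analysis.

For neurons encoding the binary choice outcome (chosen juice / chosen cost),
trials are grouped by whether the animal chose the juice the cell encodes
(E) or the other juice (O), and by whether the quantity pair was cost-overt
(choices shifted > 10% between the two cost configurations) or cost-covert
(same option chosen regardless of cost).  Spike-density functions are built
by convolving 1-ms spike trains with a Gaussian kernel (sigma = 40 ms) and
normalized per cell.  Choice probability is the ROC area (AUC) between the
two outcome groups' raw spike counts in three non-overlapping post-offer
windows, averaged across cost-overt offer types; an AUC of 0.5 is chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .task_core import Cost, Session, Trial, WINDOWS, WINDOW_NAMES, count_spikes, window_interval

__all__ = [
    "ROC_WINDOWS",
    "label_cost_overt",
    "sdf",
    "normalize_profile",
    "GroupTraces",
    "group_traces",
    "population_traces",
    "auc",
    "AUCResult",
    "cell_choice_probability",
    "population_auc_test",
]

# Non-overlapping post-offer ROC windows (seconds after offer onset).
ROC_WINDOWS: dict[str, tuple[float, float]] = {
    "post_offer_1": (0.0, 0.25),
    "post_offer_2": (0.25, 0.50),
    "post_offer_3": (0.50, 0.75),
}

OVERT_MARGIN = 0.10
MIN_CHOICES_PER_OPTION = 2
COVERT_CONSISTENCY = 0.90  # fraction of same-option choices per configuration


def label_cost_overt(session: Session, margin: float = OVERT_MARGIN) -> pd.DataFrame:
    """Label each quantity pair cost-overt / cost-covert / insufficient.

    Overt: fraction of A choices when A is low cost exceeds that when A is
    high cost by more than ``margin``, with each option chosen at least twice
    (pooled over the two configurations).  Covert: the same option chosen in
    at least 90% of trials of each configuration.  Pairs seen in only one
    configuration, or matching neither rule, are insufficient.
    """
    rows = []
    for t in session.trials:
        rows.append((t.offer.qA, t.offer.qB, t.offer.costA == Cost.LOW,
                     t.chosen_juice))
    df = pd.DataFrame(rows, columns=["qA", "qB", "A_low", "chosen"])
    out = []
    for (qA, qB), grp in df.groupby(["qA", "qB"]):
        low = grp[grp.A_low]
        high = grp[~grp.A_low]
        rec = {"qA": qA, "qB": qB, "n_low": len(low), "n_high": len(high)}
        if len(low) == 0 or len(high) == 0:
            rec.update(pA_low=np.nan, pA_high=np.nan, label="insufficient")
            out.append(rec)
            continue
        pA_low = float((low.chosen == "A").mean())
        pA_high = float((high.chosen == "A").mean())
        nA = int((grp.chosen == "A").sum())
        nB = int((grp.chosen == "B").sum())
        rec.update(pA_low=pA_low, pA_high=pA_high, nA=nA, nB=nB)
        if (pA_low - pA_high > margin and nA >= MIN_CHOICES_PER_OPTION
                and nB >= MIN_CHOICES_PER_OPTION):
            rec["label"] = "overt"
        else:
            mode_low = "A" if pA_low >= 0.5 else "B"
            mode_high = "A" if pA_high >= 0.5 else "B"
            frac_low = max(pA_low, 1 - pA_low)
            frac_high = max(pA_high, 1 - pA_high)
            if (mode_low == mode_high and frac_low >= COVERT_CONSISTENCY
                    and frac_high >= COVERT_CONSISTENCY):
                rec["label"] = "covert"
            else:
                rec["label"] = "insufficient"
        out.append(rec)
    return pd.DataFrame(out)


def sdf(spikes: np.ndarray, span: tuple[float, float], sigma: float = 0.040,
        dt: float = 0.001) -> tuple[np.ndarray, np.ndarray]:
    """Spike-density function on a 1-ms grid over ``span``.

    Spikes are binned at ``dt``, scaled to spikes/s, and convolved with a
    Gaussian kernel of standard deviation ``sigma`` seconds ("40 ms width"
    read as sigma = 40 ms).  The kernel is truncated at the span edges
    without renormalization, so the integral of the profile equals the spike
    count up to edge effects.
    """
    t0, t1 = span
    if t1 <= t0:
        raise ValueError("empty time grid")
    n = int(round((t1 - t0) / dt))
    edges = t0 + dt * np.arange(n + 1)
    counts, _ = np.histogram(np.asarray(spikes, float), bins=edges)
    rate = gaussian_filter1d(counts.astype(float) / dt, sigma=sigma / dt,
                             mode="constant", cval=0.0)
    centers = edges[:-1] + dt / 2
    return centers, rate


def normalize_profile(profile: np.ndarray, pre_offer_mean: float,
                      other_windows_mean: float) -> np.ndarray:
    """(profile - pre-offer mean) / mean rate across the other eight windows."""
    if other_windows_mean <= 0:
        raise ZeroDivisionError("divisor (mean rate over other windows) must be > 0")
    return (np.asarray(profile, float) - pre_offer_mean) / other_windows_mean


ALIGNMENTS: dict[str, tuple[str, float, float]] = {
    "offer_on": ("offer_on", -0.5, 1.5),
    "target_on": ("target_on", -0.5, 0.5),
    "juice": ("juice", -0.5, 0.5),
}

TRACE_GROUPS = ("Ec", "Eo", "Oc", "Oo")


@dataclass
class GroupTraces:
    """Per-cell normalized average profiles for the Ec/Eo/Oc/Oo trial groups."""

    neuron: str
    included: bool
    reason: str = ""
    grids: dict[str, np.ndarray] = field(default_factory=dict)
    traces: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)  # alignment -> group -> trace
    n_trials: dict[str, int] = field(default_factory=dict)


def _window_means(session: Session, train_list) -> tuple[float, float]:
    """Mean pre-offer rate and mean rate across the other eight windows."""
    per_window = []
    for w in WINDOWS:
        vals = []
        for train, trial in zip(train_list, session.trials):
            iv = window_interval(w, trial.events)
            vals.append(count_spikes(train, iv) / w.duration)
        per_window.append(float(np.mean(vals)))
    pre = per_window[WINDOW_NAMES.index("pre_offer")]
    others = [v for name, v in zip(WINDOW_NAMES, per_window) if name != "pre_offer"]
    return pre, float(np.mean(others))


def group_traces(session: Session, neuron: str, encoded_level: str,
                 labels: pd.DataFrame, kind: str = "chosen juice",
                 min_trials: int = 2) -> GroupTraces:
    """Average normalized SDFs per E/O x covert/overt group and alignment.

    ``encoded_level`` is the cell's preferred juice ('A'/'B') for chosen-juice
    cells, or the preferred cost ('low'/'high') for chosen-cost cells.  The
    cell is included only if all four groups have >= ``min_trials`` trials.
    """
    lab = {(r.qA, r.qB): r.label for r in labels.itertuples()}
    trains = session.spikes[neuron]
    groups: dict[str, list[int]] = {g: [] for g in TRACE_GROUPS}
    for i, t in enumerate(session.trials):
        pair_label = lab.get((t.offer.qA, t.offer.qB), "insufficient")
        if pair_label == "insufficient":
            continue
        if kind == "chosen juice":
            eo = "E" if t.chosen_juice == encoded_level else "O"
        elif kind == "chosen cost":
            eo = "E" if t.chosen_cost == encoded_level else "O"
        else:
            raise ValueError(f"unknown kind {kind!r}")
        groups[eo + ("o" if pair_label == "overt" else "c")].append(i)
    counts = {g: len(ix) for g, ix in groups.items()}
    if min(counts.values()) < min_trials:
        return GroupTraces(neuron=neuron, included=False,
                           reason="fewer than 2 trials in some group", n_trials=counts)
    pre, other = _window_means(session, trains)
    if other <= 0:
        return GroupTraces(neuron=neuron, included=False,
                           reason="zero normalization divisor", n_trials=counts)
    gt = GroupTraces(neuron=neuron, included=True, n_trials=counts)
    for align, (event, lo, hi) in ALIGNMENTS.items():
        dt = 0.001
        n = int(round((hi - lo) / dt))
        rel = lo + dt * (np.arange(n) + 0.5)
        gt.grids[align] = rel
        gt.traces[align] = {}
        for g, ix in groups.items():
            acc = np.zeros(n)
            for i in ix:
                t = session.trials[i]
                ev = t.events.as_dict()[event]
                _, rate = sdf(trains[i], t.span)
                # sample the full-trial profile on the aligned grid
                idx = np.clip(((ev + rel) / dt).astype(int), 0, None)
                valid = idx < rate.size
                seg = np.zeros(n)
                seg[valid] = rate[idx[valid]]
                acc += seg
            gt.traces[align][g] = normalize_profile(acc / len(ix), pre, other)
    return gt


def population_traces(cells: list[GroupTraces]) -> dict[str, dict[str, np.ndarray]]:
    """Equal-weight average of normalized traces across included cells."""
    included = [c for c in cells if c.included]
    if not included:
        raise ValueError("no included cells")
    out: dict[str, dict[str, np.ndarray]] = {}
    for align in ALIGNMENTS:
        out[align] = {g: np.mean([c.traces[align][g] for c in included], axis=0)
                      for g in TRACE_GROUPS}
    return out


def auc(group1, group2) -> float:
    """ROC area: P(X1 > X2) + 0.5 P(X1 = X2) over all cross pairs.

    Computed from midranks (equals the Mann-Whitney U statistic divided by
    n1*n2).
    """
    x1 = np.asarray(group1, float)
    x2 = np.asarray(group2, float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([x1, x2]))
    r1 = ranks[: x1.size].sum()
    u1 = r1 - x1.size * (x1.size + 1) / 2
    return float(u1 / (x1.size * x2.size))


@dataclass
class AUCResult:
    neuron: str
    window: str
    per_offer_type: dict[tuple[int, int], float]
    mean_auc: float
    n_offer_types: int


def cell_choice_probability(session: Session, neuron: str, window: str,
                            labels: pd.DataFrame, encoded_level: str,
                            kind: str = "chosen juice") -> AUCResult | None:
    """Mean AUC across cost-overt offer types for one cell in one ROC window.

    Spike counts are raw (no averaging or baseline correction).  Groups are
    E vs O choices for chosen-juice cells, low- vs high-cost choices for
    chosen-cost cells.  Returns None when no overt offer type has both
    outcome groups represented.
    """
    if window not in ROC_WINDOWS:
        raise ValueError(f"unknown ROC window {window!r}")
    lo, hi = ROC_WINDOWS[window]
    overt = {(r.qA, r.qB) for r in labels.itertuples() if r.label == "overt"}
    trains = session.spikes[neuron]
    per_pair: dict[tuple[int, int], tuple[list, list]] = {p: ([], []) for p in overt}
    for train, t in zip(trains, session.trials):
        pair = (t.offer.qA, t.offer.qB)
        if pair not in overt:
            continue
        if kind == "chosen juice":
            is_e = t.chosen_juice == encoded_level
        else:
            is_e = t.chosen_cost == encoded_level
        c = count_spikes(train, (t.events.offer_on + lo, t.events.offer_on + hi))
        per_pair[pair][0 if is_e else 1].append(c)
    aucs = {}
    for pair, (e, o) in per_pair.items():
        if e and o:
            aucs[pair] = auc(e, o)
    if not aucs:
        return None
    return AUCResult(neuron=neuron, window=window, per_offer_type=aucs,
                     mean_auc=float(np.mean(list(aucs.values()))),
                     n_offer_types=len(aucs))


def population_auc_test(auc_values, min_cells: int = 3) -> dict:
    """Mean AUC and two-sided one-sample t-test against 0.5."""
    vals = np.asarray(list(auc_values), float)
    vals = vals[np.isfinite(vals)]
    if vals.size < min_cells:
        raise ValueError(f"need at least {min_cells} cells, got {vals.size}")
    mean = float(vals.mean())
    if np.ptp(vals) == 0:
        p = 1.0 if vals[0] == 0.5 else 0.0
    else:
        p = float(stats.ttest_1samp(vals, 0.5).pvalue)
    return {"mean_auc": mean, "p_vs_half": p, "n": int(vals.size)}
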