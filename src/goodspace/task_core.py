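"""Core data model for the juice-choice task with variable saccadic action costs.

A session consists of trials in which two juices (A, B) are offered in
variable quantities, each offer carrying a low or high action cost (short vs
long saccade to the eventual target).  Offers appear left/right of fixation;
after a delay, saccade targets appear at one of four angles, the two targets
always in opposite hemifields.  This module holds the trial/session
containers, the nine canonical peri-event time windows, spike-count
bookkeeping, and plain-text (CSV/JSON) session I/O.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Cost",
    "OfferType",
    "TrialEvents",
    "Trial",
    "WindowSpec",
    "WINDOWS",
    "WINDOW_NAMES",
    "Session",
    "parse_offer_type",
    "format_offer_type",
    "hemifield_of_angle",
    "window_interval",
    "count_spikes",
    "read_session",
    "write_session",
]

# Cost levels are plain strings throughout ("low" = short saccade, "high" =
# long saccade); a tiny enum-like namespace keeps call sites readable.
class Cost:
    LOW = "low"
    HIGH = "high"


TASK_ANGLES = (22.5, 157.5, 202.5, 337.5)


def hemifield_of_angle(angle: float) -> str:
    """Map a saccade-target angle (degrees from azimuth) to its hemifield.

    The task uses four angles; 157.5 and 202.5 lie in the left hemifield,
    22.5 and 337.5 in the right.
    """
    if angle in (157.5, 202.5):
        return "L"
    if angle in (22.5, 337.5):
        return "R"
    raise ValueError(f"not a task angle: {angle!r} (expected one of {TASK_ANGLES})")


@dataclass(frozen=True)
class OfferType:
    """One choice problem: quantities of juices A and B plus cost assignment.

    Exactly one offer is low cost on every trial (the costs are
    complementary), and at least one quantity is positive.
    """

    qA: int
    qB: int
    costA: str
    costB: str

    def __post_init__(self):
        if self.costA not in (Cost.LOW, Cost.HIGH) or self.costB not in (Cost.LOW, Cost.HIGH):
            raise ValueError("costs must be 'low' or 'high'")
        if self.costA == self.costB:
            raise ValueError("exactly one offer must be low cost")
        if self.qA < 0 or self.qB < 0:
            raise ValueError("quantities must be non-negative")
        if self.qA == 0 and self.qB == 0:
            raise ValueError("at least one offered quantity must be positive")

    @property
    def quantity_pair(self) -> tuple[int, int]:
        return (self.qA, self.qB)


_OFFER_RE = re.compile(r"^\s*(\d+)\s*([AB])\s*([+−-])\s*:\s*(\d+)\s*([AB])\s*([+−-])\s*$")


def parse_offer_type(label: str) -> OfferType:
    """Parse an offer-type label like ``"1A+:3B-"`` (either juice order).

    ``+`` marks the low-cost (short saccade) offer, ``-`` (ASCII or U+2212)
    the high-cost one.
    """
    m = _OFFER_RE.match(label)
    if not m:
        raise ValueError(f"malformed offer-type label: {label!r}")
    q1, j1, c1, q2, j2, c2 = m.groups()
    if j1 == j2:
        raise ValueError(f"offer-type label names juice {j1} twice: {label!r}")
    sign = {"+": Cost.LOW, "-": Cost.HIGH, "−": Cost.HIGH}
    parts = {j1: (int(q1), sign[c1]), j2: (int(q2), sign[c2])}
    qA, costA = parts["A"]
    qB, costB = parts["B"]
    return OfferType(qA=qA, qB=qB, costA=costA, costB=costB)


def format_offer_type(offer: OfferType) -> str:
    sa = "+" if offer.costA == Cost.LOW else "-"
    sb = "+" if offer.costB == Cost.LOW else "-"
    return f"{offer.qA}A{sa}:{offer.qB}B{sb}"


@dataclass(frozen=True)
class TrialEvents:
    """Behavioral event times in seconds from trial start (fixation onset)."""

    offer_on: float
    offer_off: float
    target_on: float
    go: float
    saccade: float
    juice: float

    def __post_init__(self):
        seq = [self.offer_on, self.offer_off, self.target_on, self.go, self.saccade, self.juice]
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValueError("event times must be strictly increasing")

    def as_dict(self) -> dict[str, float]:
        return {
            "offer_on": self.offer_on,
            "offer_off": self.offer_off,
            "target_on": self.target_on,
            "go": self.go,
            "saccade": self.saccade,
            "juice": self.juice,
        }


@dataclass(frozen=True)
class Trial:
    index: int
    offer: OfferType
    offerA_side: str  # "L" or "R"
    angleA: float
    angleB: float
    chosen_juice: str  # "A" or "B"
    events: TrialEvents
    prev_chosen_juice: str = "none"  # "A", "B", or "none" (first trial)
    prev_chosen_cost: str = "none"  # "low", "high", or "none"

    def __post_init__(self):
        if self.offerA_side not in ("L", "R"):
            raise ValueError("offerA_side must be 'L' or 'R'")
        if self.chosen_juice not in ("A", "B"):
            raise ValueError("chosen_juice must be 'A' or 'B'")
        if hemifield_of_angle(self.angleA) == hemifield_of_angle(self.angleB):
            raise ValueError("target angles must lie in opposite hemifields")

    # --- derived attributes -------------------------------------------------
    @property
    def offerB_side(self) -> str:
        return "R" if self.offerA_side == "L" else "L"

    @property
    def targetA_side(self) -> str:
        return hemifield_of_angle(self.angleA)

    @property
    def targetB_side(self) -> str:
        return hemifield_of_angle(self.angleB)

    @property
    def chosen_cost(self) -> str:
        return self.offer.costA if self.chosen_juice == "A" else self.offer.costB

    @property
    def chosen_offer_side(self) -> str:
        return self.offerA_side if self.chosen_juice == "A" else self.offerB_side

    @property
    def chosen_target_side(self) -> str:
        return self.targetA_side if self.chosen_juice == "A" else self.targetB_side

    @property
    def trial_type(self) -> tuple:
        """Offer type plus choice — the unit over which responses are defined."""
        o = self.offer
        return (o.qA, o.qB, o.costA, self.chosen_juice)

    @property
    def span(self) -> tuple[float, float]:
        """Recorded span of the trial: fixation onset to 0.5 s after juice."""
        return (0.0, self.events.juice + 0.5)


@dataclass(frozen=True)
class WindowSpec:
    """One of the nine canonical peri-event analysis windows.

    Intervals are half-open [start, end); every window lasts 0.5 s.
    """

    name: str
    anchor: str
    start_offset: float
    end_offset: float

    @property
    def duration(self) -> float:
        return self.end_offset - self.start_offset


WINDOWS: tuple[WindowSpec, ...] = (
    WindowSpec("pre_offer", "offer_on", -0.5, 0.0),
    WindowSpec("post_offer", "offer_on", 0.0, 0.5),
    WindowSpec("late_delay", "offer_on", 0.5, 1.0),
    WindowSpec("mem_delay", "offer_off", 0.0, 0.5),
    WindowSpec("pre_target", "target_on", -0.5, 0.0),
    WindowSpec("post_target", "target_on", 0.0, 0.5),
    WindowSpec("pre_go", "go", -0.5, 0.0),
    WindowSpec("pre_juice", "juice", -0.5, 0.0),
    WindowSpec("post_juice", "juice", 0.0, 0.5),
)

WINDOW_NAMES = tuple(w.name for w in WINDOWS)
WINDOW_BY_NAME = {w.name: w for w in WINDOWS}


def window_interval(w: WindowSpec, ev: TrialEvents) -> tuple[float, float]:
    """Resolve a window to an absolute half-open [start, end) in trial time."""
    anchors = ev.as_dict()
    if w.anchor not in anchors:
        raise KeyError(f"event {w.anchor!r} missing from trial events")
    t0 = anchors[w.anchor]
    return (t0 + w.start_offset, t0 + w.end_offset)


def count_spikes(spikes: Sequence[float] | np.ndarray, interval: tuple[float, float]) -> int:
    """Count spikes in a half-open interval [start, end); spikes must be sorted."""
    s = np.asarray(spikes, dtype=float)
    if s.size and np.any(np.diff(s) < 0):
        raise ValueError("spike times must be sorted ascending")
    start, end = interval
    return int(np.searchsorted(s, end, side="left") - np.searchsorted(s, start, side="left"))


@dataclass
class Session:
    """One behavioral session: ordered trials plus per-neuron spike trains.

    ``spikes[neuron_id][i]`` is the sorted spike-time array (seconds from
    trial start) of neuron ``neuron_id`` on trial ``trials[i]``.
    """

    session_id: str
    trials: list[Trial]
    spikes: dict[str, list[np.ndarray]] = field(default_factory=dict)
    juice_labels: tuple[str, str] = ("A", "B")
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for i, t in enumerate(self.trials):
            if t.index != i + 1:
                raise ValueError("trial indices must be consecutive starting at 1")
        for nid, trains in self.spikes.items():
            if len(trains) != len(self.trials):
                raise ValueError(f"neuron {nid}: {len(trains)} trains for {len(self.trials)} trials")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def neuron_ids(self) -> list[str]:
        return list(self.spikes.keys())

    def add_neuron(self, neuron_id: str, trains: Sequence[np.ndarray]) -> None:
        if neuron_id in self.spikes:
            raise ValueError(f"duplicate neuron id {neuron_id!r}")
        trains = [np.asarray(t, dtype=float) for t in trains]
        if len(trains) != self.n_trials:
            raise ValueError("one spike train per trial required")
        self.spikes[neuron_id] = trains


# --- I/O ---------------------------------------------------------------------

_TRIAL_COLUMNS = [
    "trial", "qA", "qB", "costA", "costB", "offerA_side", "targetA_side",
    "angleA", "angleB", "chosen_juice", "offer_on", "offer_off", "target_on",
    "go", "saccade", "juice_time",
]


def trials_to_frame(session: Session) -> pd.DataFrame:
    rows = []
    for t in session.trials:
        rows.append({
            "trial": t.index, "qA": t.offer.qA, "qB": t.offer.qB,
            "costA": t.offer.costA, "costB": t.offer.costB,
            "offerA_side": t.offerA_side, "targetA_side": t.targetA_side,
            "angleA": t.angleA, "angleB": t.angleB,
            "chosen_juice": t.chosen_juice,
            "offer_on": t.events.offer_on, "offer_off": t.events.offer_off,
            "target_on": t.events.target_on, "go": t.events.go,
            "saccade": t.events.saccade, "juice_time": t.events.juice,
        })
    return pd.DataFrame(rows, columns=_TRIAL_COLUMNS)


def _trials_from_frame(df: pd.DataFrame) -> list[Trial]:
    trials: list[Trial] = []
    prev_juice, prev_cost = "none", "none"
    for _, r in df.sort_values("trial").iterrows():
        offer = OfferType(int(r.qA), int(r.qB), str(r.costA), str(r.costB))
        ev = TrialEvents(float(r.offer_on), float(r.offer_off), float(r.target_on),
                         float(r.go), float(r.saccade), float(r.juice_time))
        t = Trial(index=int(r.trial), offer=offer, offerA_side=str(r.offerA_side),
                  angleA=float(r.angleA), angleB=float(r.angleB),
                  chosen_juice=str(r.chosen_juice), events=ev,
                  prev_chosen_juice=prev_juice, prev_chosen_cost=prev_cost)
        trials.append(t)
        prev_juice, prev_cost = t.chosen_juice, t.chosen_cost
    return trials


def write_session(session: Session, out_dir: str | Path) -> Path:
    """Write a session as trials.csv + spikes.csv + manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials_to_frame(session).to_csv(out / "trials.csv", index=False)
    rows = []
    for nid, trains in session.spikes.items():
        for trial_idx, train in enumerate(trains, start=1):
            for t in train:
                rows.append((nid, trial_idx, float(t)))
    pd.DataFrame(rows, columns=["neuron_id", "trial", "spike_time_s"]).to_csv(
        out / "spikes.csv", index=False)
    manifest = {
        "session_id": session.session_id,
        "juice_labels": list(session.juice_labels),
        "neuron_ids": session.neuron_ids,
        "n_trials": session.n_trials,
        **session.meta,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def read_session(in_dir: str | Path) -> Session:
    """Load a session written by :func:`write_session`."""
    d = Path(in_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    df = pd.read_csv(d / "trials.csv")
    trials = _trials_from_frame(df)
    spikes: dict[str, list[np.ndarray]] = {}
    spk_path = d / "spikes.csv"
    if spk_path.exists():
        sdf = pd.read_csv(spk_path)
        for nid in manifest.get("neuron_ids", []):
            sub = sdf[sdf.neuron_id == nid]
            by_trial = {k: np.sort(v.spike_time_s.to_numpy()) for k, v in sub.groupby("trial")}
            spikes[str(nid)] = [by_trial.get(i, np.empty(0)) for i in range(1, len(trials) + 1)]
    meta = {k: v for k, v in manifest.items()
            if k not in ("session_id", "juice_labels", "neuron_ids", "n_trials")}
    return Session(session_id=str(manifest["session_id"]), trials=trials, spikes=spikes,
                   juice_labels=tuple(manifest.get("juice_labels", ("A", "B"))), meta=meta)
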