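"""Synthetic sessions and spike trains with known ground truth.

Choices are drawn from the logistic model (see :mod:`goodspace.behavior`)
with configurable generating coefficients; task conditions (quantity pair x
cost assignment x offer side x target side) are fully counterbalanced and
shuffled.  Neurons fire as homogeneous Poisson processes at a baseline rate,
with the rate inside tuned windows shifted linearly by any catalog variable
evaluated at the generating indices.  Every cohort carries a ground-truth
table for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import variables as V
from .task_core import (Cost, OfferType, Session, Trial, TrialEvents,
                        WINDOW_BY_NAME, WINDOW_NAMES, window_interval,
                        write_session)

__all__ = [
    "DEFAULT_MENU",
    "GeneratorConfig",
    "NeuronSpec",
    "Cohort",
    "generate_session",
    "generate_neuron",
    "generate_cohort",
    "write_cohort",
    "slope_for_snr",
]

# Quantity-pair menu spanning #B:#A ratios 1..4 around a typical relative
# value of ~2.5; forced choices (zero quantity) excluded by default.
DEFAULT_MENU: tuple[tuple[int, int], ...] = ((1, 1), (1, 2), (1, 3), (1, 4), (2, 3))

_DIAMETRIC = {22.5: 202.5, 157.5: 337.5, 202.5: 22.5, 337.5: 157.5}
_ANGLES_BY_HEMI = {"L": (157.5, 202.5), "R": (22.5, 337.5)}


@dataclass(frozen=True)
class GeneratorConfig:
    """Generating parameters: a0 plus the six normalized indices.

    The logistic coefficients are a1 = a0*rho, a2 = a0*xi, ..., a6 = a0*eps.
    Each quantity pair is generated under all 8 counterbalance cells
    (cost assignment x offer side x target side), trials_per_condition each.
    """

    a0: float = 2.0
    rho: float = 2.5
    xi: float = 0.25
    eta: float = 0.2
    phi: float = 0.0
    delta: float = 0.0
    eps: float = 0.0
    offer_types: tuple[tuple[int, int], ...] = DEFAULT_MENU
    trials_per_condition: int = 50
    seed: int = 0
    go_jitter: tuple[float, float] = (0.6, 1.2)
    reaction_time: float = 0.2  # saccade latency after go; not reported, fixed
    session_id: str = "synthetic"

    def __post_init__(self):
        if self.a0 <= 0:
            raise ValueError("a0 must be positive")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if not self.offer_types:
            raise ValueError("offer_types menu must be non-empty")

    @property
    def coefficients(self) -> np.ndarray:
        return self.a0 * np.array([1.0, self.rho, self.xi, self.eta,
                                   self.phi, self.delta, self.eps])

    @property
    def n_trials(self) -> int:
        return len(self.offer_types) * 8 * self.trials_per_condition


def generate_session(cfg: GeneratorConfig) -> Session:
    """Draw one session: counterbalanced conditions, sequential choices.

    History terms use the previous trial's realized choice, so hysteresis is
    genuinely recoverable.  Deterministic given cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    cells = [(q, costA, sideA, themi)
             for q in cfg.offer_types
             for costA in (Cost.LOW, Cost.HIGH)
             for sideA in ("L", "R")
             for themi in ("L", "R")]
    conditions = cells * cfg.trials_per_condition
    order = rng.permutation(len(conditions))
    n = len(order)
    a = cfg.coefficients
    # vectorized draws and history-free part of X; only hysteresis terms stay
    # in the sequential loop
    qA = np.array([conditions[k][0][0] for k in order], float)
    qB = np.array([conditions[k][0][1] for k in order], float)
    costA_low = np.array([conditions[k][1] == Cost.LOW for k in order])
    sideA_L = np.array([conditions[k][2] == "L" for k in order])
    themi_L = np.array([conditions[k][3] == "L" for k in order])
    x2 = np.where(costA_low, -1.0, 1.0)  # d_B+ - d_A+
    x5 = np.where(sideA_L, -1.0, 1.0)
    x6 = np.where(themi_L, -1.0, 1.0)
    X_base = a[0] * qB - a[1] * qA + a[2] * x2 + a[5] * x5 + a[6] * x6
    angle_pick = rng.integers(0, 2, size=n)
    u_choice = rng.random(n)
    go_delay = rng.uniform(*cfg.go_jitter, size=n)
    trials: list[Trial] = []
    prev_juice, prev_cost = "none", "none"
    for i in range(n):
        costA = Cost.LOW if costA_low[i] else Cost.HIGH
        costB = Cost.HIGH if costA_low[i] else Cost.LOW
        x34 = 0.0
        if prev_juice != "none":
            h3 = (prev_juice == "B") - (prev_juice == "A")
            h4 = (costB == prev_cost) - (costA == prev_cost)
            x34 = a[3] * h3 + a[4] * h4
        p_b = 1.0 / (1.0 + np.exp(-(X_base[i] + x34)))
        chosen = "B" if u_choice[i] < p_b else "A"
        angleA = _ANGLES_BY_HEMI["L" if themi_L[i] else "R"][angle_pick[i]]
        angleB = _DIAMETRIC[angleA]
        offer_on = 1.5
        offer_off = offer_on + 1.0
        target_on = offer_off + 1.0
        go = target_on + go_delay[i]
        saccade = go + cfg.reaction_time
        juice = saccade + 0.75
        ev = TrialEvents(offer_on, offer_off, target_on, go, saccade, juice)
        t = Trial(index=i + 1,
                  offer=OfferType(int(qA[i]), int(qB[i]), costA, costB),
                  offerA_side="L" if sideA_L[i] else "R",
                  angleA=angleA, angleB=angleB,
                  chosen_juice=chosen, events=ev,
                  prev_chosen_juice=prev_juice, prev_chosen_cost=prev_cost)
        trials.append(t)
        prev_juice, prev_cost = chosen, t.chosen_cost
    meta = {"generator": {
        "a0": cfg.a0, "rho": cfg.rho, "xi": cfg.xi, "eta": cfg.eta,
        "phi": cfg.phi, "delta": cfg.delta, "eps": cfg.eps,
        "trials_per_condition": cfg.trials_per_condition, "seed": cfg.seed,
    }}
    return Session(session_id=cfg.session_id, trials=trials, meta=meta)


@dataclass(frozen=True)
class NeuronSpec:
    """Linear-rate tuning of one simulated neuron.

    Inside each tuned window the rate is max(0, baseline + sign*slope*v),
    where v is the encoded catalog variable on that trial; elsewhere the
    neuron fires at baseline.  ``window_overrides`` may retarget individual
    windows to a different (variable, variant) pair, e.g. to inject the cost
    term only after target onset.
    """

    neuron_id: str
    encoded_variable: str = "untuned"  # catalog variable name or "untuned"
    baseline_rate: float = 20.0
    slope: float = 0.0
    sign: int = 1
    tuned_windows: tuple[str, ...] = ()
    variant: str = "affected"
    window_overrides: Mapping[str, tuple[str, str]] | None = None

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise ValueError("baseline rate must be >= 0")
        if self.encoded_variable == "untuned" and self.slope != 0:
            raise ValueError("untuned neurons must have slope 0")
        for w in self.tuned_windows:
            if w not in WINDOW_NAMES:
                raise ValueError(f"unknown window {w!r}")


def slope_for_snr(snr: float, baseline_rate: float, value_range: float) -> float:
    """Slope such that slope * value_range = snr * sqrt(baseline_rate)."""
    if value_range <= 0:
        raise ValueError("value range must be positive")
    return snr * np.sqrt(baseline_rate) / value_range


def _window_variable(spec: NeuronSpec, window: str) -> tuple[str, str] | None:
    if spec.window_overrides and window in spec.window_overrides:
        return tuple(spec.window_overrides[window])
    if spec.encoded_variable != "untuned" and window in spec.tuned_windows:
        return (spec.encoded_variable, spec.variant)
    return None


def generate_neuron(spec: NeuronSpec, session: Session, indices,
                    seed: int | np.random.Generator = 0) -> list[np.ndarray]:
    """Poisson spike trains (one sorted array per trial) for one neuron.

    ``indices`` supplies rho and xi for variable evaluation (generating
    config or a behavioral fit).  Spike times are reported at 0.1 ms
    resolution, seconds from trial start.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # pre-evaluate per-window variable values across trials
    win_vals: dict[str, np.ndarray] = {}
    for w in WINDOW_NAMES:
        target = _window_variable(spec, w)
        if target is not None:
            vname, variant = target
            vspec = V.VARIABLE_BY_NAME[vname]
            win_vals[w] = np.array([V.evaluate_variable(vspec, t, indices, variant)
                                    for t in session.trials])
    trains: list[np.ndarray] = []
    for i, trial in enumerate(session.trials):
        t0, t1 = trial.span
        # piecewise-constant rate: baseline plus tuned-window deltas
        edges = {t0, t1}
        deltas = []
        for w, vals in win_vals.items():
            a, b = window_interval(WINDOW_BY_NAME[w], trial.events)
            a, b = max(a, t0), min(b, t1)
            if b > a:
                edges.update((a, b))
                deltas.append((a, b, spec.sign * spec.slope * vals[i]))
        grid = np.array(sorted(edges))
        times = []
        for a, b in zip(grid[:-1], grid[1:]):
            rate = spec.baseline_rate + sum(d for (x, y, d) in deltas if x <= a and b <= y)
            rate = max(0.0, rate)
            if rate <= 0:
                continue
            n = rng.poisson(rate * (b - a))
            if n:
                times.append(rng.uniform(a, b, size=n))
        if times:
            st = np.sort(np.concatenate(times))
            st = np.round(st, 4)
            trains.append(st)
        else:
            trains.append(np.empty(0))
    return trains


@dataclass
class Cohort:
    session: Session
    ground_truth: pd.DataFrame

    @property
    def neuron_ids(self) -> list[str]:
        return self.session.neuron_ids


def generate_cohort(cfg: GeneratorConfig, neuron_specs: Sequence[NeuronSpec],
                    seed: int | None = None) -> Cohort:
    """One session plus spike trains and the ground-truth label table."""
    if len(neuron_specs) < 1:
        raise ValueError("at least one neuron spec required")
    ids = [s.neuron_id for s in neuron_specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate neuron ids")
    session = generate_session(cfg)
    root = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    for spec in neuron_specs:
        trains = generate_neuron(spec, session, cfg, root.spawn(1)[0])
        session.add_neuron(spec.neuron_id, trains)
        vspec = (V.VARIABLE_BY_NAME.get(spec.encoded_variable)
                 if spec.encoded_variable != "untuned" else None)
        rows.append({
            "neuron_id": spec.neuron_id,
            "encoded_variable": spec.encoded_variable,
            "collapsed": vspec.collapsed_parent if vspec else "untuned",
            "baseline_rate": spec.baseline_rate,
            "slope": spec.slope, "sign": spec.sign,
            "tuned_windows": ";".join(spec.tuned_windows),
        })
    return Cohort(session=session, ground_truth=pd.DataFrame(rows))


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = write_session(cohort.session, out_dir)
    cohort.ground_truth.to_csv(Path(out) / "ground_truth.csv", index=False)
    return out
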