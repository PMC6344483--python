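"""Response matrix construction and the task-relatedness ANOVA screen.

A "response" is the activity of one neuron in one of the nine peri-event
windows as a function of the trial type.  Each response is screened with two
three-way main-effects ANOVAs on firing rates — factors (trial type x offer A
location x target A location) and (trial type x chosen offer location x
chosen target location) — and called task-related when any factor is
significant at p < 0.001.  The trial-type factor is shared between the two
ANOVAs and computed once.

The ANOVA uses type-II sums of squares (full model vs model dropping one
factor), implemented directly on orthonormal bases for speed across the
thousands of responses a cohort produces; tests cross-check it against
statsmodels' anova_lm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task_core import Session, WINDOWS, WINDOW_BY_NAME, WINDOW_NAMES, count_spikes, window_interval

__all__ = [
    "ResponseMatrix",
    "windowed_rates",
    "build_response_matrix",
    "anova_screen",
    "task_related_set",
    "table1_tally",
    "FACTORS",
]

FACTORS = ("trial_type", "offerA_loc", "targetA_loc", "chosen_offer_loc", "chosen_target_loc")


@dataclass
class ResponseMatrix:
    """Spike counts and rates per neuron x window x trial (NaN = missing cell)."""

    neuron_ids: list[str]
    counts: np.ndarray  # (n_neurons, 9, n_trials)
    rates: np.ndarray

    def rates_for(self, neuron: str, window: str) -> np.ndarray:
        i = self.neuron_ids.index(neuron)
        j = WINDOW_NAMES.index(window)
        return self.rates[i, j]

    def counts_for(self, neuron: str, window: str) -> np.ndarray:
        i = self.neuron_ids.index(neuron)
        j = WINDOW_NAMES.index(window)
        return self.counts[i, j]


def windowed_rates(session: Session, neuron: str) -> tuple[np.ndarray, np.ndarray]:
    """Counts and rates (counts / window duration) for one neuron, (9, n_trials)."""
    trains = session.spikes[neuron]
    n = session.n_trials
    counts = np.full((len(WINDOWS), n), np.nan)
    rates = np.full((len(WINDOWS), n), np.nan)
    durations = np.array([w.duration for w in WINDOWS])
    for i, trial in enumerate(session.trials):
        edges = np.empty(2 * len(WINDOWS))
        for j, w in enumerate(WINDOWS):
            try:
                edges[2 * j], edges[2 * j + 1] = window_interval(w, trial.events)
            except KeyError:
                edges[2 * j] = edges[2 * j + 1] = np.nan  # missing anchor
        idx = np.searchsorted(trains[i], edges, side="left").astype(float)
        idx[np.isnan(edges)] = np.nan
        c = idx[1::2] - idx[0::2]
        counts[:, i] = c
        rates[:, i] = c / durations
    return counts, rates


def build_response_matrix(session: Session, neurons: Sequence[str] | None = None) -> ResponseMatrix:
    ids = list(neurons) if neurons is not None else session.neuron_ids
    counts = np.empty((len(ids), len(WINDOWS), session.n_trials))
    rates = np.empty_like(counts)
    for k, nid in enumerate(ids):
        counts[k], rates[k] = windowed_rates(session, nid)
    return ResponseMatrix(neuron_ids=ids, counts=counts, rates=rates)


# --- fast type-II main-effects ANOVA ------------------------------------------

def _dummies(labels: np.ndarray) -> np.ndarray | None:
    levels = pd.unique(labels)
    if len(levels) < 2:
        return None
    idx = pd.Categorical(labels, categories=levels).codes
    d = np.zeros((len(labels), len(levels) - 1))
    for k in range(1, len(levels)):
        d[idx == k, k - 1] = 1.0
    return d


def _basis(blocks: list[np.ndarray], n: int) -> tuple[np.ndarray, int]:
    """Orthonormal column basis of [1 | blocks]; returns (U, rank)."""
    X = np.hstack([np.ones((n, 1))] + blocks) if blocks else np.ones((n, 1))
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps
    r = int((s > tol).sum())
    return u[:, :r], r


class _AnovaDesign:
    """Precomputed bases for a three-way main-effects ANOVA on fixed factors."""

    def __init__(self, factors: dict[str, np.ndarray]):
        n = len(next(iter(factors.values())))
        self.n = n
        self.blocks = {}
        for name, labels in factors.items():
            self.blocks[name] = _dummies(np.asarray(labels))
        usable = [b for b in self.blocks.values() if b is not None]
        self.full_U, self.full_rank = _basis(usable, n)
        self.reduced = {}
        for name, b in self.blocks.items():
            if b is None:
                continue
            others = [v for k, v in self.blocks.items() if k != name and v is not None]
            self.reduced[name] = _basis(others, n)

    def factor_pvalues(self, y: np.ndarray) -> dict[str, float]:
        """Type-II F-test p-value per factor; NaN for degenerate factors."""
        n = self.n
        yty = float(y @ y)
        proj_full = self.full_U.T @ y
        rss_full = max(yty - float(proj_full @ proj_full), 0.0)
        df_resid = n - self.full_rank
        out: dict[str, float] = {}
        for name, b in self.blocks.items():
            if b is None or df_resid <= 0:
                out[name] = np.nan
                continue
            U_r, rank_r = self.reduced[name]
            proj_r = U_r.T @ y
            rss_r = max(yty - float(proj_r @ proj_r), 0.0)
            df_f = self.full_rank - rank_r
            if df_f <= 0 or rss_full <= 0:
                out[name] = np.nan
                continue
            F = ((rss_r - rss_full) / df_f) / (rss_full / df_resid)
            out[name] = float(stats.f.sf(F, df_f, df_resid))
        return out


def _trial_factors(session: Session) -> pd.DataFrame:
    rows = []
    for t in session.trials:
        rows.append({
            "trial_type": t.trial_type,
            "offerA_loc": t.offerA_side,
            "targetA_loc": t.targetA_side,
            "chosen_offer_loc": t.chosen_offer_side,
            "chosen_target_loc": t.chosen_target_side,
        })
    return pd.DataFrame(rows)


def anova_screen(matrix: ResponseMatrix, session: Session, alpha: float = 0.001) -> pd.DataFrame:
    """Screen every response; returns one row per (neuron, window).

    Columns: p_<factor> for the five factors and the task_related flag
    (min available factor p < alpha).  Trial-type levels with fewer than two
    trials are dropped before fitting.
    """
    fac = _trial_factors(session)
    tt_counts = fac["trial_type"].value_counts()
    keep = fac["trial_type"].map(tt_counts) >= 2
    fac = fac[keep.to_numpy()]
    kept_idx = np.flatnonzero(keep.to_numpy())
    d1 = _AnovaDesign({"trial_type": fac["trial_type"].to_numpy(),
                       "offerA_loc": fac["offerA_loc"].to_numpy(),
                       "targetA_loc": fac["targetA_loc"].to_numpy()})
    d2 = _AnovaDesign({"trial_type": fac["trial_type"].to_numpy(),
                       "chosen_offer_loc": fac["chosen_offer_loc"].to_numpy(),
                       "chosen_target_loc": fac["chosen_target_loc"].to_numpy()})
    rows = []
    for i, nid in enumerate(matrix.neuron_ids):
        for j, wname in enumerate(WINDOW_NAMES):
            y = matrix.rates[i, j, kept_idx]
            ok = np.isfinite(y)
            record = {"neuron": nid, "window": wname}
            if ok.sum() < 3 or np.ptp(y[ok]) == 0:
                for f in FACTORS:
                    record[f"p_{f}"] = np.nan
                record["task_related"] = False
                rows.append(record)
                continue
            if not ok.all():
                # missing cells: rebuild designs on the available subset
                sub = fac.iloc[np.flatnonzero(ok)]
                dd1 = _AnovaDesign({k: sub[k].to_numpy() for k in
                                    ("trial_type", "offerA_loc", "targetA_loc")})
                dd2 = _AnovaDesign({k: sub[k].to_numpy() for k in
                                    ("trial_type", "chosen_offer_loc", "chosen_target_loc")})
                p1 = dd1.factor_pvalues(y[ok])
                p2 = dd2.factor_pvalues(y[ok])
            else:
                p1 = d1.factor_pvalues(y)
                p2 = d2.factor_pvalues(y)
            record["p_trial_type"] = p1["trial_type"]  # shared factor, computed once
            record["p_offerA_loc"] = p1["offerA_loc"]
            record["p_targetA_loc"] = p1["targetA_loc"]
            record["p_chosen_offer_loc"] = p2["chosen_offer_loc"]
            record["p_chosen_target_loc"] = p2["chosen_target_loc"]
            ps = np.array([record[f"p_{f}"] for f in FACTORS], float)
            record["task_related"] = bool(np.nanmin(ps) < alpha) if np.any(np.isfinite(ps)) else False
            rows.append(record)
    return pd.DataFrame(rows)


def task_related_set(relatedness: pd.DataFrame) -> tuple[list[tuple[str, str]], list[str]]:
    """Responses passing the screen and the cells contributing at least one."""
    if len(relatedness) == 0:
        return [], []
    sig = relatedness[relatedness["task_related"].astype(bool)]
    responses = list(zip(sig["neuron"], sig["window"]))
    cells = list(pd.unique(sig["neuron"]))
    return responses, cells


def table1_tally(relatedness: pd.DataFrame, alpha: float = 0.001) -> pd.DataFrame:
    """Window x factor counts of significant responses, plus an 'at least 1' row."""
    out = {}
    for f in FACTORS:
        col = relatedness[f"p_{f}"]
        sig = relatedness[col < alpha]
        out[f] = sig.groupby("window").size().reindex(WINDOW_NAMES, fill_value=0)
    tab = pd.DataFrame(out)
    at_least = {f: relatedness.loc[relatedness[f"p_{f}"] < alpha, "neuron"].nunique()
                for f in FACTORS}
    tab.loc["at_least_one_window"] = pd.Series(at_least)
    return tab
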