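"""Candidate encoded variables, response regressions, and variable selection.

The catalog holds 19 trial-level regressors spanning four reference frames
(commodity, cost, visual/offer location, action/target location) plus
frame-association binaries and the chosen value.  Offer values are expressed
in units of juice B using the session's behavioral estimates of the relative
value rho and the action cost xi: value(A) = rho*#A + xi*1[A low cost],
value(B) = #B + xi*1[B low cost].

Per-response linear regressions, collapsed-variable R2 bookkeeping, and the
two selection procedures (stepwise, exhaustive best-subset) live here, as
does the final cell classification by largest summed R2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task_core import Cost, Session, Trial, WINDOW_NAMES

__all__ = [
    "VariableSpec",
    "CATALOG",
    "COLLAPSED",
    "COLLAPSED_ORDER",
    "PRE_TARGET_WINDOWS",
    "POST_TARGET_WINDOWS",
    "RegressionResult",
    "SelectionResult",
    "CellClassification",
    "evaluate_variable",
    "variable_values",
    "regress_response",
    "collapse_r2",
    "best_fit_assignment",
    "regress_catalog",
    "collapse_table",
    "stepwise_selection",
    "best_subset_selection",
    "classify_cells",
]

# Variable-selection epochs: the task transitions from choice to action at
# target onset, so selection runs separately before and after it.  The
# pre-offer window is baseline and belongs to neither epoch.
PRE_TARGET_WINDOWS = ("post_offer", "late_delay", "mem_delay", "pre_target")
POST_TARGET_WINDOWS = ("post_target", "pre_go", "pre_juice", "post_juice")


def _value_A(t: Trial, rho: float, xi: float, cost_term: bool = True) -> float:
    v = rho * t.offer.qA
    if cost_term and t.offer.costA == Cost.LOW:
        v += xi
    return v


def _value_B(t: Trial, rho: float, xi: float, cost_term: bool = True) -> float:
    v = float(t.offer.qB)
    if cost_term and t.offer.costB == Cost.LOW:
        v += xi
    return v


def _value_of(t: Trial, juice: str, rho: float, xi: float, cost_term: bool = True) -> float:
    return _value_A(t, rho, xi, cost_term) if juice == "A" else _value_B(t, rho, xi, cost_term)


def _juice_with_cost(t: Trial, cost: str) -> str:
    return "A" if t.offer.costA == cost else "B"


def _juice_on_side(t: Trial, side: str) -> str:
    return "A" if t.offerA_side == side else "B"


def _juice_with_target_side(t: Trial, side: str) -> str:
    return "A" if t.targetA_side == side else "B"


@dataclass(frozen=True)
class VariableSpec:
    """One catalog regressor: identity, reference frame, and trial evaluator.

    ``variant_mode`` names the dimensional-integration contrast available for
    the variable: cost variants for juice-based values, commodity variants
    for cost-based values, n/a otherwise.  The "independent" variant removes
    exactly the determinant under test (the xi cost term, or rho).
    """

    id: int
    name: str
    reference_frame: str
    collapsed_parent: str
    variant_mode: str  # "cost", "commodity", or "n/a"
    _eval: Callable[[Trial, float, float, str], float]

    def evaluate(self, trial: Trial, rho: float, xi: float, variant: str = "affected") -> float:
        if variant not in ("affected", "independent"):
            raise ValueError(f"unknown variant {variant!r}")
        return self._eval(trial, rho, xi, variant)


def _ev_offer_value_A(t, rho, xi, variant):
    return _value_A(t, rho, xi, cost_term=(variant == "affected"))


def _ev_offer_value_B(t, rho, xi, variant):
    return _value_B(t, rho, xi, cost_term=(variant == "affected"))


def _ev_chosen_juice(t, rho, xi, variant):
    return 1.0 if t.chosen_juice == "B" else 0.0


def _ev_offer_value_minus(t, rho, xi, variant):
    j = _juice_with_cost(t, Cost.HIGH)
    if variant == "independent":  # commodity-independent: raw quantity, rho -> 1
        return _value_of(t, j, 1.0, xi)
    return _value_of(t, j, rho, xi)


def _ev_offer_value_plus(t, rho, xi, variant):
    j = _juice_with_cost(t, Cost.LOW)
    if variant == "independent":
        return _value_of(t, j, 1.0, xi)
    return _value_of(t, j, rho, xi)


def _ev_chosen_cost(t, rho, xi, variant):
    return 1.0 if t.chosen_cost == Cost.LOW else 0.0


def _ev_offer_value_L(t, rho, xi, variant):
    return _value_of(t, _juice_on_side(t, "L"), rho, xi)


def _ev_offer_value_R(t, rho, xi, variant):
    return _value_of(t, _juice_on_side(t, "R"), rho, xi)


def _ev_chosen_location(t, rho, xi, variant):
    return 1.0 if t.chosen_offer_side == "L" else 0.0


def _ev_offer_value_target_L(t, rho, xi, variant):
    return _value_of(t, _juice_with_target_side(t, "L"), rho, xi)


def _ev_offer_value_target_R(t, rho, xi, variant):
    return _value_of(t, _juice_with_target_side(t, "R"), rho, xi)


def _ev_chosen_target(t, rho, xi, variant):
    return 1.0 if t.chosen_target_side == "L" else 0.0


def _ev_cost_of_A(t, rho, xi, variant):
    return 1.0 if t.offer.costA == Cost.LOW else 0.0


def _ev_offer_A_location(t, rho, xi, variant):
    return 1.0 if t.offerA_side == "L" else 0.0


def _ev_target_A_location(t, rho, xi, variant):
    return 1.0 if t.targetA_side == "L" else 0.0


def _ev_offer_plus_location(t, rho, xi, variant):
    side = t.offerA_side if t.offer.costA == Cost.LOW else t.offerB_side
    return 1.0 if side == "L" else 0.0


def _ev_target_plus_location(t, rho, xi, variant):
    side = t.targetA_side if t.offer.costA == Cost.LOW else t.targetB_side
    return 1.0 if side == "L" else 0.0


def _ev_spatial_congruence(t, rho, xi, variant):
    # congruent iff each juice's offer and target share a hemifield; with the
    # two offers and the two targets in opposite hemifields, congruence for A
    # implies congruence for B
    return 1.0 if t.offerA_side == t.targetA_side else 0.0


def _ev_chosen_value(t, rho, xi, variant):
    return _value_of(t, t.chosen_juice, rho, xi, cost_term=(variant == "affected"))


CATALOG: dict[int, VariableSpec] = {s.id: s for s in (
    VariableSpec(1, "offer value A", "commodity", "offer value (juice)", "cost", _ev_offer_value_A),
    VariableSpec(2, "offer value B", "commodity", "offer value (juice)", "cost", _ev_offer_value_B),
    VariableSpec(3, "chosen juice", "commodity", "chosen juice", "n/a", _ev_chosen_juice),
    VariableSpec(4, "offer value -", "cost", "offer value (cost)", "commodity", _ev_offer_value_minus),
    VariableSpec(5, "offer value +", "cost", "offer value (cost)", "commodity", _ev_offer_value_plus),
    VariableSpec(6, "chosen cost", "cost", "chosen cost", "n/a", _ev_chosen_cost),
    VariableSpec(7, "offer value L", "visual", "offer value (location)", "n/a", _ev_offer_value_L),
    VariableSpec(8, "offer value R", "visual", "offer value (location)", "n/a", _ev_offer_value_R),
    VariableSpec(9, "chosen location", "visual", "chosen location", "n/a", _ev_chosen_location),
    VariableSpec(10, "offer value target L", "action", "offer value (target)", "n/a", _ev_offer_value_target_L),
    VariableSpec(11, "offer value target R", "action", "offer value (target)", "n/a", _ev_offer_value_target_R),
    VariableSpec(12, "chosen target", "action", "chosen target", "n/a", _ev_chosen_target),
    VariableSpec(13, "cost of A", "mixed", "cost of A", "n/a", _ev_cost_of_A),
    VariableSpec(14, "offer A location", "mixed", "offer A location", "n/a", _ev_offer_A_location),
    VariableSpec(15, "target A location", "mixed", "target A location", "n/a", _ev_target_A_location),
    VariableSpec(16, "offer + location", "mixed", "offer + location", "n/a", _ev_offer_plus_location),
    VariableSpec(17, "target + location", "mixed", "target + location", "n/a", _ev_target_plus_location),
    VariableSpec(18, "spatial congruence", "mixed", "spatial congruence", "n/a", _ev_spatial_congruence),
    VariableSpec(19, "chosen value", "commodity", "chosen value", "cost", _ev_chosen_value),
)}

VARIABLE_BY_NAME = {s.name: s for s in CATALOG.values()}

# Collapsed variables in catalog order; a collapsed variable is credited with
# the larger R2 of its component variables.
COLLAPSED: dict[str, tuple[int, ...]] = {}
for _s in CATALOG.values():
    COLLAPSED.setdefault(_s.collapsed_parent, tuple())
    COLLAPSED[_s.collapsed_parent] = COLLAPSED[_s.collapsed_parent] + (_s.id,)
COLLAPSED_ORDER = tuple(COLLAPSED.keys())


def evaluate_variable(spec: VariableSpec | int, trial: Trial, fit, variant: str = "affected") -> float:
    """Evaluate one catalog variable on one trial.

    ``fit`` is anything exposing ``rho`` and ``xi`` (a behavioral fit or the
    generating indices).
    """
    if isinstance(spec, int):
        spec = CATALOG[spec]
    rho, xi = float(fit.rho), float(fit.xi)
    if not np.isfinite(rho) or not np.isfinite(xi):
        raise ValueError("variable evaluation requires finite rho and xi")
    return spec.evaluate(trial, rho, xi, variant)


def variable_values(spec: VariableSpec | int, session: Session, fit,
                    variant: str = "affected") -> np.ndarray:
    if isinstance(spec, int):
        spec = CATALOG[spec]
    rho, xi = float(fit.rho), float(fit.xi)
    return np.array([spec.evaluate(t, rho, xi, variant) for t in session.trials])


# --- per-response regression ---------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p_slope: float
    r2_raw: float
    n_points: int
    constant: bool = False

    @property
    def r2_effective(self) -> float:
        """R2 zeroed when the slope is not significant (p >= 0.05)."""
        if self.constant or not np.isfinite(self.p_slope) or self.p_slope >= 0.05:
            return 0.0
        return self.r2_raw

    @property
    def explains(self) -> bool:
        return self.r2_effective > 0.0


_CONSTANT = RegressionResult(np.nan, np.nan, np.nan, 0.0, 0, constant=True)


def regress_response(rates: np.ndarray, values: np.ndarray,
                     group_keys: Sequence | None = None,
                     level: str = "type") -> RegressionResult:
    """OLS of a response on a variable, by default at the trial-type level.

    With ``level='type'`` trials are grouped by (group key, variable value)
    and group-mean rates are regressed on the variable; spatial variables,
    which vary within a trial type, thereby split each type by the spatial
    attribute.  ``level='trial'`` regresses raw per-trial rates.
    """
    rates = np.asarray(rates, float)
    values = np.asarray(values, float)
    if rates.shape != values.shape:
        raise ValueError("rates and values must align")
    if level == "type":
        if group_keys is None:
            raise ValueError("type-level regression needs group keys")
        df = pd.DataFrame({"g": list(group_keys), "v": values, "r": rates})
        m = df.groupby(["g", "v"], sort=False)["r"].mean().reset_index()
        x, y = m["v"].to_numpy(), m["r"].to_numpy()
    elif level == "trial":
        x, y = values, rates
    else:
        raise ValueError(f"unknown level {level!r}")
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return _CONSTANT
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            p_slope=float(res.pvalue), r2_raw=float(res.rvalue ** 2),
                            n_points=int(x.size))


def collapse_r2(components: Mapping[int, RegressionResult]) -> tuple[float, int | None]:
    """Collapsed R2 = max effective R2 among components; returns (r2, winner id)."""
    if not components:
        raise ValueError("at least one component required")
    best_id, best = None, 0.0
    for vid in sorted(components):
        r2 = components[vid].r2_effective
        if r2 > best:
            best, best_id = r2, vid
    return best, best_id


def best_fit_assignment(collapsed: Mapping[str, float]) -> str | None:
    """Variable with the largest (positive) R2; None if nothing explains.

    Ties broken by catalog order of the collapsed variable.
    """
    best_name, best = None, 0.0
    for name in COLLAPSED_ORDER:
        if name in collapsed and collapsed[name] > best:
            best, best_name = collapsed[name], name
    return best_name


def regress_catalog(session: Session, rmatrix, fit,
                    responses: Sequence[tuple[str, str]],
                    variants: Mapping[int, str] | None = None,
                    level: str = "type") -> pd.DataFrame:
    """Regress every response on every catalog variable.

    ``responses`` is a list of (neuron_id, window) pairs; ``variants`` maps a
    variable id to 'affected'/'independent' (default 'affected').  Returns a
    long table with one row per response x variable.
    """
    variants = dict(variants or {})
    types = [t.trial_type for t in session.trials]
    values = {vid: variable_values(vid, session, fit, variants.get(vid, "affected"))
              for vid in CATALOG}
    rows = []
    for neuron, window in responses:
        rates = rmatrix.rates_for(neuron, window)
        ok = np.isfinite(rates)
        for vid, spec in CATALOG.items():
            res = regress_response(rates[ok], values[vid][ok],
                                   group_keys=[types[i] for i in np.flatnonzero(ok)],
                                   level=level)
            rows.append((neuron, window, vid, spec.name, spec.collapsed_parent,
                         res.slope, res.p_slope, res.r2_raw, res.r2_effective))
    return pd.DataFrame(rows, columns=[
        "neuron", "window", "variable_id", "variable", "collapsed",
        "slope", "p_slope", "r2_raw", "r2_effective"])


def collapse_table(reg: pd.DataFrame) -> pd.DataFrame:
    """Collapse a regress_catalog table to one row per response x collapsed variable."""
    idx = reg.groupby(["neuron", "window", "collapsed"], sort=False)["r2_effective"].idxmax()
    out = reg.loc[idx, ["neuron", "window", "collapsed", "variable_id",
                        "slope", "p_slope", "r2_raw", "r2_effective"]].copy()
    out["explains"] = out["r2_effective"] > 0
    return out.reset_index(drop=True)


# --- selection -----------------------------------------------------------------

@dataclass
class SelectionResult:
    epoch: str
    procedure: str
    selected: list[str]
    trace: list[dict]
    n_responses: int

    @property
    def explained_counts(self) -> list[int]:
        return [s["newly_explained"] for s in self.trace]


def _pivot(collapsed: pd.DataFrame, windows: Sequence[str]):
    if len(collapsed) == 0:
        return pd.DataFrame(index=pd.MultiIndex.from_arrays([[], []],
                                                            names=["neuron", "window"]))
    sub = collapsed[collapsed["window"].isin(windows)]
    r2 = sub.pivot_table(index=["neuron", "window"], columns="collapsed",
                         values="r2_effective", fill_value=0.0)
    # keep catalog order for deterministic tie-breaks
    cols = [c for c in COLLAPSED_ORDER if c in r2.columns]
    return r2[cols]


def stepwise_selection(collapsed: pd.DataFrame, epoch: str,
                       windows: Sequence[str] | None = None,
                       stop_fraction: float = 0.05,
                       removal: str = "best_fit") -> SelectionResult:
    """Iterative select-and-remove over collapsed variables.

    At each step the variable providing the highest number of best fits
    within any single time window is selected (ties broken by total best
    fits, then catalog order) and the responses it accounts for are removed.
    ``removal='best_fit'`` (default) removes the responses the variable
    best-fits; ``removal='explained'`` removes every response the variable
    explains (slope p < 0.05).  With correlated value variables the
    'explained' rule lets the first value variable absorb the responses of
    all the others, so the best-fit rule is the default (see the methods
    note).  The procedure stops when the candidate's marginal explanatory
    power falls below ``stop_fraction``; under the best-fit rule marginal
    power is the increment in summed best-member R2 per epoch response (the
    same measure best-subset optimizes, so the two procedures stop on the
    same scale), under the explained rule it is the fraction of epoch
    responses newly explained.
    """
    if removal not in ("best_fit", "explained"):
        raise ValueError(f"unknown removal rule {removal!r}")
    if windows is None:
        windows = PRE_TARGET_WINDOWS if epoch == "pre_target" else POST_TARGET_WINDOWS
    r2 = _pivot(collapsed, windows)
    total = len(r2)
    selected: list[str] = []
    trace: list[dict] = []
    if total == 0:
        return SelectionResult(epoch, "stepwise", selected, trace, 0)
    remaining = r2.copy()
    variables = list(r2.columns)
    all_vals = r2.to_numpy()
    all_cols = list(r2.columns)
    picked_cols: list[int] = []
    prev_power = 0.0
    while len(remaining) and variables:
        vals = remaining[variables].to_numpy()
        explained_any = vals.max(axis=1) > 0
        # best-fit indicator: variable attains the row max (ties -> first in
        # catalog order, keeping one best fit per response)
        bf = np.zeros_like(vals, dtype=bool)
        rows_idx = np.flatnonzero(explained_any)
        arg = vals[rows_idx].argmax(axis=1)
        bf[rows_idx, arg] = True
        win = np.asarray(remaining.index.get_level_values("window"))
        per_window = pd.DataFrame(bf, columns=variables).groupby(win).sum()
        score = per_window.max(axis=0)  # highest # best fits within any window
        totals = per_window.sum(axis=0)
        order = pd.DataFrame({"score": score, "total": totals,
                              "rank": [variables.index(v) for v in score.index]})
        order = order.sort_values(["score", "total", "rank"], ascending=[False, False, True])
        pick = order.index[0]
        if removal == "explained":
            remove_mask = remaining[pick].to_numpy() > 0
            newly = int(remove_mask.sum())
            marginal = newly / total
        else:
            remove_mask = bf[:, variables.index(pick)]
            newly = int(remove_mask.sum())
            power, _ = subset_power(all_vals, picked_cols + [all_cols.index(pick)])
            marginal = (power - prev_power) / total
        if marginal < stop_fraction or newly == 0:
            break
        selected.append(pick)
        trace.append({"variable": pick, "newly_explained": newly,
                      "marginal_power": marginal,
                      "best_fits_max_window": int(order.iloc[0]["score"]),
                      "best_fits_total": int(order.iloc[0]["total"])})
        if removal == "best_fit":
            picked_cols.append(all_cols.index(pick))
            prev_power, _ = subset_power(all_vals, picked_cols)
        remaining = remaining[~remove_mask]
        variables.remove(pick)
    return SelectionResult(epoch, "stepwise", selected, trace, total)


def subset_power(r2_matrix: np.ndarray, cols: Sequence[int]) -> tuple[float, int]:
    """Explanatory power of a variable subset on a response x variable R2 matrix.

    Power = sum over responses of the best member R2 (0 if none explains);
    also returns the count of responses explained by >= 1 member.
    """
    sub = r2_matrix[:, list(cols)]
    best = sub.max(axis=1)
    return float(best.sum()), int((best > 0).sum())


def best_subset_selection(collapsed: pd.DataFrame, epoch: str,
                          windows: Sequence[str] | None = None,
                          n_max: int | None = None,
                          stop_fraction: float = 0.05,
                          objective: str = "total_r2") -> SelectionResult:
    """Exhaustive best-subset search over collapsed variables.

    For each subset size n the subset maximizing the explanatory power is
    found by enumeration (guaranteed optimal).  With
    ``objective='total_r2'`` (default) power is the summed best-member
    effective R2 over responses, ties broken by more responses explained,
    then catalog order; with ``objective='count'`` power is the number of
    responses explained by >= 1 member, ties broken by larger summed R2,
    then catalog order.  The reported selected set is the optimum at the
    largest n whose gain over n-1 is at least ``stop_fraction`` (gain is
    measured per response: newly explained count, or power increment, over
    the number of epoch responses); the full per-n trace is returned.
    """
    if objective not in ("total_r2", "count"):
        raise ValueError(f"unknown objective {objective!r}")
    if windows is None:
        windows = PRE_TARGET_WINDOWS if epoch == "pre_target" else POST_TARGET_WINDOWS
    r2 = _pivot(collapsed, windows)
    total = len(r2)
    if total == 0:
        return SelectionResult(epoch, "best_subset", [], [], 0)
    variables = list(r2.columns)
    vals = r2.to_numpy()
    k = len(variables)
    if n_max is None or n_max > k:
        n_max = k
    trace: list[dict] = []
    prev_power, prev_count = 0.0, 0
    selected: list[str] = []
    max_count = int((vals.max(axis=1) > 0).sum())
    max_power = float(vals.max(axis=1).sum())
    for n in range(1, n_max + 1):
        best_combo, best_power, best_count = None, -np.inf, -1
        for combo in itertools.combinations(range(k), n):
            power, count = subset_power(vals, combo)
            if objective == "total_r2":
                key = (power, count)
                best_key = (best_power, best_count)
            else:
                key = (count, power)
                best_key = (best_count, best_power)
            if key[0] > best_key[0] + 1e-12 or (
                    abs(key[0] - best_key[0]) <= 1e-12 and key[1] > best_key[1] + 1e-12):
                best_combo, best_power, best_count = combo, power, count
        subset = [variables[i] for i in best_combo]
        if objective == "total_r2":
            gain = (best_power - prev_power) / total
        else:
            gain = (best_count - prev_count) / total
        trace.append({"n": n, "subset": subset, "explained": best_count,
                      "power": best_power, "gain": gain})
        if n == 1 or gain >= stop_fraction:
            selected = subset
        else:
            break
        prev_power, prev_count = best_power, best_count
        if best_count == max_count and best_power >= max_power - 1e-12:
            break  # nothing left to gain
    return SelectionResult(epoch, "best_subset", selected, trace, total)


# --- cell classification --------------------------------------------------------

@dataclass
class CellClassification:
    table: pd.DataFrame  # neuron, assigned, sum_r2, encoded_level, tie

    def cells_for(self, variable: str) -> list[str]:
        t = self.table
        return list(t.loc[t["assigned"] == variable, "neuron"])


def classify_cells(collapsed: pd.DataFrame, selected: Iterable[str],
                   windows: Sequence[str] = WINDOW_NAMES) -> CellClassification:
    """Assign each cell to the selected variable with the largest summed R2.

    The sum runs over all nine time windows.  For chosen-juice (chosen-cost)
    cells the encoded level is the juice (cost) eliciting higher firing,
    read from the sign of the summed-R2-weighted slope of the binary
    regressor (variable = 1 for juice B / low cost).
    """
    selected = [v for v in COLLAPSED_ORDER if v in set(selected)]
    sub = collapsed[collapsed["window"].isin(windows) & collapsed["collapsed"].isin(selected)]
    rows = []
    for neuron, grp in sub.groupby("neuron", sort=False):
        sums = grp.groupby("collapsed")["r2_effective"].sum()
        sums = sums.reindex(selected, fill_value=0.0)
        if float(sums.max()) <= 0:
            rows.append({"neuron": neuron, "assigned": None, "sum_r2": 0.0,
                         "encoded_level": None, "tie": False})
            continue
        top = float(sums.max())
        winners = [v for v in selected if sums[v] >= top - 1e-12]
        assigned = winners[0]
        level = None
        if assigned in ("chosen juice", "chosen cost"):
            g = grp[(grp["collapsed"] == assigned) & (grp["r2_effective"] > 0)]
            w = float((g["slope"] * g["r2_effective"]).sum())
            if assigned == "chosen juice":
                level = "B" if w > 0 else "A"
            else:
                level = Cost.LOW if w > 0 else Cost.HIGH
        rows.append({"neuron": neuron, "assigned": assigned, "sum_r2": top,
                     "encoded_level": level, "tie": len(winners) > 1})
    return CellClassification(pd.DataFrame(
        rows, columns=["neuron", "assigned", "sum_r2", "encoded_level", "tie"]))
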