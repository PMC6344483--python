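"""Logistic choice model with action-cost, hysteresis, and spatial-bias terms.

Choice of juice B is modeled as P(B) = 1 / (1 + exp(-X)) with

    X = a0*#B - a1*#A + a2*(d_B+ - d_A+) + a3*(d_{n-1,B} - d_{n-1,A})
        + a4*(d_{costB=cost n-1} - d_{costA=cost n-1})
        + a5*(d_offerB,L - d_offerA,L) + a6*(d_targetB,L - d_targetA,L)

where d_J+ = 1 if juice J is offered at low cost, d_{n-1,J} = 1 if juice J
was chosen on the previous trial, d_{costJ = cost n-1} = 1 if J's cost level
matches the previously chosen cost, and the last two indicators mark the
offer and target of J appearing in the left hemifield.  Normalizing by a0
expresses every effect in units of juice B: relative value rho = a1/a0,
action cost xi = a2/a0, juice hysteresis eta = a3/a0, cost hysteresis
phi = a4/a0, offer-side bias delta = a5/a0, target-side bias eps = a6/a0.

Sessions with a significant target-side bias (eps) are screened out, since a
spatial bias confounds the question of whether choices are resolved in a
non-spatial (goods-based) representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .task_core import Cost, Session, Trial

__all__ = [
    "LogisticFit",
    "ChoicePatternSummary",
    "design_matrix",
    "fit_choice_model",
    "fit_simplified_model",
    "screen_session",
    "summarize_choice_pattern",
    "population_summary",
    "INDEX_NAMES",
]

INDEX_NAMES = ("rho", "xi", "eta", "phi", "delta", "eps")

# indices are ratios a_k/a0; below this |a0| they are numerically meaningless
DEGENERACY_THRESHOLD = 0.05


def trial_regressors(trial: Trial) -> np.ndarray:
    """The seven choice-model regressors for one trial (first-trial history terms 0)."""
    o = trial.offer
    x = np.empty(7)
    x[0] = o.qB
    x[1] = -o.qA
    x[2] = (o.costB == Cost.LOW) - (o.costA == Cost.LOW)
    if trial.prev_chosen_juice == "none":
        x[3] = 0.0
        x[4] = 0.0
    else:
        x[3] = (trial.prev_chosen_juice == "B") - (trial.prev_chosen_juice == "A")
        x[4] = (o.costB == trial.prev_chosen_cost) - (o.costA == trial.prev_chosen_cost)
    x[5] = (trial.offerB_side == "L") - (trial.offerA_side == "L")
    x[6] = (trial.targetB_side == "L") - (trial.targetA_side == "L")
    return x


def design_matrix(session: Session) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial regressor matrix (n x 7) and chose-B indicator vector."""
    X = np.array([trial_regressors(t) for t in session.trials])
    y = np.array([t.chosen_juice == "B" for t in session.trials], dtype=float)
    return X, y


@dataclass
class LogisticFit:
    """ML estimates of a0..a6 with Wald inference and the normalized indices.

    For the simplified model (terms a3..a6 removed) the unused slots are NaN.
    """

    a: np.ndarray  # length 7; NaN for terms not in the model
    se: np.ndarray
    p: np.ndarray
    llf: float
    n_trials: int
    converged: bool = True
    separation: bool = False
    terms: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)

    @property
    def degenerate(self) -> bool:
        return (not self.converged) or abs(self.a[0]) < DEGENERACY_THRESHOLD

    def _index(self, k: int) -> float:
        if self.degenerate or k not in self.terms:
            return np.nan
        return float(self.a[k] / self.a[0])

    @property
    def rho(self) -> float:
        return self._index(1)

    @property
    def xi(self) -> float:
        return self._index(2)

    @property
    def eta(self) -> float:
        return self._index(3)

    @property
    def phi(self) -> float:
        return self._index(4)

    @property
    def delta(self) -> float:
        return self._index(5)

    @property
    def eps(self) -> float:
        return self._index(6)

    def indices(self) -> dict[str, float]:
        return dict(zip(INDEX_NAMES, (self.rho, self.xi, self.eta, self.phi,
                                      self.delta, self.eps)))

    def to_dict(self) -> dict:
        return {
            "a": [None if not np.isfinite(v) else float(v) for v in self.a],
            "se": [None if not np.isfinite(v) else float(v) for v in self.se],
            "p": [None if not np.isfinite(v) else float(v) for v in self.p],
            "llf": float(self.llf), "n_trials": int(self.n_trials),
            "converged": bool(self.converged), "separation": bool(self.separation),
            "degenerate": bool(self.degenerate),
            "indices": {k: float(v) for k, v in self.indices().items()},
        }


def _ridge_logit(X: np.ndarray, y: np.ndarray, lam: float = 1e-3):
    """Ridge-penalized logistic fit used as a fallback under separation."""

    def nll(a):
        z = X @ a
        # log(1 + e^-z) for y=1, log(1 + e^z) for y=0, numerically stable
        return float(np.sum(np.logaddexp(0.0, -z) * y + np.logaddexp(0.0, z) * (1 - y))
                     + lam * np.sum(a ** 2))

    def grad(a):
        p = 1.0 / (1.0 + np.exp(-(X @ a)))
        return X.T @ (p - y) + 2 * lam * a

    res = optimize.minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS")
    a = res.x
    p = 1.0 / (1.0 + np.exp(-(X @ a)))
    W = p * (1 - p)
    H = (X * W[:, None]).T @ X + 2 * lam * np.eye(X.shape[1])
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.diag(cov))
    z = X @ a
    llf = -float(np.sum(np.logaddexp(0.0, -z) * y + np.logaddexp(0.0, z) * (1 - y)))
    return a, se, llf


def _fit(X: np.ndarray, y: np.ndarray, terms: tuple[int, ...]) -> LogisticFit:
    n = len(y)
    if n == 0:
        raise ValueError("empty session")
    if len(np.unique(y)) < 2:
        raise ValueError("session must contain both choice outcomes")
    Xs = X[:, list(terms)]
    a = np.full(7, np.nan)
    se = np.full(7, np.nan)
    p = np.full(7, np.nan)
    separation = False
    try:
        import warnings
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation warnings handled below
            model = sm.Logit(y, Xs)
            res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        coefs, ses, llf = res.params, res.bse, float(res.llf)
        if not converged or not np.all(np.isfinite(ses)) or np.max(np.abs(coefs)) > 50:
            raise RuntimeError("unstable ML fit")
    except Exception:
        separation = True
        coefs, ses, llf = _ridge_logit(Xs, y)
    a[list(terms)] = coefs
    se[list(terms)] = ses
    with np.errstate(all="ignore"):
        z = coefs / ses
        p[list(terms)] = 2 * stats.norm.sf(np.abs(z))
    return LogisticFit(a=a, se=se, p=p, llf=float(llf), n_trials=n,
                       converged=True, separation=separation, terms=terms)


def fit_choice_model(session: Session) -> LogisticFit:
    """ML fit of the full seven-term model; Wald p-values per coefficient."""
    X, y = design_matrix(session)
    return _fit(X, y, (0, 1, 2, 3, 4, 5, 6))


def fit_simplified_model(session: Session) -> LogisticFit:
    """Fit with the history and spatial terms (a3..a6) removed."""
    X, y = design_matrix(session)
    return _fit(X, y, (0, 1, 2))


def screen_session(fit: LogisticFit, alpha: float = 0.01) -> dict:
    """Keep a session unless the target-side bias eps is significant.

    Returns {'keep': bool, 'reason': str}.
    """
    if fit.degenerate:
        return {"keep": False, "reason": "degenerate fit (|a0| below threshold)"}
    p6 = fit.p[6]
    if np.isfinite(p6) and p6 < alpha:
        return {"keep": False, "reason": f"significant target-side bias (p={p6:.2g})"}
    return {"keep": True, "reason": ""}


@dataclass
class ChoicePatternSummary:
    """Percent-B-choice table split by cost configuration, plus indifference points.

    The indifference point is the #B:#A ratio at which the simplified model
    predicts P(B) = 0.5: rho + xi when A is low cost, rho - xi when A is
    high cost.
    """

    table: pd.DataFrame
    indifference_A_low: float
    indifference_A_high: float


def summarize_choice_pattern(session: Session, fit: LogisticFit | None = None) -> ChoicePatternSummary:
    if fit is None or set(fit.terms) != {0, 1, 2}:
        fit = fit_simplified_model(session)
    rows = []
    for t in session.trials:
        rows.append((t.offer.qA, t.offer.qB,
                     "A_low" if t.offer.costA == Cost.LOW else "A_high",
                     t.chosen_juice == "B"))
    df = pd.DataFrame(rows, columns=["qA", "qB", "cost_config", "chose_B"])
    tab = (df.groupby(["qA", "qB", "cost_config"])
             .agg(n=("chose_B", "size"), frac_B=("chose_B", "mean"))
             .reset_index())
    tab["ratio"] = np.where(tab.qA > 0, tab.qB / tab.qA, np.inf)
    tab = tab.sort_values(["ratio", "cost_config"]).reset_index(drop=True)
    rho, xi = fit.rho, fit.xi
    return ChoicePatternSummary(table=tab,
                                indifference_A_low=rho + xi,
                                indifference_A_high=rho - xi)


def population_summary(fits: list[LogisticFit], min_sessions: int = 6) -> pd.DataFrame:
    """Median and two-sided Wilcoxon signed-rank p (vs 0) per normalized index."""
    if len(fits) < min_sessions:
        raise ValueError(f"need at least {min_sessions} sessions, got {len(fits)}")
    rows = []
    for name in INDEX_NAMES:
        vals = np.array([f.indices()[name] for f in fits], float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            rows.append((name, np.nan, np.nan, 0))
            continue
        if np.all(vals == 0):
            pval = 1.0
        else:
            pval = float(stats.wilcoxon(vals).pvalue)
        rows.append((name, float(np.median(vals)), pval, int(vals.size)))
    return pd.DataFrame(rows, columns=["index", "median", "p_signed_rank", "n"])
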