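"""Cause-specific proportional-hazards regression with a time-dependent
SMN exposure via counting-process episodes.

Each survivor contributes (start, stop] episodes on the time-since-
diagnosis scale with delayed entry at 5 years: one unexposed episode up
to the SMN (if any), then an exposed episode to the terminating event.
For the cause-specific hazard of one event type, the competing event
simply censors the episode (event = 0).  The partial likelihood is
maximised by Newton-Raphson with step-halving; tied event times use the
Efron correction by default (Breslow available); the variance is the
model-based inverse information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._designs import COVARIATE_SETS, build_design
from .cohort import Cohort, ENTRY_TIME

__all__ = ["Episode", "CoxFitResult", "episodes_from_cohort", "fit_cox",
           "run_csh_suite", "ConvergenceError"]

log = logging.getLogger(__name__)

EPISODE_COLUMNS = ("subject_id", "start", "stop", "event")


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace):
        super().__init__(message)
        self.trace = trace


@dataclass
class Episode:
    subject_id: str
    start: float
    stop: float
    event: int
    covariates: dict = field(default_factory=dict)


def episodes_from_cohort(cohort: Cohort, cause: str = "cardiac",
                         exposure_mode: str = "binary") -> pd.DataFrame:
    """Counting-process table: one row per episode with entry at 5 years
    and a split exactly at the SMN time.  An SMN coinciding with the
    terminating event yields a single fully exposed episode (the SMN is
    taken as diagnosed first)."""
    df = cohort.df
    if (df["T"] <= ENTRY_TIME).any():
        raise ValueError("all subjects must have T > 5 (apply the "
                         "five-year exclusion first)")
    smn = df["smn_time"].values.astype(float)
    has_smn = ~np.isnan(smn)
    if np.any(smn[has_smn] < ENTRY_TIME):
        raise ValueError("smn_time < 5 encountered; invalid cohort")
    split = has_smn & (smn > ENTRY_TIME) & (smn < df["T"].values)
    exposed_whole = has_smn & ~split  # smn at entry or exactly at T

    ev = (df["e"].values == cause).astype(int)
    base_cols = [c for c in df.columns if c not in ("smn_time",)]

    first = df.loc[:, base_cols].copy()
    first["start"] = ENTRY_TIME
    first["stop"] = np.where(split, smn, df["T"].values)
    first["event"] = np.where(split, 0, ev)
    first["exposure"] = exposed_whole.astype(int)

    second = df.loc[split, base_cols].copy()
    second["start"] = smn[split]
    second["stop"] = df.loc[split, "T"].values
    second["event"] = ev[split]
    second["exposure"] = 1

    out = pd.concat([first, second], ignore_index=True)
    out = out.sort_values(["subject_id", "start"], kind="stable").reset_index(drop=True)
    if exposure_mode == "by_type":
        out["exposure_type"] = np.where(out["exposure"] == 1, out["smn_type"], "no_smn")
    return out


def _risk_sums(order_vals, X, w, t, side_arr, grad_dim):
    raise NotImplementedError  # not used; kept for clarity of intent


def _partial_likelihood(beta, X, start, stop, event, ties):
    """Log partial likelihood, gradient and information with delayed
    entry: risk set at t is {rows : start < t <= stop}.  Suffix sums over
    rows sorted by stop and by start give each risk-set aggregate as a
    difference of two cumulative tails."""
    n, p = X.shape
    eta = X @ beta
    eta -= eta.max()  # common factor cancels in the partial likelihood
    w = np.exp(eta)
    wX = w[:, None] * X
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)

    stop_ord = np.argsort(stop, kind="stable")
    start_ord = np.argsort(start, kind="stable")
    stop_sorted = stop[stop_ord]
    start_sorted = start[start_ord]

    def suffix(arr, order):
        a = arr[order]
        return np.concatenate([np.cumsum(a[::-1], axis=0)[::-1],
                               np.zeros((1,) + arr.shape[1:])])

    s0_stop, s0_start = suffix(w[:, None], stop_ord)[:, 0], suffix(w[:, None], start_ord)[:, 0]
    s1_stop, s1_start = suffix(wX, stop_ord), suffix(wX, start_ord)
    s2_stop, s2_start = suffix(wXX, stop_ord), suffix(wXX, start_ord)

    ev_times = np.unique(stop[event == 1])
    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for t in ev_times:
        i_stop = np.searchsorted(stop_sorted, t, side="left")
        i_start = np.searchsorted(start_sorted, t, side="left")
        S0 = s0_stop[i_stop] - s0_start[i_start]
        S1 = s1_stop[i_stop] - s1_start[i_start]
        S2 = s2_stop[i_stop] - s2_start[i_start]

        tied = (stop == t) & (event == 1)
        d = int(tied.sum())
        sum_eta = eta[tied].sum()
        sum_x = X[tied].sum(axis=0)
        loglik += sum_eta
        grad += sum_x
        if ties == "efron":
            T0 = w[tied].sum()
            T1 = wX[tied].sum(axis=0)
            T2 = wXX[tied].sum(axis=0)
            for l in range(d):
                f = l / d
                D0 = S0 - f * T0
                D1 = S1 - f * T1
                D2 = S2 - f * T2
                loglik -= np.log(D0)
                v = D1 / D0
                grad -= v
                info += D2 / D0 - np.outer(v, v)
        else:  # breslow
            loglik -= d * np.log(S0)
            v = S1 / S0
            grad -= d * v
            info += d * (S2 / S0 - np.outer(v, v))
    return loglik, grad, info


@dataclass
class CoxFitResult:
    terms: list
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_events: int
    n_episodes: int
    ties: str
    converged: bool
    n_iter: int
    warnings: list = field(default_factory=list)
    inestimable: list = field(default_factory=list)
    level: float = 0.95

    @property
    def hazard_ratio(self) -> np.ndarray:
        return np.exp(self.coef)

    def wald_ci(self, level: float | None = None):
        z = norm.ppf(0.5 + (level or self.level) / 2.0)
        return self.coef - z * self.se, self.coef + z * self.se

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.coef / self.se, np.nan)
        return 2.0 * norm.sf(np.abs(z))

    def summary_frame(self) -> pd.DataFrame:
        lo, hi = self.wald_ci()
        with np.errstate(over="ignore"):
            frame = pd.DataFrame({
                "term": self.terms, "coef": self.coef, "se": self.se,
                "hr": np.exp(self.coef), "hr_lo": np.exp(lo), "hr_hi": np.exp(hi),
                "p": self.p_values,
            })
        if self.inestimable:
            extra = pd.DataFrame({"term": self.inestimable})
            for c in ("coef", "se", "hr", "hr_lo", "hr_hi", "p"):
                extra[c] = np.nan
            frame = pd.concat([frame, extra], ignore_index=True)
        return frame


def fit_cox(episodes: pd.DataFrame, covset: str = "univariable",
            exposure_mode: str = "binary", ties: str = "efron",
            max_iter: int = 50, tol: float = 1e-8,
            design: pd.DataFrame | None = None) -> CoxFitResult:
    """Maximise the cause-specific partial likelihood on counting-process
    episodes.  ``design`` overrides the covariate-set design matrix (used
    for custom column sets); constant (inestimable) columns are dropped
    and flagged rather than fitted."""
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    Z = design if design is not None else build_design(episodes, covset, exposure_mode)
    names = list(Z.columns)
    start = episodes["start"].values.astype(float)
    stop = episodes["stop"].values.astype(float)
    event = episodes["event"].values.astype(int)
    if np.any(start >= stop):
        raise ValueError("episodes must satisfy start < stop")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events of the modelled cause")

    X = Z.values.astype(float)
    variation = X.std(axis=0) > 0
    inestimable = [nm for nm, keep in zip(names, variation) if not keep]
    names = [nm for nm, keep in zip(names, variation) if keep]
    X = X[:, variation]
    p = X.shape[1]
    if p == 0:
        raise ValueError("no estimable covariates in the design")
    # centring leaves the partial likelihood (hence beta) unchanged but
    # greatly improves the conditioning of the risk-set sums
    X = X - X.mean(axis=0)

    beta = np.zeros(p)
    trace = []
    loglik, grad, info = _partial_likelihood(beta, X, start, stop, event, ties)
    converged = False
    it = 0
    warn: list = []
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            warn.append("singular information matrix")
            break
        # step-halving until the likelihood does not decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, g_new, i_new = _partial_likelihood(cand, X, start, stop, event, ties)
            if ll_new >= loglik - 1e-12:
                break
            factor /= 2.0
        delta = np.abs(cand - beta).max()
        beta, loglik, grad, info = cand, ll_new, g_new, i_new
        trace.append({"iter": it, "loglik": loglik,
                      "grad_norm": float(np.abs(grad).max())})
        # the score criterion, with a step-size fallback for when the
        # score sits at the floating-point floor of the risk-set sums
        if np.abs(grad).max() < tol or delta < 1e-12:
            converged = True
            break
    if np.abs(beta).max() > 10:
        # a diverging coefficient with a numerically flat likelihood is
        # the signature of a monotone partial likelihood (separation)
        converged = False
        warn.append("possible monotone partial likelihood: estimate "
                    "diverging (|coef| > 10); flagged, not trusted")
    elif not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations", trace)

    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return CoxFitResult(terms=names, coef=beta, se=se, loglik=float(loglik),
                        n_events=n_events, n_episodes=len(episodes), ties=ties,
                        converged=converged, n_iter=it, warnings=warn,
                        inestimable=inestimable)


def null_loglik(episodes: pd.DataFrame, ties: str = "efron") -> float:
    """Log partial likelihood at beta = 0 (no covariates requested)."""
    start = episodes["start"].values.astype(float)
    stop = episodes["stop"].values.astype(float)
    event = episodes["event"].values.astype(int)
    X = np.zeros((len(episodes), 1))
    ll, _, _ = _partial_likelihood(np.zeros(1), X, start, stop, event, ties)
    return float(ll)


def run_csh_suite(cohort: Cohort, covsets=COVARIATE_SETS,
                  causes=("cardiac", "death_other"),
                  exposure_modes=("binary",), ties: str = "efron") -> pd.DataFrame:
    """One Cox fit per (cause x covariate set x exposure mode); failed
    cells are reported with the error and the suite continues."""
    rows = []
    for cause in causes:
        for mode in exposure_modes:
            eps = episodes_from_cohort(cohort, cause, mode)
            for covset in covsets:
                try:
                    fit = fit_cox(eps, covset, mode, ties=ties)
                except (ValueError, ConvergenceError, np.linalg.LinAlgError) as err:
                    log.warning("cox cause=%s covset=%s mode=%s failed: %s",
                                cause, covset, mode, err)
                    rows.append({"cause": cause, "covset": covset,
                                 "exposure_mode": mode, "term": None,
                                 "error": str(err)})
                    continue
                summ = fit.summary_frame()
                exp_terms = summ[summ["term"].str.startswith("smn")]
                for _, r in exp_terms.iterrows():
                    rows.append({
                        "cause": cause, "covset": covset, "exposure_mode": mode,
                        "term": r["term"], "coef": r["coef"], "se": r["se"],
                        "hr": r["hr"], "hr_lo": r["hr_lo"], "hr_hi": r["hr_hi"],
                        "p": r["p"], "n_events": fit.n_events,
                        "error": "; ".join(fit.warnings) if fit.warnings else "",
                    })
    return pd.DataFrame(rows)
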