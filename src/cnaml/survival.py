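"""Endpoint construction and self-contained survival estimation.

Endpoints (times in months):

* OS — diagnosis to death or last follow-up;
* LFS — CR1 to relapse, death or last follow-up (only for patients who
  reached CR1);
* EFS — diagnosis to induction failure, relapse or death.  Induction
  failure for patients who never reach CR1 is an event placed at a
  configurable assessment time (default 2 months), an interpretation the
  source analyses leave open.

Either endpoint can be censored at HSCT (event replaced by censoring at
the transplant date) for transplant-free views of the curves.

Estimators are implemented directly so that every number is checkable
against a hand computation: product-limit Kaplan–Meier with Greenwood
variance, the k-group log-rank test with hypergeometric variance, and a
Cox proportional-hazards model (Breslow ties) fitted by Newton–Raphson,
exposed statsmodels-style as ``CoxPH(...).fit() -> CoxPHResults``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schema import Cohort, PatientRecord

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "derive_endpoints",
    "cohort_endpoints",
    "km_estimate",
    "logrank_test",
    "CoxPH",
    "CoxPHResults",
]

DEFAULT_ASSESSMENT_MONTHS = 2.0


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    endpoint: str  # LFS | EFS | OS
    time: float
    event: bool
    censored_at_hsct: bool = False


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: S(0)=1, non-increasing, with Greenwood
    variance accumulated at each event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    variance: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float, alpha: float = 0.05) -> tuple[float, float]:
        """Plain (linear) pointwise confidence interval from the Greenwood SE."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        s = float(self.survival[idx])
        se = float(np.sqrt(self.variance[idx]))
        z = stats.norm.ppf(1 - alpha / 2)
        return (max(0.0, s - z * se), min(1.0, s + z * se))


def _maybe_censor_at_hsct(time: float, event: bool, origin: float,
                          hsct_time: Optional[float]) -> tuple[float, bool, bool]:
    if hsct_time is None:
        return time, event, False
    hsct_rel = hsct_time - origin
    if hsct_rel < time or (hsct_rel == time and event):
        return max(hsct_rel, 0.0), False, True
    return time, event, False


def derive_endpoints(
    patient: PatientRecord,
    censor_at_hsct: bool = False,
    assessment_months: float = DEFAULT_ASSESSMENT_MONTHS,
) -> list[SurvivalRecord]:
    """LFS/EFS/OS records for one patient (LFS omitted without CR1)."""
    h = patient.history
    records = []

    # OS: diagnosis -> death or censoring
    os_time = h.death_time if h.death_time is not None else h.last_followup
    os_event = h.death_time is not None
    t, e, c = (os_time, os_event, False)
    if censor_at_hsct:
        t, e, c = _maybe_censor_at_hsct(os_time, os_event, 0.0, h.hsct_time)
    records.append(SurvivalRecord(patient.patient_id, "OS", t, e, c))

    # LFS: CR1 -> relapse/death or censoring
    if h.cr1_time is not None:
        candidates = [x for x in (h.relapse_time, h.death_time) if x is not None]
        end = min(candidates) if candidates else h.last_followup
        event = bool(candidates)
        time = end - h.cr1_time
        t, e, c = (time, event, False)
        if censor_at_hsct:
            t, e, c = _maybe_censor_at_hsct(time, event, h.cr1_time, h.hsct_time)
        records.append(SurvivalRecord(patient.patient_id, "LFS", t, e, c))

    # EFS: diagnosis -> induction failure / relapse / death
    if h.cr1_time is None:
        efs_time = min(assessment_months, h.last_followup)
        if h.death_time is not None:
            efs_time = min(efs_time, h.death_time)
        efs_event = True
    else:
        candidates = [x for x in (h.relapse_time, h.death_time) if x is not None]
        efs_time = min(candidates) if candidates else h.last_followup
        efs_event = bool(candidates)
    t, e, c = (efs_time, efs_event, False)
    if censor_at_hsct:
        t, e, c = _maybe_censor_at_hsct(efs_time, efs_event, 0.0, h.hsct_time)
    records.append(SurvivalRecord(patient.patient_id, "EFS", t, e, c))
    return records


def cohort_endpoints(
    cohort: Cohort,
    endpoint: str,
    censor_at_hsct: bool = False,
    assessment_months: float = DEFAULT_ASSESSMENT_MONTHS,
) -> list[SurvivalRecord]:
    endpoint = endpoint.upper()
    if endpoint not in {"LFS", "EFS", "OS"}:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    out = []
    for p in cohort:
        for rec in derive_endpoints(p, censor_at_hsct, assessment_months):
            if rec.endpoint == endpoint:
                out.append(rec)
    return out


def _times_events(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray([r.time for r in records], dtype=float)
    e = np.asarray([r.event for r in records], dtype=bool)
    return t, e


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan–Meier product-limit estimate with Greenwood variance.

    At tied times, events precede censorings (the censored subjects are
    still in the risk set at that time).
    """
    if not records:
        raise ValueError("km_estimate requires at least one record")
    times, events = _times_events(records)
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    n = len(times)

    uniq = np.unique(times[events])
    surv, var_acc = [], []
    s, acc = 1.0, 0.0
    at_risk, n_ev = [], []
    for t in uniq:
        r = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= (r - d) / r
        if r - d > 0:
            acc += d / (r * (r - d))
        at_risk.append(r)
        n_ev.append(d)
        surv.append(s)
        var_acc.append(s * s * acc if r - d > 0 else 0.0)
    return KMCurve(
        event_times=uniq,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_ev),
        variance=np.asarray(var_acc),
    )


def logrank_test(groups: Sequence[Sequence[SurvivalRecord]]) -> tuple[float, int, float]:
    """k-group log-rank test.

    Returns (chi-square statistic, df = k-1, p-value).  Observed-minus-
    expected vectors use the hypergeometric variance/covariance at every
    distinct event time.
    """
    k = len(groups)
    if k < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("logrank_test needs >= 2 non-empty groups")
    times = [np.asarray([r.time for r in g], float) for g in groups]
    events = [np.asarray([r.event for r in g], bool) for g in groups]
    all_event_times = np.unique(np.concatenate([t[e] for t, e in zip(times, events)]))

    O_minus_E = np.zeros(k - 1)
    V = np.zeros((k - 1, k - 1))
    for t in all_event_times:
        n_g = np.array([np.sum(tt >= t) for tt in times], float)
        d_g = np.array([np.sum((tt == t) & ee) for tt, ee in zip(times, events)], float)
        N, D = n_g.sum(), d_g.sum()
        if N <= 1 or D == 0:
            continue
        expected = D * n_g / N
        O_minus_E += (d_g - expected)[: k - 1]
        factor = D * (N - D) / (N - 1)
        p = n_g / N
        cov = factor * (np.diag(p[: k - 1]) - np.outer(p[: k - 1], p[: k - 1]))
        V += cov
    if np.allclose(V, 0):
        return 0.0, k - 1, 1.0
    chi2 = float(O_minus_E @ np.linalg.solve(V, O_minus_E))
    df = k - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)


class ConvergenceWarningFlag:
    pass


@dataclass
class CoxPHResults:
    """Fitted Cox model: coefficients, Wald inference and diagnostics."""

    params: pd.Series
    bse: pd.Series
    llf: float
    llf_null: float
    n_iter: int
    score_norm: float
    converged: bool
    separation_flag: bool
    n: int
    n_events: int

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params).rename("HR")

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({
            "lower": self.params - z * self.bse,
            "upper": self.params + z * self.bse,
        })

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index, name="p")

    @property
    def lr_pvalue(self) -> float:
        """Global likelihood-ratio test against the null model."""
        lr = 2 * (self.llf - self.llf_null)
        return float(stats.chi2.sf(max(lr, 0.0), len(self.params)))

    def summary(self) -> str:
        ci = self.conf_int()
        hr_ci = np.exp(ci)
        lines = [
            "Cox proportional hazards (Breslow ties)",
            f"n = {self.n}, events = {self.n_events}, "
            f"log-partial-likelihood = {self.llf:.4f} "
            f"(null {self.llf_null:.4f}, LR p = {self.lr_pvalue:.4g})",
            f"converged: {self.converged} in {self.n_iter} iterations "
            f"(score norm {self.score_norm:.2e})"
            + ("  [monotone-likelihood flag]" if self.separation_flag else ""),
            "",
            f"{'covariate':<18}{'coef':>10}{'HR':>10}{'HR 95% CI':>22}{'p':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<18}{self.params[name]:>10.4f}{np.exp(self.params[name]):>10.4f}"
                f"{'[' + format(hr_ci.loc[name, 'lower'], '.3f') + ', ' + format(hr_ci.loc[name, 'upper'], '.3f') + ']':>22}"
                f"{self.pvalues[name]:>10.4g}"
            )
        return "\n".join(lines)


class CoxPH:
    """Cox proportional-hazards model on right-censored data.

    Parameters
    ----------
    time, event : array-like
        Follow-up times and event indicators.
    exog : DataFrame or 2-D array
        Covariate matrix; no column may be constant.
    """

    def __init__(self, time, event, exog):
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=bool)
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            self.exog = exog.to_numpy(dtype=float)
        else:
            self.exog = np.asarray(exog, dtype=float)
            if self.exog.ndim == 1:
                self.exog = self.exog[:, None]
            self.exog_names = [f"x{i}" for i in range(self.exog.shape[1])]
        if len(self.time) != len(self.event) or len(self.time) != self.exog.shape[0]:
            raise ValueError("time, event and exog must have matching lengths")
        if np.any(self.time < 0):
            raise ValueError("negative follow-up time")
        for j, name in enumerate(self.exog_names):
            if np.ptp(self.exog[:, j]) == 0:
                raise ValueError(f"covariate {name!r} is constant")
        if int(self.event.sum()) < self.exog.shape[1]:
            raise ValueError("fewer events than covariates")

    @classmethod
    def from_records(cls, records: Sequence[SurvivalRecord], exog: pd.DataFrame) -> "CoxPH":
        t = [r.time for r in records]
        e = [r.event for r in records]
        return cls(t, e, exog)

    def loglike(self, beta) -> float:
        """Breslow log-partial-likelihood at ``beta``."""
        beta = np.asarray(beta, dtype=float)
        eta = self.exog @ beta
        ll = 0.0
        for t in np.unique(self.time[self.event]):
            at_risk = self.time >= t
            d_mask = (self.time == t) & self.event
            d = int(d_mask.sum())
            ll += float(eta[d_mask].sum()) - d * float(
                np.log(np.sum(np.exp(eta[at_risk])))
            )
        return ll

    def _score_hessian(self, beta):
        eta = self.exog @ beta
        w = np.exp(eta)
        score = np.zeros_like(beta)
        hess = np.zeros((len(beta), len(beta)))
        for t in np.unique(self.time[self.event]):
            at_risk = self.time >= t
            d_mask = (self.time == t) & self.event
            d = int(d_mask.sum())
            wr = w[at_risk]
            xr = self.exog[at_risk]
            s0 = wr.sum()
            s1 = wr @ xr
            s2 = xr.T @ (wr[:, None] * xr)
            xbar = s1 / s0
            score += self.exog[d_mask].sum(axis=0) - d * xbar
            hess -= d * (s2 / s0 - np.outer(xbar, xbar))
        return score, hess

    def fit(self, tol: float = 1e-8, maxiter: int = 50) -> CoxPHResults:
        """Newton–Raphson with step-halving; converges when the score's
        max absolute component drops below ``tol``.  Monotone likelihood
        (perfect separation) is flagged, not silently diverged."""
        p = self.exog.shape[1]
        beta = np.zeros(p)
        ll = self.loglike(beta)
        ll_null = ll
        separation = False
        n_iter = 0
        score = np.zeros(p)
        for n_iter in range(1, maxiter + 1):
            score, hess = self._score_hessian(beta)
            if np.max(np.abs(score)) < tol:
                break
            try:
                step = np.linalg.solve(-hess, score)
            except np.linalg.LinAlgError:
                separation = True
                break
            # step-halving keeps the partial likelihood non-decreasing
            alpha = 1.0
            for _ in range(30):
                cand = beta + alpha * step
                ll_cand = self.loglike(cand)
                if ll_cand >= ll - 1e-12:
                    beta, ll = cand, ll_cand
                    break
                alpha /= 2
            if np.max(np.abs(beta)) > 50:
                separation = True
                break
        score, hess = self._score_hessian(beta)
        if np.max(np.abs(beta)) > 10:
            # log-HR beyond exp(10): monotone likelihood in practice
            separation = True
        converged = bool(np.max(np.abs(score)) < max(tol, 1e-6)) and not separation
        try:
            cov = np.linalg.inv(-hess)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            bse = np.full(p, np.nan)
            separation = True
        return CoxPHResults(
            params=pd.Series(beta, index=self.exog_names, name="coef"),
            bse=pd.Series(bse, index=self.exog_names, name="se"),
            llf=ll,
            llf_null=ll_null,
            n_iter=n_iter,
            score_norm=float(np.max(np.abs(score))),
            converged=converged,
            separation_flag=separation,
            n=len(self.time),
            n_events=int(self.event.sum()),
        )
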