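"""Survival statistics for GARD analyses.

Kaplan-Meier estimation, the standardized two-sample log-rank statistic,
Cox proportional-hazards regression (Efron ties, via lifelines), Weibull
fitting of right-censored data (censored MLE or least-squares against the
KM steps), and the IPCW (inverse-probability-of-censoring-weighted)
cumulative/dynamic time-dependent AUC.

All functions take plain arrays of follow-up times (months) and event
indicators (1 = death observed, 0 = censored).  Follow-up in the target
application is administratively censored at 60 months upstream, by the
cohort generator or data preparation — no implicit truncation happens here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter, WeibullFitter
from lifelines.exceptions import ConvergenceError
from scipy import optimize, stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxResult",
    "WeibullModel",
    "km_estimate",
    "logrank_statistic",
    "fit_cox",
    "fit_weibull",
    "weibull_from_survival_points",
    "censoring_km",
    "td_auc_ipcw",
    "survival_at",
]


def _validate(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if t.size == 0:
        raise ValueError("need at least one record")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("times must be finite and >= 0")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicators must be 0/1")
    return t, e


@dataclass
class KMCurve:
    """Product-limit survival estimate with Greenwood confidence bounds."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n: int
    n_events: int

    def survival_at(self, t: float, warn_extrapolation: bool = True) -> float:
        """Step-function value of S at time ``t`` (S(0) = 1)."""
        if t < 0:
            raise ValueError("t must be >= 0")
        if self.times.size and t > self.times[-1]:
            if warn_extrapolation:
                warnings.warn(
                    f"t={t} beyond last observed time {self.times[-1]}; "
                    "returning last KM value (extrapolation)",
                    RuntimeWarning,
                    stacklevel=2,
                )
            return float(self.survival[-1])
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        return float(self.ci_lower[idx]), float(self.ci_upper[idx])


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate (delegates to lifelines)."""
    t, e = _validate(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_.iloc[:, 0]
    ci = kmf.confidence_interval_survival_function_
    times = sf.index.to_numpy(dtype=float)
    # lifelines includes t=0 row; keep post-0 steps, S(0)=1 handled by survival_at
    keep = times > 0
    ev = kmf.event_table
    at_risk = ev["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return KMCurve(
        times=times[keep],
        survival=sf.to_numpy(dtype=float)[keep],
        at_risk=at_risk[keep],
        ci_lower=ci.iloc[:, 0].to_numpy(dtype=float)[keep],
        ci_upper=ci.iloc[:, 1].to_numpy(dtype=float)[keep],
        n=int(t.size),
        n_events=int(e.sum()),
    )


@dataclass
class LogRankResult:
    z: float  # standardized (O - E)/sqrt(V), group A as reference
    chi2: float
    p: float
    observed_a: float
    expected_a: float
    variance: float


def logrank_statistic(time_a, event_a, time_b, event_b) -> LogRankResult:
    """Standardized two-sample log-rank statistic (O_A - E_A)/sqrt(V).

    The squared statistic is chi-square with 1 df.  Zero variance (no
    events, or one group exhausted before any event) is flagged with an
    explicit error rather than propagating NaN.
    """
    ta, ea = _validate(time_a, event_a)
    tb, eb = _validate(time_b, event_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones_like(ta, bool), np.zeros_like(tb, bool)])
    event_times = np.unique(t[e == 1])
    O = E = V = 0.0
    for u in event_times:
        at_risk = t >= u
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = int(((t == u) & (e == 1)).sum())
        d_a = int(((t == u) & (e == 1) & in_a).sum())
        O += d_a
        E += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if V <= 0:
        raise ValueError("log-rank variance is zero (no comparable events); statistic undefined")
    z = (O - E) / math.sqrt(V)
    chi2 = z * z
    return LogRankResult(
        z=float(z), chi2=float(chi2), p=float(stats.chi2.sf(chi2, df=1)),
        observed_a=float(O), expected_a=float(E), variance=float(V),
    )


@dataclass
class CoxResult:
    """Cox PH fit: per-covariate coefficients with Wald inference."""

    coefficients: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_values: pd.Series
    log_likelihood: float
    n: int
    n_events: int
    ties: str

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.coefficients.index].to_numpy(dtype=float)
        return X @ self.coefficients.to_numpy()

    def to_dict(self) -> dict:
        return {
            "coef": self.coefficients.to_dict(),
            "hr": self.hazard_ratios.to_dict(),
            "ci_lower": self.ci_lower.to_dict(),
            "ci_upper": self.ci_upper.to_dict(),
            "p": self.p_values.to_dict(),
            "log_likelihood": self.log_likelihood,
            "n": self.n,
            "events": self.n_events,
            "method": f"cox-{self.ties}",
        }


def fit_cox(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time_months",
    event_col: str = "event",
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards regression (lifelines, Efron tie handling)."""
    if ties != "efron":
        raise NotImplementedError("only Efron tie handling is supported")
    cols = [duration_col, event_col, *covariates]
    df = cohort[cols].astype(float)
    if df[event_col].sum() < 1:
        raise ValueError("Cox fit requires at least one event")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(f"Cox fit failed to converge: {err}") from err
    summ = cph.summary
    return CoxResult(
        coefficients=summ["coef"],
        hazard_ratios=summ["exp(coef)"],
        ci_lower=np.exp(summ["coef lower 95%"]),
        ci_upper=np.exp(summ["coef upper 95%"]),
        p_values=summ["p"],
        log_likelihood=float(cph.log_likelihood_),
        n=int(df.shape[0]),
        n_events=int(df[event_col].sum()),
        ties=ties,
    )


@dataclass
class WeibullModel:
    """Weibull survival model S(t) = exp(-(t/scale)^shape).

    A group with zero observed events cannot identify a proper Weibull;
    it is represented as a degenerate plateau S(t) = 1 on the observed
    horizon with ``degenerate=True`` (an optional pseudo-event fallback is
    available in :func:`fit_weibull`).
    """

    shape: float
    scale: float
    n: int = 0
    n_events: int = 0
    method: str = "mle"
    degenerate: bool = False
    horizon: float = field(default=math.inf)

    def __post_init__(self) -> None:
        if not self.degenerate and not (self.shape > 0 and self.scale > 0):
            raise ValueError(f"shape and scale must be > 0 (got {self.shape}, {self.scale})")

    def survival(self, t):
        t = np.asarray(t, dtype=float)
        if self.degenerate:
            out = np.ones_like(t)
        else:
            out = np.exp(-np.power(t / self.scale, self.shape))
        return out if out.ndim else float(out)

    def survival_at(self, t: float) -> float:
        if t < 0:
            raise ValueError("t must be >= 0")
        if self.degenerate and t > self.horizon:
            warnings.warn("degenerate plateau model queried beyond horizon", RuntimeWarning)
        return float(self.survival(t))

    @property
    def median(self) -> float:
        if self.degenerate:
            return math.inf
        return self.scale * math.log(2) ** (1.0 / self.shape)

    def sample_event_times(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.degenerate:
            return np.full(n, np.inf)
        return self.scale * rng.weibull(self.shape, size=n)


def fit_weibull(
    time,
    event,
    method: Literal["mle", "km-curve-fit"] = "mle",
    pseudo_event_fallback: bool = False,
) -> WeibullModel:
    """Fit a Weibull survival model to right-censored data.

    ``"mle"`` maximizes the right-censored Weibull likelihood (lifelines);
    ``"km-curve-fit"`` least-squares matches S(t) to the Kaplan-Meier step
    values at the observed event times.  With zero events the model is a
    flagged degenerate plateau, unless ``pseudo_event_fallback`` converts
    the last follow-up into a single event.
    """
    t, e = _validate(time, event)
    if e.sum() == 0:
        if pseudo_event_fallback:
            e = e.copy()
            e[np.argmax(t)] = 1
        else:
            return WeibullModel(
                shape=math.nan, scale=math.nan, n=t.size, n_events=0,
                method=method, degenerate=True, horizon=float(t.max()),
            )
    if method == "mle":
        wf = WeibullFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wf.fit(np.clip(t, 1e-9, None), e)
        return WeibullModel(
            shape=float(wf.rho_), scale=float(wf.lambda_),
            n=int(t.size), n_events=int(e.sum()), method="mle",
        )
    if method == "km-curve-fit":
        km = km_estimate(t, e)
        mask = km.survival > 0
        tt, ss = km.times[mask], km.survival[mask]
        if tt.size < 2:
            raise ValueError("km-curve-fit needs >= 2 KM steps with S > 0")

        def resid(params):
            k, lam = np.exp(params)
            return np.exp(-np.power(tt / lam, k)) - ss

        start = np.log([1.0, max(np.median(tt), 1e-6) / math.log(2)])
        sol = optimize.least_squares(resid, start)
        k, lam = np.exp(sol.x)
        return WeibullModel(
            shape=float(k), scale=float(lam),
            n=int(t.size), n_events=int(e.sum()), method="km-curve-fit",
        )
    raise ValueError(f"unknown method {method!r}")


def weibull_from_survival_points(t1: float, s1: float, t2: float, s2: float) -> WeibullModel:
    """Exact two-point Weibull: the unique (shape, scale) with S(t1)=s1, S(t2)=s2."""
    if not (0 < s2 < s1 < 1 and 0 < t1 < t2):
        raise ValueError("need 0 < t1 < t2 and 0 < s2 < s1 < 1")
    h1, h2 = -math.log(s1), -math.log(s2)
    k = math.log(h2 / h1) / math.log(t2 / t1)
    lam = t1 / h1 ** (1.0 / k)
    return WeibullModel(shape=k, scale=lam, method="two-point")


def censoring_km(time, event) -> KMCurve:
    """KM estimate of the censoring survival G(t) (event indicator flipped)."""
    t, e = _validate(time, event)
    return km_estimate(t, 1 - e)


def td_auc_ipcw(
    cohort: pd.DataFrame,
    marker: str,
    horizon: float,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> float:
    """IPCW cumulative-case / dynamic-control time-dependent AUC at ``horizon``.

    Cases are subjects with an observed event by the horizon, weighted
    1/G(T_i-); controls are subjects still at risk past the horizon,
    weighted 1/G(horizon), with G the Kaplan-Meier censoring survival.
    Marker ties between a case and control count 0.5.  Higher marker must
    indicate higher event risk for AUC > 0.5 (pass a negated marker
    otherwise).
    """
    t, e = _validate(cohort[duration_col], cohort[event_col])
    m = np.asarray(cohort[marker], dtype=float)
    if horizon <= 0 or horizon > t.max():
        raise ValueError(f"horizon must lie within follow-up (0, {t.max()}]")
    case = (t <= horizon) & (e == 1)
    ctrl = t > horizon
    if case.sum() < 1 or ctrl.sum() < 1:
        raise ValueError("need >= 1 case and >= 1 control at the horizon")
    G = censoring_km(t, e)
    g_horizon = G.survival_at(horizon, warn_extrapolation=False)
    # left-limit G(T-): evaluate just before each case's event time
    g_case = np.array(
        [G.survival_at(np.nextafter(ti, -np.inf), warn_extrapolation=False) for ti in t[case]]
    )
    if g_horizon <= 0 or np.any(g_case <= 0):
        raise ValueError(
            "censoring survival reaches 0 before the horizon; reduce the horizon"
        )
    w_case = 1.0 / g_case
    w_ctrl = np.full(int(ctrl.sum()), 1.0 / g_horizon)
    mc, mk = m[case], m[ctrl]
    gt = (mc[:, None] > mk[None, :]).astype(float)
    eq = (mc[:, None] == mk[None, :]).astype(float)
    weights = np.outer(w_case, w_ctrl)
    num = float((weights * (gt + 0.5 * eq)).sum())
    den = float(weights.sum())
    return num / den


def survival_at(curve_or_model, t: float):
    """Survival probability at time ``t`` from a KM curve or Weibull model.

    For a :class:`KMCurve` returns ``(estimate, (ci_lower, ci_upper))``;
    for a :class:`WeibullModel`, the closed-form value.
    """
    if isinstance(curve_or_model, KMCurve):
        return curve_or_model.survival_at(t), curve_or_model.ci_at(t)
    if isinstance(curve_or_model, WeibullModel):
        return curve_or_model.survival_at(t)
    raise TypeError(f"unsupported object {type(curve_or_model)!r}")
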