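"""Failure-at-horizon estimators: simple proportion, 1−Kaplan-Meier, and the
non-parametric cumulative incidence function (CIF).

All three return a :class:`FailureEstimate` — the point estimate of the
probability of device failure by the benchmarking horizon τ together with a
two-sided confidence interval:

* ``estimate_proportion`` — observed failures over subjects not removed by the
  competing event, with a Wald interval (the one-sample z-test estimator).
* ``estimate_km_failure`` — ``1 − Ŝ(τ)`` from the Kaplan-Meier product-limit
  survivor, deaths treated as random right-censoring (net failure); CI from
  the Greenwood variance on the log(−log) scale, so bounds stay in [0, 1].
* ``estimate_cif`` — the Aalen-Johansen cause-specific cumulative incidence
  (crude failure); delta-method variance, again transformed on the log(−log)
  scale.

Degenerate cohorts with zero failures return point 0 with CI [0, 0] and the
``degenerate`` flag set, so that downstream performance summaries can count
them explicitly.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import Cohort, EventType

__all__ = [
    "Method",
    "FailureEstimate",
    "RiskTable",
    "build_risk_table",
    "estimate_proportion",
    "estimate_km_failure",
    "estimate_cif",
    "AllSubjectsDeadError",
]


class Method(str, enum.Enum):
    PROPORTION = "PROPORTION"
    KM = "KM"
    CIF = "CIF"


class AllSubjectsDeadError(ValueError):
    """The failure proportion is undefined: every subject died before τ."""


@dataclass(frozen=True)
class FailureEstimate:
    """Point estimate of failure by ``horizon`` with a two-sided CI."""

    method: Method
    horizon: float
    point: float
    ci_lower: float
    ci_upper: float
    alpha_two_sided: float = 0.05
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_lower <= self.point + 1e-12
                and self.point <= self.ci_upper + 1e-12 and self.ci_upper <= 1.0):
            raise ValueError(
                f"invalid interval: lower={self.ci_lower} point={self.point} upper={self.ci_upper}"
            )

    @property
    def ci_width(self) -> float:
        return self.ci_upper - self.ci_lower

    def to_dict(self) -> dict:
        return {
            "method": self.method.value,
            "horizon": self.horizon,
            "point": self.point,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "alpha_two_sided": self.alpha_two_sided,
            "degenerate": self.degenerate,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class RiskTable:
    """Event/censoring counts at the distinct observed times of a cohort.

    At each distinct time ``t_j``: ``n_risk`` subjects are still at risk just
    before ``t_j`` (subjects censored at ``t_j`` are counted at risk there),
    ``n_failure``/``n_death``/``n_censor`` leave the risk set at ``t_j``.
    """

    time: np.ndarray
    n_risk: np.ndarray
    n_failure: np.ndarray
    n_death: np.ndarray
    n_censor: np.ndarray

    @property
    def n_total(self) -> int:
        return int(self.n_risk[0]) if self.time.size else 0


def build_risk_table(cohort: Cohort) -> RiskTable:
    """Tabulate at-risk and event counts at every distinct observed time."""
    if len(cohort) == 0:
        raise ValueError("cannot build a risk table from an empty cohort")
    if not (cohort.time > 0).all():
        raise ValueError("cohort contains non-positive times")
    order = np.argsort(cohort.time, kind="stable")
    t_sorted = cohort.time[order]
    e_sorted = cohort.event[order]
    times, first_idx = np.unique(t_sorted, return_index=True)
    n = len(cohort)
    n_risk = n - first_idx  # number with observed time >= t_j
    # per-time event counts via bincount on the group index of each subject
    group = np.searchsorted(times, t_sorted)
    k = times.size
    n_failure = np.bincount(group[e_sorted == EventType.FAILURE], minlength=k)
    n_death = np.bincount(group[e_sorted == EventType.DEATH], minlength=k)
    n_censor = np.bincount(group[e_sorted == EventType.ADMIN_CENSORED], minlength=k)
    return RiskTable(
        time=times,
        n_risk=n_risk.astype(np.int64),
        n_failure=n_failure.astype(np.int64),
        n_death=n_death.astype(np.int64),
        n_censor=n_censor.astype(np.int64),
    )


def _z(alpha_two_sided: float) -> float:
    return float(stats.norm.ppf(1.0 - alpha_two_sided / 2.0))


def estimate_proportion(cohort: Cohort, alpha_two_sided: float = 0.05) -> FailureEstimate:
    """Simple failure proportion with a Wald interval (z-test estimator).

    Subjects whose follow-up ended in death are excluded from the denominator;
    the numerator is the observed failure count.  With no competing deaths this
    is failures over the full cohort size.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    n_fail = int((cohort.event == EventType.FAILURE).sum())
    denom = int((cohort.event != EventType.DEATH).sum())
    if denom == 0:
        raise AllSubjectsDeadError("all subjects died before the horizon; proportion undefined")
    p = n_fail / denom
    se = np.sqrt(p * (1.0 - p) / denom)
    z = _z(alpha_two_sided)
    return FailureEstimate(
        method=Method.PROPORTION,
        horizon=cohort.horizon,
        point=p,
        ci_lower=max(p - z * se, 0.0),
        ci_upper=min(p + z * se, 1.0),
        alpha_two_sided=alpha_two_sided,
        degenerate=(n_fail == 0),
    )


def _degenerate(method: Method, horizon: float, alpha: float) -> FailureEstimate:
    return FailureEstimate(
        method=method, horizon=horizon, point=0.0, ci_lower=0.0, ci_upper=0.0,
        alpha_two_sided=alpha, degenerate=True,
    )


def estimate_km_failure(cohort: Cohort, alpha_two_sided: float = 0.05) -> FailureEstimate:
    """Failure by τ as ``1 − Ŝ(τ)`` from the Kaplan-Meier survivor.

    Deaths are treated as non-informative right-censoring, so the estimand is
    *net* failure — the failure probability in a hypothetical cohort where
    death cannot pre-empt it.  The CI applies the normal approximation to
    ``log(−log Ŝ(τ))`` with Greenwood variance and back-transforms, which keeps
    both bounds inside [0, 1].
    """
    table = build_risk_table(cohort)
    tau = cohort.horizon
    sel = table.time <= tau
    n_risk = table.n_risk[sel].astype(float)
    events = table.n_failure[sel].astype(float)
    has = events > 0
    n_risk, events = n_risk[has], events[has]
    if events.size == 0:
        return _degenerate(Method.KM, tau, alpha_two_sided)
    surv = float(np.prod((n_risk - events) / n_risk))
    if surv <= 0.0:
        # every remaining subject failed: point mass at 1
        return FailureEstimate(
            method=Method.KM, horizon=tau, point=1.0, ci_lower=1.0, ci_upper=1.0,
            alpha_two_sided=alpha_two_sided,
        )
    # Greenwood variance of log S
    with np.errstate(divide="ignore"):
        var_log_s = float(np.sum(events / (n_risk * (n_risk - events))))
    se_cloglog = np.sqrt(var_log_s) / abs(np.log(surv))
    z = _z(alpha_two_sided)
    s_lower = surv ** np.exp(z * se_cloglog)
    s_upper = surv ** np.exp(-z * se_cloglog)
    return FailureEstimate(
        method=Method.KM,
        horizon=tau,
        point=1.0 - surv,
        ci_lower=1.0 - s_upper,
        ci_upper=1.0 - s_lower,
        alpha_two_sided=alpha_two_sided,
    )


def estimate_cif(
    cohort: Cohort,
    cause: EventType = EventType.FAILURE,
    alpha_two_sided: float = 0.05,
) -> FailureEstimate:
    """Aalen-Johansen cumulative incidence of ``cause`` by τ (crude failure).

    ``CIF_k(τ) = Σ_{t_j ≤ τ} Ŝ(t_{j−1}) · d_kj / n_j`` where ``Ŝ`` is the
    all-cause (failure + death) Kaplan-Meier survivor and ``d_kj`` the cause-k
    events at ``t_j``.  Unlike 1−KM, subjects who die remain in the risk-set
    accounting through ``Ŝ``, so the estimate is the real-world probability of
    failure acknowledging that death can pre-empt it.

    The variance is the Marubini-Valsecchi (Aalen-type) delta-method form; the
    CI is built on the log(−log) scale and back-transformed.
    """
    if cause not in (EventType.FAILURE, EventType.DEATH):
        raise ValueError("cause must be FAILURE or DEATH")
    table = build_risk_table(cohort)
    tau = cohort.horizon
    sel = table.time <= tau
    n_risk = table.n_risk[sel].astype(float)
    d_fail = table.n_failure[sel].astype(float)
    d_death = table.n_death[sel].astype(float)
    d_all = d_fail + d_death
    d_cause = d_fail if cause is EventType.FAILURE else d_death
    has = d_all > 0
    n_risk, d_all, d_cause = n_risk[has], d_all[has], d_cause[has]
    if d_cause.sum() == 0:
        return _degenerate(Method.CIF, tau, alpha_two_sided)
    # all-cause survivor just before each event time
    frac = (n_risk - d_all) / n_risk
    s_prev = np.concatenate([[1.0], np.cumprod(frac)[:-1]])
    increments = s_prev * d_cause / n_risk
    cif_at = np.cumsum(increments)
    cif = float(cif_at[-1])
    # Marubini-Valsecchi variance of the cumulative incidence at tau
    tail = cif - cif_at  # CIF(tau) - CIF(t_j)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(
            n_risk > d_all, tail ** 2 * d_all / (n_risk * (n_risk - d_all)), 0.0
        )
    term2 = s_prev ** 2 * ((n_risk - d_cause) / n_risk) * d_cause / n_risk ** 2
    term3 = -2.0 * tail * s_prev * d_cause / n_risk ** 2
    var = float(np.sum(term1 + term2 + term3))
    var = max(var, 0.0)
    if cif >= 1.0:
        return FailureEstimate(
            method=Method.CIF, horizon=tau, point=1.0, ci_lower=1.0, ci_upper=1.0,
            alpha_two_sided=alpha_two_sided,
        )
    se_cloglog = np.sqrt(var) / abs(cif * np.log(cif))
    z = _z(alpha_two_sided)
    lower = cif ** np.exp(z * se_cloglog)
    upper = cif ** np.exp(-z * se_cloglog)
    return FailureEstimate(
        method=Method.CIF,
        horizon=tau,
        point=cif,
        ci_lower=lower,
        ci_upper=upper,
        alpha_two_sided=alpha_two_sided,
    )
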