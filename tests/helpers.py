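"""Independent brute-force oracles and cohort builders for the test suite.

The oracles recompute Kaplan-Meier and cumulative-incidence points directly
from sorted raw times with plain Python loops — no risk table, no shared code
with the package implementation.
"""

from __future__ import annotations

import numpy as np

from nibench import Cohort, EventType

CENSOR, FAIL, DEATH = (
    int(EventType.ADMIN_CENSORED),
    int(EventType.FAILURE),
    int(EventType.DEATH),
)


def make_cohort(pairs, horizon: float = 10.0) -> Cohort:
    """Build a cohort from (time, event_code) pairs."""
    times = np.array([t for t, _ in pairs], dtype=float)
    events = np.array([e for _, e in pairs], dtype=np.int8)
    return Cohort(time=times, event=events, horizon=horizon)


def km_failure_brute(cohort: Cohort) -> float:
    """1 − KM at the horizon by direct product over raw times (deaths censored)."""
    tau = cohort.horizon
    times = list(cohort.time)
    surv = 1.0
    for t in sorted(set(times)):
        if t > tau:
            continue
        at_risk = sum(1 for x in times if x >= t)
        fails = sum(
            1 for x, e in zip(cohort.time, cohort.event) if x == t and e == FAIL
        )
        if fails:
            surv *= (at_risk - fails) / at_risk
    return 1.0 - surv


def cif_brute(cohort: Cohort, cause: int = FAIL) -> float:
    """Aalen-Johansen cumulative incidence at the horizon by direct summation."""
    tau = cohort.horizon
    times = list(cohort.time)
    surv_all = 1.0
    cif = 0.0
    for t in sorted(set(times)):
        if t > tau:
            continue
        at_risk = sum(1 for x in times if x >= t)
        fails = sum(1 for x, e in zip(cohort.time, cohort.event) if x == t and e == FAIL)
        deaths = sum(1 for x, e in zip(cohort.time, cohort.event) if x == t and e == DEATH)
        d_cause = fails if cause == FAIL else deaths
        cif += surv_all * d_cause / at_risk
        surv_all *= (at_risk - fails - deaths) / at_risk
    return cif


def all_cause_km_brute(cohort: Cohort) -> float:
    """All-cause KM survivor at the horizon (failure + death both events)."""
    tau = cohort.horizon
    times = list(cohort.time)
    surv = 1.0
    for t in sorted(set(times)):
        if t > tau:
            continue
        at_risk = sum(1 for x in times if x >= t)
        ev = sum(1 for x, e in zip(cohort.time, cohort.event) if x == t and e != CENSOR)
        if ev:
            surv *= (at_risk - ev) / at_risk
    return surv


def random_cohort(rng: np.random.Generator, n: int, horizon: float = 10.0,
                  tie_prone: bool = True) -> Cohort:
    """Random small cohort with failures, deaths and scattered censorings.

    Times are optionally rounded to one decimal so that ties (including
    event/censoring ties) actually occur.
    """
    times = rng.uniform(0.05, horizon, size=n)
    if tie_prone:
        times = np.maximum(np.round(times, 1), 0.1)
    events = rng.choice([CENSOR, FAIL, DEATH], size=n, p=[0.3, 0.4, 0.3])
    # administrative censoring style: push some censorings to the horizon
    at_horizon = (events == CENSOR) & (rng.uniform(size=n) < 0.5)
    times[at_horizon] = horizon
    return Cohort(time=times, event=events.astype(np.int8), horizon=horizon)
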