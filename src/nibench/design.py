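"""One-sample non-inferiority decisions and analytic design calculations.

A device is benchmarked against an externally specified maximum acceptable
failure proportion ``p_bm`` (e.g. 5% at 10 years for hip prostheses).  With a
non-inferiority margin δ, the device is declared non-inferior when the upper
bound of the two-sided (1−2α) CI of its failure estimate does not exceed
``p_bm + δ``; δ = 0 recovers the one-sided superiority test.

For the z-test of one proportion the required sample size has the closed form

    n = p(1−p) · ((z_{1−α} + z_{1−β}) / (p − p_bm − δ))²

ceiling-rounded to the smallest integer cohort achieving the requested power.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import FailureEstimate

__all__ = [
    "BenchmarkSpec",
    "Decision",
    "DecisionResult",
    "test_noninferiority",
    "sample_size_ni",
    "sample_size_ni_exact",
    "power_ni_analytic",
    "sample_size_table",
    "InfeasibleDesignError",
    "DEFAULT_MARGINS",
]

DEFAULT_MARGINS = (0.01, 0.02, 0.03, 0.04, 0.05)


class InfeasibleDesignError(ValueError):
    """No finite sample size can achieve the requested design."""


@dataclass(frozen=True)
class BenchmarkSpec:
    """External benchmark against which a device failure estimate is judged."""

    p_bm: float = 0.05
    margins: tuple[float, ...] = DEFAULT_MARGINS
    alpha_one_sided: float = 0.025
    horizon: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_bm < 1.0:
            raise ValueError(f"benchmark proportion must be in (0, 1), got {self.p_bm}")
        margins = tuple(float(m) for m in self.margins)
        if any(m < 0 or m >= 1.0 - self.p_bm for m in margins):
            raise ValueError(f"margins must satisfy 0 <= δ < 1 - p_bm, got {margins}")
        if list(margins) != sorted(margins):
            raise ValueError("margins must be sorted ascending")
        object.__setattr__(self, "margins", margins)
        if not 0.0 < self.alpha_one_sided < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha_one_sided}")

    @property
    def alpha_two_sided(self) -> float:
        return 2.0 * self.alpha_one_sided


class Decision(str, enum.Enum):
    NON_INFERIOR = "NON_INFERIOR"
    NOT_DEMONSTRATED = "NOT_DEMONSTRATED"


@dataclass(frozen=True)
class DecisionResult:
    margin: float
    decision: Decision
    basis: FailureEstimate

    @property
    def non_inferior(self) -> bool:
        return self.decision is Decision.NON_INFERIOR


def test_noninferiority(
    estimate: FailureEstimate, spec: BenchmarkSpec, margin: float
) -> DecisionResult:
    """Declare non-inferiority when ``ci_upper <= p_bm + margin`` (inclusive).

    ``margin = 0`` is the superiority test: the whole CI must lie below the
    benchmark.
    """
    if margin < 0:
        raise ValueError(f"margin must be non-negative, got {margin}")
    ok = estimate.ci_upper <= spec.p_bm + margin
    return DecisionResult(
        margin=margin,
        decision=Decision.NON_INFERIOR if ok else Decision.NOT_DEMONSTRATED,
        basis=estimate,
    )


def sample_size_ni_exact(
    p_f: float, spec: BenchmarkSpec, margin: float, power: float
) -> float:
    """Continuous (un-rounded) solution of the one-proportion design formula."""
    if not 0.0 < p_f < 1.0:
        raise ValueError(f"assumed failure proportion must be in (0, 1), got {p_f}")
    if not 0.0 < power < 1.0:
        raise ValueError(f"power must be in (0, 1), got {power}")
    effect = p_f - spec.p_bm - margin
    if effect == 0.0:
        raise InfeasibleDesignError(
            "assumed failure equals benchmark plus margin; no finite n suffices"
        )
    z_a = stats.norm.ppf(1.0 - spec.alpha_one_sided)
    z_b = stats.norm.ppf(power)
    return float(p_f * (1.0 - p_f) * ((z_a + z_b) / effect) ** 2)


def sample_size_ni(p_f: float, spec: BenchmarkSpec, margin: float, power: float) -> int:
    """Smallest integer cohort size achieving at least the requested power."""
    return int(math.ceil(sample_size_ni_exact(p_f, spec, margin, power)))


def power_ni_analytic(n: int, p_f: float, spec: BenchmarkSpec, margin: float) -> float:
    """Analytic power of the one-proportion non-inferiority z-test at size ``n``.

    ``Φ( |p_f − p_bm − δ| · sqrt(n / (p_f(1−p_f))) − z_{1−α} )``; inverse of
    :func:`sample_size_ni_exact`, so round-tripping through the ceiling-rounded
    sample size always returns at least the requested power.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 < p_f < 1.0:
        raise ValueError(f"assumed failure proportion must be in (0, 1), got {p_f}")
    effect = abs(p_f - spec.p_bm - margin)
    z_a = stats.norm.ppf(1.0 - spec.alpha_one_sided)
    return float(stats.norm.cdf(effect * np.sqrt(n / (p_f * (1.0 - p_f))) - z_a))


def sample_size_table(
    p_f: float,
    spec: BenchmarkSpec,
    powers,
    margins=None,
) -> pd.DataFrame:
    """Design grid: required n for every (margin, power) combination.

    Mirrors the margin-by-power curves a study planner would consult, with
    margins from the benchmark spec by default.
    """
    margins = spec.margins if margins is None else tuple(margins)
    rows = []
    for margin in margins:
        for power in powers:
            rows.append(
                {
                    "p_bm": spec.p_bm,
                    "p_f": p_f,
                    "margin": margin,
                    "alpha_one_sided": spec.alpha_one_sided,
                    "power": power,
                    "n": sample_size_ni(p_f, spec, margin, power),
                }
            )
    return pd.DataFrame(rows, columns=["p_bm", "p_f", "margin", "alpha_one_sided", "power", "n"])
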