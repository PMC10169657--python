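"""Exact binomial power and minimum sample size for screening studies.

The design question: how many reference-positive subjects are needed so
that an exact binomial test can distinguish a screener sensitivity of p1
(e.g. 0.70) from a null of p0 (e.g. 0.50, chance) with a given power?

The test rejects when the observed number of correctly flagged positives
is at least the critical count c, where c is the smallest count whose
upper tail under p0 does not exceed the working alpha (alpha/2 in the
upper tail for a two-sided test, alpha for one-sided). Power is the upper
tail of c under p1. Everything uses exact binomial tail sums — no normal
approximation — so power is a saw-tooth function of n; the minimum sample
size is the smallest n whose power reaches the target, matching standard
guidance tables.

The total sample size follows by dividing the required positives by the
expected prevalence of the condition (ceiling by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from pro55.errors import InvalidInputError


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for a sensitivity-driven sample-size calculation."""

    p0: float = 0.5
    p1: float = 0.7
    alpha: float = 0.05
    power_target: float = 0.8
    sided: str = "two"
    prevalence: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.p0 < self.p1 < 1:
            raise InvalidInputError("need 0 < p0 < p1 < 1")
        if not 0 < self.alpha < 1:
            raise InvalidInputError("alpha must be in (0, 1)")
        if not 0 < self.power_target < 1:
            raise InvalidInputError("power_target must be in (0, 1)")
        if self.sided not in {"one", "two"}:
            raise InvalidInputError("sided must be 'one' or 'two'")
        if not 0 < self.prevalence < 1:
            raise InvalidInputError("prevalence must be in (0, 1)")

    @property
    def tail_alpha(self) -> float:
        return self.alpha / 2 if self.sided == "two" else self.alpha


def critical_count(n: int, spec: PowerSpec) -> int:
    """Smallest rejection count c with P(X >= c | n, p0) <= working alpha.

    Always exists (c = n + 1 rejects never, with tail probability 0).
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    for c in range(n + 2):
        # sf(c-1) = P(X >= c)
        if stats.binom.sf(c - 1, n, spec.p0) <= spec.tail_alpha:
            return c
    raise AssertionError("unreachable: c = n + 1 has tail probability 0")


def exact_binomial_power(n: int, spec: PowerSpec) -> float:
    """Exact power of the binomial test with n reference-positives.

    P(X >= c | n, p1) with c from :func:`critical_count`.
    """
    c = critical_count(n, spec)
    return float(stats.binom.sf(c - 1, n, spec.p1))


def min_positives_for_sensitivity(spec: PowerSpec, n_max: int = 10**6) -> int:
    """Smallest number of reference-positives reaching the target power.

    Scans n upward and returns the first n with
    ``exact_binomial_power(n, spec) >= power_target``. Because exact power
    saw-tooths in n, some larger n may dip below the target again; the
    smallest qualifying n is returned, matching standard guidance tables.
    """
    for n in range(1, n_max + 1):
        if exact_binomial_power(n, spec) >= spec.power_target:
            return n
    raise InvalidInputError(f"no n <= {n_max} reaches power {spec.power_target}")


def total_sample_size(
    n_pos: int, prevalence: float, rounding: str = "ceiling"
) -> int:
    """Total cohort size providing ``n_pos`` expected reference-positives.

    ``rounding`` is ``"ceiling"`` (conservative default) or ``"nearest"``
    (banker's rounding of n_pos / prevalence).
    """
    if not 0 < prevalence < 1:
        raise InvalidInputError("prevalence must be in (0, 1)")
    if n_pos < 1:
        raise InvalidInputError("n_pos must be >= 1")
    raw = n_pos / prevalence
    if rounding == "ceiling":
        return math.ceil(raw)
    if rounding == "nearest":
        return round(raw)
    raise InvalidInputError("rounding must be 'ceiling' or 'nearest'")


def sample_size_report(spec: PowerSpec, rounding: str = "ceiling") -> dict:
    """Bundle the full calculation into one JSON-ready mapping."""
    n_pos = min_positives_for_sensitivity(spec)
    return {
        "n_positives": n_pos,
        "n_total": total_sample_size(n_pos, spec.prevalence, rounding=rounding),
        "achieved_power": exact_binomial_power(n_pos, spec),
        "critical_value": critical_count(n_pos, spec),
        "p0": spec.p0,
        "p1": spec.p1,
        "alpha": spec.alpha,
        "sided": spec.sided,
        "prevalence": spec.prevalence,
        "rounding": rounding,
    }
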