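"""Derivation of model-ready contrasts from published summary statistics.

Trials report relative effects in heterogeneous forms: a hazard ratio with
its 95% CI, responder counts per arm, or percentages. The NMA likelihoods
want a log effect and its standard error. The conversions here are the
standard ones: the SE of a log hazard ratio recovered from the CI width
(ln(hi) - ln(lo)) / (2 * 1.96), and the Woolf log odds ratio from a 2x2
contingency table with a 0.5 continuity correction when any cell is empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ContrastRecord",
    "loghr_from_hr_ci",
    "or_from_counts",
    "counts_from_percent",
]

Z95 = 1.96  # normal quantile used by convention for 95% CIs


@dataclass(frozen=True)
class ContrastRecord:
    """One trial's relative effect for a treatment pair, on the log scale."""

    trial_id: str
    outcome: str
    treatment: str
    baseline_treatment: str
    log_effect: float
    se: float
    effect_scale: str = "log_hr"  # or "log_or"

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"trial {self.trial_id}: se must be > 0, got {self.se}")
        if self.treatment == self.baseline_treatment:
            raise ValueError(f"trial {self.trial_id}: treatment equals baseline")
        if self.effect_scale not in ("log_hr", "log_or"):
            raise ValueError(f"unknown effect_scale {self.effect_scale!r}")


def loghr_from_hr_ci(hr: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Log hazard ratio and SE from a reported HR and its 95% CI.

    se = (ln(ci_high) - ln(ci_low)) / (2 * 1.96). Requires
    0 < ci_low <= hr <= ci_high with a strictly positive CI width.
    """
    if min(hr, ci_low, ci_high) <= 0:
        raise ValueError("HR and CI limits must be positive")
    if not (ci_low <= hr <= ci_high):
        raise ValueError(f"HR {hr} outside its CI [{ci_low}, {ci_high}]")
    if ci_low >= ci_high:
        raise ValueError("CI has zero or negative width")
    log_effect = math.log(hr)
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z95)
    return log_effect, se


def or_from_counts(r1: int, n1: int, r2: int, n2: int) -> tuple[float, float]:
    """Log odds ratio (arm 1 vs arm 2) with Woolf SE from a 2x2 table.

    If any of the four cells (r, n-r per arm) is zero, 0.5 is added to
    all four cells before taking logs (Gart continuity correction).
    """
    for r, n in ((r1, n1), (r2, n2)):
        if n < 1:
            raise ValueError("arm size must be >= 1")
        if not (0 <= r <= n):
            raise ValueError(f"responders {r} outside [0, {n}]")
    a, b = float(r1), float(n1 - r1)
    c, d = float(r2), float(n2 - r2)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return log_or, se


def counts_from_percent(pct: float, n: int) -> int:
    """Event count back-calculated from a reported percentage.

    Rounds to the nearest integer, halves away from zero; clamped to [0, n].
    """
    if not (0.0 <= pct <= 100.0):
        raise ValueError(f"percentage {pct} outside [0, 100]")
    if n < 1:
        raise ValueError("n must be >= 1")
    x = pct * n / 100.0
    count = math.floor(x + 0.5)  # half away from zero; x >= 0 here
    return min(count, n)
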