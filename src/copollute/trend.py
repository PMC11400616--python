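"""Mann-Kendall trend test with tie-corrected variance.

The test statistic ``S`` counts concordant minus discordant pairs in a
temporally ordered sequence; its variance is reduced by tied groups; the
standardized statistic ``Z`` carries a +/-1 continuity correction. Two-tailed
significance is decided against the standard normal quantiles at the 90/95/99%
confidence levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MKResult",
    "mk_s",
    "mk_var",
    "mk_z",
    "mk_test",
    "critical_value",
    "CONFIDENCE_LEVELS",
]

#: Confidence levels used by the significance tiers.
CONFIDENCE_LEVELS = (90, 95, 99)


def critical_value(confidence: float) -> float:
    """Two-sided standard normal critical value for a confidence level in %.

    ``critical_value(95)`` is the quantile at 1 - alpha/2 with alpha = 0.05.
    """
    if not 0 < confidence < 100:
        raise ValueError(f"confidence must be in (0, 100), got {confidence}")
    alpha = 1.0 - confidence / 100.0
    return float(stats.norm.ppf(1.0 - alpha / 2.0))


@dataclass(frozen=True)
class MKResult:
    """Outcome of the Mann-Kendall test on one series."""

    n: int
    s: int
    var_s: float
    z: float
    direction: str  # "increasing" | "decreasing" | "none"
    sig_tier: int  # 0 (none), 90, 95 or 99


def _validate(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("input series must be one-dimensional")
    if x.size < 2:
        raise ValueError(f"need at least 2 observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values present; drop invalid periods before testing")
    return x


def mk_s(x) -> int:
    """Pairwise-sign statistic S = sum_{i<j} sgn(x_j - x_i)."""
    x = _validate(x)
    diff = np.sign(x[None, :] - x[:, None])
    return int(np.triu(diff, k=1).sum())


def mk_var(x) -> float:
    """Tie-corrected variance of S.

    var_S = [n(n-1)(2n+5) - sum_k q_k(q_k-1)(2q_k+5)] / 18 over tied groups of
    size q_k >= 2.
    """
    x = _validate(x)
    n = x.size
    _, counts = np.unique(x, return_counts=True)
    q = counts[counts > 1].astype(float)
    tie_term = float(np.sum(q * (q - 1) * (2 * q + 5)))
    return (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0


def mk_z(s: int, var_s: float, n: int) -> float:
    """Continuity-corrected standardized statistic.

    Z = (S-1)/sqrt(var_S) for S>0, 0 for S=0, (S+1)/sqrt(var_S) for S<0.
    A degenerate series (var_S = 0, all values tied) yields Z = 0.
    """
    if n <= 10:
        logger.warning("normal approximation used with n=%d <= 10", n)
    if var_s < 0:
        raise ValueError(f"var_s must be nonnegative, got {var_s}")
    if s == 0:
        return 0.0
    if var_s == 0:
        logger.warning("var_S = 0 (all values identical); Z defined as 0")
        return 0.0
    correction = -1.0 if s > 0 else 1.0
    return (s + correction) / np.sqrt(var_s)


def _direction(z: float) -> str:
    if z > 0:
        return "increasing"
    if z < 0:
        return "decreasing"
    return "none"


def _sig_tier(z: float) -> int:
    tier = 0
    for conf in CONFIDENCE_LEVELS:
        if abs(z) >= critical_value(conf):
            tier = conf
    return tier


def mk_test(x) -> MKResult:
    """Run the full test on a temporally ordered series."""
    x = _validate(x)
    n = int(x.size)
    s = mk_s(x)
    var_s = mk_var(x)
    z = mk_z(s, var_s, n)
    return MKResult(n=n, s=s, var_s=var_s, z=z, direction=_direction(z), sig_tier=_sig_tier(z))
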