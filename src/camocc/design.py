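"""Survey-design analysis: cumulative detection probability p*.

Given a constant per-occasion detection probability p, the probability of
detecting the species at least once in K occasions is

    p*(p, K) = 1 - (1 - p)^K.

Uncertainty in p propagates to p* by the delta method,
SE(p*) = K (1-p)^(K-1) SE(p), with intervals truncated to [0, 1].  With
occasion-varying detection the miss product generalizes to prod_j (1-p_j).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["PStarCurve", "p_star", "p_star_curve", "required_surveys"]


@dataclass
class PStarCurve:
    """Cumulative detection probability across survey counts 1..K_max."""

    baseline_p: float
    se_p: float
    counts: np.ndarray
    p_star: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": self.counts,
                "p_star": self.p_star,
                "lower": self.lower,
                "upper": self.upper,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def p_star(p, K):
    """Probability of >= 1 detection in K occasions: 1 - (1-p)^K.

    ``p`` may be a scalar (with scalar or array ``K``) or a vector of
    per-occasion probabilities, in which case K is ignored and the miss
    product prod(1 - p_j) is used.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p must lie in [0, 1]")
    if p_arr.ndim >= 1 and p_arr.size > 1:
        return float(1.0 - np.prod(1.0 - p_arr))
    K = np.asarray(K)
    if np.any(K < 1):
        raise ValueError("K must be >= 1")
    out = 1.0 - (1.0 - float(p_arr)) ** K
    return float(out) if out.ndim == 0 else out


def p_star_curve(
    p: float, se: float = 0.0, k_max: int = 15, level: float = 0.95
) -> PStarCurve:
    """p* for K = 1..k_max with delta-method confidence bounds.

    SE(p*) = K (1-p)^(K-1) SE(p); bounds are symmetric and truncated to
    [0, 1], matching the usual error-bar presentation of these curves.
    """
    if se < 0:
        raise ValueError("SE must be non-negative")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    counts = np.arange(1, k_max + 1)
    point = p_star(p, counts)
    se_star = counts * (1.0 - p) ** (counts - 1) * se
    z = norm.ppf(0.5 + level / 2.0)
    lower = np.clip(point - z * se_star, 0.0, 1.0)
    upper = np.clip(point + z * se_star, 0.0, 1.0)
    return PStarCurve(float(p), float(se), counts, point, lower, upper, level)


def required_surveys(p: float, target: float) -> int:
    """Smallest K with 1 - (1-p)^K >= target: ceil(log(1-target)/log(1-p))."""
    if not 0 < target < 1:
        raise ValueError("target must lie in (0, 1)")
    if not 0 < p < 1:
        raise ValueError(
            "p must lie strictly in (0, 1); the target is unreachable at p = 0"
        )
    k = int(np.ceil(np.log1p(-target) / np.log1p(-p)))
    return max(k, 1)
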