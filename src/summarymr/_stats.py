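"""Small shared statistical helpers.

Conventions used throughout the package: two-sided p-values from the normal
approximation z = beta/se, the 97.5% normal quantile carried at 1.959964,
and p-values floored at 1e-300 so extreme z-scores never underflow to zero.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: Normal quantile used for all 95% confidence intervals.
Z_975 = 1.959964

#: Lower bound applied to every p-value to avoid underflow to exactly 0.
P_FLOOR = 1e-300


def two_sided_p(beta: float, se: float) -> float:
    """Two-sided normal p-value for beta/se, floored at ``P_FLOOR``.

    With se == 0 the convention is p = 0 for a nonzero beta (a point mass away
    from the null) and p = 1 at beta == 0.
    """
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return max(float(p), P_FLOOR)


def normal_ci(beta: float, se: float, alpha: float = 0.05) -> tuple[float, float]:
    """Equal-tailed normal (1-alpha) confidence interval on the beta scale."""
    z = Z_975 if alpha == 0.05 else float(stats.norm.ppf(1.0 - alpha / 2.0))
    return beta - z * se, beta + z * se


def as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr
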