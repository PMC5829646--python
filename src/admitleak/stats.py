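"""Two-sample tests used to compare offset distributions.

Both procedures are implemented directly from their defining formulas:

* Two-sample Kolmogorov–Smirnov: D = sup_t |F1(t) - F2(t)| over the empirical
  CDFs, with the two-sided p-value from the asymptotic Kolmogorov
  distribution at effective size n1*n2/(n1+n2). Day offsets are heavily tied
  integers; under ties the asymptotic p-value is conservative (the true
  rejection rate at a nominal level is below it), which matches the reference
  behavior of the usual statistical environments.
* Two-sample proportion test: pooled z statistic without continuity
  correction, two-sided normal p-value. A Yates-corrected variant is
  available via ``continuity_correction=True``.

Plus the Bonferroni adjustment min(1, p*m). p-values below the double
precision floor 2.2e-16 are rendered as "< 2.2e-16" by :func:`format_p`.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

__all__ = [
    "KSResult",
    "PropTestResult",
    "kolmogorov_sf",
    "ks_two_sample",
    "prop_two_sample",
    "bonferroni",
    "format_p",
]

P_FLOOR = 2.2e-16


@dataclass
class KSResult:
    D: float
    p_value: float
    n1: int
    n2: int

    def __post_init__(self):
        if not 0.0 <= self.D <= 1.0:
            raise ValueError("KS statistic must lie in [0, 1]")


@dataclass
class PropTestResult:
    p1: float
    p2: float
    z: float
    p_value: float
    n1: int
    n2: int
    degenerate: bool = False


def kolmogorov_sf(x: float) -> float:
    """Survival function of the Kolmogorov distribution.

    Q(x) = 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 x^2), clamped to [0, 1].
    For x near zero the alternating series converges too slowly to be useful,
    but Q is 1 to double precision there anyway.
    """
    if x <= 0.05:
        return 1.0
    total = 0.0
    for k in range(1, 201):
        term = math.exp(-2.0 * k * k * x * x)
        total += -term if k % 2 == 0 else term
        if term < 1e-18:
            break
    return min(1.0, max(0.0, 2.0 * total))


def ks_two_sample(x, y) -> KSResult:
    """Two-sample KS test on two non-empty multisets.

    D is the exact maximum vertical gap between the two empirical CDFs,
    evaluated over the pooled support; the p-value is asymptotic.
    """
    xs = np.sort(np.asarray(list(x) if not isinstance(x, np.ndarray) else x).ravel())
    ys = np.sort(np.asarray(list(y) if not isinstance(y, np.ndarray) else y).ravel())
    n1, n2 = xs.size, ys.size
    if n1 == 0 or n2 == 0:
        raise ValueError("ks_two_sample requires two non-empty samples")
    pooled = np.concatenate([xs, ys])
    cdf1 = np.searchsorted(xs, pooled, side="right") / n1
    cdf2 = np.searchsorted(ys, pooled, side="right") / n2
    d = float(np.max(np.abs(cdf1 - cdf2)))
    n_eff = n1 * n2 / (n1 + n2)
    p = kolmogorov_sf(math.sqrt(n_eff) * d)
    return KSResult(D=d, p_value=p, n1=int(n1), n2=int(n2))


def _normal_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def prop_two_sample(
    x1: int, n1: int, x2: int, n2: int, continuity_correction: bool = False
) -> PropTestResult:
    """Two-sample pooled proportion z-test, two-sided.

    z = (p1 - p2) / sqrt(p*(1-p*)(1/n1 + 1/n2)) with p* the pooled
    proportion. When the pooled proportion is 0 or 1 the statistic is
    undefined; the result is flagged degenerate with p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return PropTestResult(p1=p1, p2=p2, z=0.0, p_value=1.0,
                              n1=n1, n2=n2, degenerate=True)
    diff = p1 - p2
    if continuity_correction:
        cc = 0.5 * (1.0 / n1 + 1.0 / n2)
        diff = math.copysign(max(0.0, abs(diff) - cc), diff)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = diff / se
    p = min(1.0, 2.0 * _normal_sf(abs(z)))
    return PropTestResult(p1=p1, p2=p2, z=z, p_value=p, n1=n1, n2=n2)


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, p*m); m defaults to len(p_values)."""
    p_list = list(p_values)
    if m is None:
        m = len(p_list)
    if m < len(p_list):
        raise ValueError("m must be at least the number of p-values")
    for p in p_list:
        if not 0.0 <= p <= 1.0:
            raise ValueError("p-values must lie in [0, 1]")
    return [min(1.0, p * m) for p in p_list]


def format_p(p: float) -> str:
    """Render a p-value, flooring at the double-precision convention."""
    if p < P_FLOOR:
        return "< 2.2e-16"
    return f"{p:.4g}"
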