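"""Independent brute-force oracles used to cross-check the package.

Everything here deliberately avoids the code paths under test: correlation
uses explicit covariance sums in pure Python, the t tail is obtained by
numeric integration of a hand-written density, and OLS comes straight from
the normal equations.
"""

from __future__ import annotations

import math

from scipy.integrate import quad


def brute_pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def t_density(t: float, df: int) -> float:
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + t * t / df) ** (-(df + 1) / 2)


def t_tail(t: float, df: int) -> float:
    """P(T >= t) for Student's t by numeric integration."""
    value, _ = quad(t_density, t, math.inf, args=(df,), epsabs=1e-14, epsrel=1e-13)
    return value


def brute_pearson_p(x, y) -> tuple[float, float]:
    """Two-sided p of the Pearson coefficient via the t transform."""
    n = len(x)
    r = brute_pearson(x, y)
    if abs(r) >= 1:
        return r, 0.0
    t = abs(r) * math.sqrt((n - 2) / (1 - r * r))
    return r, 2.0 * t_tail(t, n - 2)


def brute_ols(x, y) -> tuple[float, float]:
    """Slope and intercept from the normal equations."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(a * a for a in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def brute_feature(tumor: float, normal: float, intensity: float,
                  base: float = 1.1) -> float:
    return (math.log(tumor / normal) / math.log(2.0)) * (
        math.log(intensity) / math.log(base)
    )
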