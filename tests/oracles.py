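"""Independent brute-force oracles used to cross-check the package's
statistics: tail probabilities by numerical quadrature of densities written
directly from gamma functions, never via scipy.stats distribution objects."""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def t_pdf(x: float, df: float) -> float:
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    return c * (1 + x * x / df) ** (-(df + 1) / 2)


def t_two_sided_p(t: float, df: float) -> float:
    tail, _ = quad(t_pdf, abs(t), np.inf, args=(df,))
    return min(2.0 * tail, 1.0)


def chi2_pdf(x: float, df: float) -> float:
    if x <= 0:
        return 0.0
    return x ** (df / 2 - 1) * math.exp(-x / 2) / (2 ** (df / 2) * math.gamma(df / 2))


def chi2_sf(x: float, df: float) -> float:
    tail, _ = quad(chi2_pdf, x, np.inf, args=(df,))
    return tail


def welch_oracle(a, b):
    """Welch statistic, df and two-sided p computed from first principles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df, t_two_sided_p(t, df)


def chi_square_oracle(table):
    """Pearson chi-square by direct summation over the 2x2 cells."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = t[i].sum() * t[:, j].sum() / n
            stat += (t[i, j] - e) ** 2 / e
    return stat, chi2_sf(stat, 1.0)


def pearson_oracle(x, y):
    """Pearson r from raw sums plus the t-transform p via quadrature."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    r = num / den
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, t_two_sided_p(t, n - 2)
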