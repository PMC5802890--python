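"""Independent reference implementations used only to check the package.

Deliberately slow and literal: exact rational hypergeometric enumeration
for the two-sided Fisher test, and a loop-based Efron partial likelihood
maximized by dense grid + golden-section refinement for the binary-covariate
Cox model.  Nothing here imports from ``cutscan``.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_exact(a, b, c, d) -> Fraction:
    """Sum of hypergeometric probabilities <= that of the observed table.

    All tables share the denominator C(n, a+c), so the comparison is done
    on integer numerators: exact arithmetic, no floating-point gates.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    obs = comb(r1, a) * comb(r2, c)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = comb(r1, x) * comb(r2, c1 - x)
        if num <= obs:
            total += num
    return Fraction(total, comb(n, c1))


def efron_loglik(beta, time, event, z):
    """Literal Efron partial log-likelihood for one binary covariate."""
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    z = np.asarray(z, float)
    ll = 0.0
    for t in np.unique(time[event]):
        deaths = (time == t) & event
        risk = time >= t
        d = int(deaths.sum())
        ll += beta * z[deaths].sum()
        s0 = np.exp(beta * z[risk]).sum()
        s0d = np.exp(beta * z[deaths]).sum()
        for l in range(d):
            ll -= np.log(s0 - (l / d) * s0d)
    return ll


def cox_grid_oracle(time, event, z, lo=-8.0, hi=8.0):
    """Maximize the Efron partial likelihood by grid + golden-section search.

    Returns ``(beta_hat, hr, wald_p)`` with the Wald statistic built from a
    central-difference observed information at the optimum.
    """
    from scipy import optimize, stats

    grid = np.linspace(lo, hi, 2001)
    vals = np.array([efron_loglik(b, time, event, z) for b in grid])
    b0 = grid[np.argmax(vals)]
    res = optimize.minimize_scalar(
        lambda b: -efron_loglik(b, time, event, z),
        bracket=None, bounds=(b0 - 0.02, b0 + 0.02), method="bounded",
        options={"xatol": 1e-10})
    beta = res.x
    h = 1e-4
    info = -(efron_loglik(beta + h, time, event, z)
             - 2 * efron_loglik(beta, time, event, z)
             + efron_loglik(beta - h, time, event, z)) / h**2
    se = 1.0 / np.sqrt(info)
    p = 2 * stats.norm.sf(abs(beta) / se)
    return beta, np.exp(beta), p


def km_product_limit(time, event):
    """Hand product-limit estimator; returns (times, survival) at event times."""
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(time):
        at_risk = (time >= t).sum()
        d = ((time == t) & event).sum()
        if d:
            s *= 1 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)
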