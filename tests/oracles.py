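"""Independent brute-force oracles used to check the package's numerics.

Everything here is deliberately naive: fixed-grid Riemann/trapezoid sums,
direct normal-equation algebra, and textbook formulas, sharing no code with
the implementation they check.
"""

import math

import numpy as np
from scipy.special import betaln, gammaln, hyp2f1


def ols_line_bruteforce(t, y):
    """Slope/intercept/RSS by the raw normal equations, no shortcuts."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = t.size
    sxx = np.sum(t * t) - np.sum(t) ** 2 / n
    sxy = np.sum(t * y) - np.sum(t) * np.sum(y) / n
    slope = sxy / sxx
    intercept = (np.sum(y) - slope * np.sum(t)) / n
    resid = y - slope * t - intercept
    return slope, intercept, float(np.sum(resid**2))


def jzs_bf_grid(t, n, scale=math.sqrt(2) / 2, n_grid=200_001, z_lo=-25.0, z_hi=25.0):
    """One-sample JZS Bayes factor by trapezoid quadrature on a fixed
    log-g grid (Cauchy prior on effect size = inverse-gamma mixture on g)."""
    nu = n - 1
    z = np.linspace(z_lo, z_hi, n_grid)
    g = np.exp(z)
    log_num = (
        -0.5 * np.log1p(n * g)
        - 0.5 * (nu + 1) * np.log1p(t * t / (nu * (1 + n * g)))
        + math.log(scale)
        - 0.5 * math.log(2 * math.pi)
        - 1.5 * z
        - scale**2 / (2 * g)
        + z  # Jacobian dg = g dz
    )
    m = np.max(log_num)
    num = np.trapezoid(np.exp(log_num - m), z)
    log_den = -0.5 * (nu + 1) * math.log1p(t * t / nu)
    return math.exp(m + math.log(num) - log_den)


def corr_posterior_grid(r, n, kappa=1.0, n_grid=200_001):
    """Correlation Bayes factor and posterior summaries by trapezoid sums on
    a fixed rho grid, using the exact sampling density of the sample
    correlation coefficient and a stretched-beta prior."""
    eps = 1e-9
    rho = np.linspace(-1 + eps, 1 - eps, n_grid)
    a = 1.0 / kappa
    log_prior = (
        (a - 1.0) * np.log1p(-rho * rho) - (2 * a - 1) * math.log(2) - betaln(a, a)
    )
    rr = rho * r
    c = n - 0.5
    log_lik_ratio = (
        0.5 * (n - 1) * np.log1p(-rho * rho)
        - (n - 1.5) * np.log1p(-rr)
        + np.log(hyp2f1(0.5, 0.5, c, (1 + rr) / 2))
        - math.log(hyp2f1(0.5, 0.5, c, 0.5))
    )
    log_int = log_lik_ratio + log_prior
    m = np.max(log_int)
    w = np.exp(log_int - m)
    bf10 = math.exp(m + math.log(np.trapezoid(w, rho)))
    # posterior summaries from the same grid
    dens = w / np.trapezoid(w, rho)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(rho))])
    cdf /= cdf[-1]
    median = float(np.interp(0.5, cdf, rho))
    ci = (float(np.interp(0.05, cdf, rho)), float(np.interp(0.95, cdf, rho)))
    dev = np.abs(rho - median)
    order = np.argsort(dev)
    wt = np.gradient(rho) * dens
    cw = np.cumsum(wt[order])
    mad = float(dev[order][np.searchsorted(cw, 0.5 * cw[-1])])
    return bf10, median, mad, ci


def uniform_mean_se(lo, hi, n):
    """Standard error of the mean of n Uniform(lo, hi) draws."""
    return (hi - lo) / math.sqrt(12.0) / math.sqrt(n)
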