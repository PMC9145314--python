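"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the profile-CI
oracle walks a fixed grid of constrained refits (with the potency
parameter solved by sign-change bracketing + Brent, not the closed-form
inverse, and the nuisance parameters optimized by Nelder-Mead), the
enrichment-score oracle walks the ranked list gene by gene, and the
t-test oracle is the textbook formula."""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize, stats

from goldpath.fitting import DoseResponseDataset, FitResult, log_likelihood_from_rss
from goldpath.models import C_BOUNDS, D_BOUNDS, response_direction


def _curve(family, level, b, c, d, x):
    """Unit-background mean response, raw arithmetic (b may be an array)."""
    b = np.asarray(b, dtype=float)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        if family == "exponential":
            if level == 2:
                y = np.exp(b * x)
            elif level == 3:
                y = np.exp(b * x**d)
            elif level == 4:
                y = c - (c - 1.0) * np.exp(-b * x)
            else:
                y = c - (c - 1.0) * np.exp(-b * x**d)
        else:
            if level == 2:
                y = 1.0 - x / (b + x)
            elif level == 3:
                y = 1.0 - x**d / (b**d + x**d)
            elif level == 4:
                y = 1.0 + (c - 1.0) * x / (b + x)
            else:
                y = 1.0 + (c - 1.0) * x**d / (b**d + x**d)
    return y


def _solve_b(family, level, c, d, bmd, target_ratio):
    """b such that the unit-background response at the BMD equals the
    target ratio, by bracketing on a wide grid + Brent."""
    if family == "hill":
        grid = np.geomspace(1e-6, 1e8, 200)
    else:
        grid = np.concatenate([-np.geomspace(1e2, 1e-9, 120),
                               np.geomspace(1e-9, 1e2, 120)])
    vals = _curve(family, level, grid, c, d, bmd) - target_ratio
    ok = np.isfinite(vals)
    sign_change = ok[:-1] & ok[1:] & (np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    idx = np.where(sign_change)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    f = lambda b: float(_curve(family, level, b, c, d, bmd)) - target_ratio
    return optimize.brentq(f, grid[i], grid[i + 1], xtol=1e-14, rtol=1e-15)


def constrained_loglik(fit: FitResult, data: DoseResponseDataset, bmr: float,
                       bmd: float) -> float:
    """Best log-likelihood subject to the curve passing through the
    benchmark response at the given BMD."""
    family, level = fit.spec.family, fit.spec.level
    target = 1.0 + response_direction(fit.spec) * bmr
    x, logy = data.doses, np.log(data.responses)
    n = data.n_obs

    def rss_of(vec):
        la = vec[0]
        i = 1
        c = d = None
        if level >= 4:
            c = float(np.clip(vec[i], *C_BOUNDS)); i += 1
        if level in (3, 5):
            d = float(np.clip(vec[i], *D_BOUNDS))
        b = _solve_b(family, level, c, d, bmd, target)
        if b is None:
            return 1e12
        g = _curve(family, level, b, c, d, x)
        if np.any(g <= 0) or not np.all(np.isfinite(g)):
            return 1e12
        return float(np.sum((logy - np.log(g) - la) ** 2))

    v0 = [float(np.mean(logy))]
    if level >= 4:
        v0.append(fit.spec.c)
    if level in (3, 5):
        v0.append(fit.spec.d)
    res = optimize.minimize(rss_of, np.asarray(v0, float), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12,
                                     "maxiter": 500})
    return log_likelihood_from_rss(float(res.fun), n)


def grid_profile_ci(fit: FitResult, data: DoseResponseDataset, bmr: float,
                    bmd_hat: float, level: float = 0.90,
                    span: float = 6.0, n_grid: int = 200) -> tuple[float, float]:
    """Profile bounds from a fixed log-spaced grid of constrained refits,
    crossing points by linear interpolation of the profile in log dose."""
    grid = np.geomspace(bmd_hat / span, bmd_hat * span, n_grid)
    prof = np.array([constrained_loglik(fit, data, bmr, g) for g in grid])
    ll_ref = max(float(prof.max()), fit.log_likelihood)
    target = ll_ref - 0.5 * stats.chi2.ppf(level, 1)
    below = prof < target
    i_hat = int(np.argmin(np.abs(grid - bmd_hat)))

    def cross(i, j):
        x0, x1, y0, y1 = grid[i], grid[j], prof[i], prof[j]
        f = (target - y0) / (y1 - y0)
        return float(x0 * (x1 / x0) ** f)

    lo = grid[0]
    for i in range(i_hat, 0, -1):
        if below[i - 1] and not below[i]:
            lo = cross(i - 1, i)
            break
    hi = grid[-1]
    for i in range(i_hat, n_grid - 1):
        if below[i + 1] and not below[i]:
            hi = cross(i, i + 1)
            break
    return lo, hi


def brute_enrichment_score(metric: np.ndarray, hits: np.ndarray,
                           weight: float = 1.0) -> float:
    """Running-sum ES by explicit walk (ties between equal-magnitude
    extrema resolve positive, matching the documented convention)."""
    n = len(metric)
    nh = int(hits.sum())
    w = np.abs(metric) ** weight
    nr = w[hits].sum()
    if nr == 0:
        w = np.ones(n)
        nr = float(nh)
    run, pos, neg = 0.0, 0.0, 0.0
    for i in range(n):
        run += w[i] / nr if hits[i] else -1.0 / (n - nh)
        pos, neg = max(pos, run), min(neg, run)
    return pos if pos + neg >= -1e-12 else neg


def textbook_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Equal-variance two-sample t statistic and two-sided p."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)
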