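"""Benchmark-dose estimation with profile-likelihood confidence intervals.

The benchmark dose (BMD) for a continuous endpoint is the dose at which
the fitted mean response differs from the background ``a`` by a chosen
benchmark response (BMR, a fraction such as 0.10), in the direction the
fitted curve moves.  Per-model 90% confidence bounds (BMDL, BMDU) come
from the profile-likelihood method: the BMD is made an explicit model
parameter (``b`` is eliminated through the closed-form inverse) and the
bounds are where the profile log-likelihood drops by chi2_1(0.90)/2 =
1.3528 from its maximum.  Accepted models are combined by taking the
geometric mean of their BMDs, with the combined 90% interval spanning
the smallest BMDL and the largest BMDU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .fitting import (
    DoseResponseDataset,
    FitResult,
    goodness_of_fit,
    log_likelihood_from_rss,
    select_model,
)
from .models import (
    C_BOUNDS,
    D_BOUNDS,
    ModelSpec,
    b_from_bmd,
    bmd_closed_form,
    eval_model,
    is_constant,
    response_direction,
)

_LOG_FLOOR = 1e-300


class BmdRangeError(ValueError):
    """The fitted curve does not reach the benchmark response in range."""


class NoAcceptedModelError(RuntimeError):
    pass


def compute_bmd(fit: FitResult, bmr: float, range_factor: float = 10.0) -> float:
    """Benchmark dose of a fitted, non-constant model (closed form).

    Raises ``BmdRangeError`` when the curve only reaches the BMR beyond
    ``range_factor`` times the highest tested dose (extrapolation far
    outside the design carries no information).
    """
    spec = fit.spec
    if is_constant(spec):
        raise BmdRangeError("constant model has no benchmark dose")
    try:
        bmd = bmd_closed_form(spec, bmr)
    except ValueError as err:
        raise BmdRangeError(str(err)) from err
    if fit.max_dose > 0 and bmd > range_factor * fit.max_dose:
        raise BmdRangeError(
            f"BMD {bmd:.3g} beyond observed range (>{range_factor:g}x max dose)"
        )
    return bmd


# ---------------------------------------------------------------------------
# profile likelihood
# ---------------------------------------------------------------------------

def _profile_rss(family, level, bmd, bmr, direction, cd, x, logy):
    """Log-scale RSS at fixed BMD with nuisance (c, d) given; the
    background a is profiled analytically (the curve is multiplicative
    in a)."""
    c = d = None
    i = 0
    if level >= 4:
        c = float(np.clip(cd[i], *C_BOUNDS))
        i += 1
    if level in (3, 5):
        d = float(np.clip(cd[i], *D_BOUNDS))
    template = ModelSpec(family=family, level=level, a=1.0, b=1.0,
                         c=c if c is not None else None,
                         d=d if d is not None else None)
    try:
        b = b_from_bmd(template, bmd, bmr, direction)
        if family == "hill" and b <= 0:
            return np.inf
        unit = template.with_parameters(b=b)
    except (ValueError, OverflowError, ZeroDivisionError):
        return np.inf
    g = np.asarray(eval_model(unit, x), float)
    if np.any(g <= 0) or not np.all(np.isfinite(g)):
        return np.inf
    logg = np.log(g)
    resid = logy - logg
    la = resid.mean()
    return float(np.sum((resid - la) ** 2))


def profile_loglik(
    fit: FitResult,
    data: DoseResponseDataset,
    bmr: float,
    bmd: float,
    direction: int,
    warm: np.ndarray | None = None,
) -> tuple[float, np.ndarray | None]:
    """Profile log-likelihood at a fixed BMD: maximize over the nuisance
    parameters with ``b`` eliminated via the BMD reparameterization."""
    family, level = fit.spec.family, fit.spec.level
    x, logy = data.doses, np.log(data.responses)
    n = data.n_obs
    n_cd = (1 if level >= 4 else 0) + (1 if level in (3, 5) else 0)
    if n_cd == 0:
        rss = _profile_rss(family, level, bmd, bmr, direction, (), x, logy)
        if not math.isfinite(rss):
            return -np.inf, None
        return log_likelihood_from_rss(rss, n), None

    starts = []
    if warm is not None:
        starts.append(np.asarray(warm, float))
    mle_cd = []
    if level >= 4:
        mle_cd.append(fit.spec.c)
    if level in (3, 5):
        mle_cd.append(fit.spec.d)
    starts.append(np.array(mle_cd, float))

    def objective(cd):
        rss = _profile_rss(family, level, bmd, bmr, direction, cd, x, logy)
        return rss if math.isfinite(rss) else 1e12

    best_rss, best_cd = np.inf, None
    for s0 in starts:
        res = optimize.minimize(objective, s0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-12,
                                         "maxiter": 400})
        if res.fun < best_rss:
            best_rss, best_cd = float(res.fun), res.x
    if not math.isfinite(best_rss) or best_rss >= 1e12:
        return -np.inf, None
    return log_likelihood_from_rss(best_rss, n), best_cd


def profile_ci(
    fit: FitResult,
    data: DoseResponseDataset,
    bmr: float,
    level: float = 0.90,
    rel_tol: float = 1e-4,
) -> tuple[float, float]:
    """Profile-likelihood (BMDL, BMDU) for the fitted model's BMD.

    A bound that is never crossed within a factor 10^6 of the BMD is
    reported as 0.0 (lower) or inf (upper), flagging an unbounded
    profile rather than inventing a number.
    """
    bmd_hat = compute_bmd(fit, bmr, range_factor=np.inf)
    direction = response_direction(fit.spec)
    drop = 0.5 * stats.chi2.ppf(level, 1)

    ll_at_hat, warm0 = profile_loglik(fit, data, bmr, bmd_hat, direction)
    ll_ref = max(fit.log_likelihood, ll_at_hat)
    target = ll_ref - drop

    def search(step: float) -> float:
        x_prev, warm = bmd_hat, warm0
        for _ in range(200):
            x_new = x_prev * step
            if x_new < bmd_hat * 1e-6:
                return 0.0
            if x_new > bmd_hat * 1e6:
                return math.inf
            ll, warm = profile_loglik(fit, data, bmr, x_new, direction, warm)
            if ll < target:
                lo, hi = (x_new, x_prev) if step < 1 else (x_prev, x_new)
                f = lambda v: profile_loglik(fit, data, bmr, v, direction, warm)[0] - target
                return float(optimize.brentq(f, lo, hi, rtol=rel_tol))
            x_prev = x_new
        return 0.0 if step < 1 else math.inf

    bmdl = search(0.75)
    bmdu = search(1.0 / 0.75)
    bmdl = min(bmdl, bmd_hat)
    bmdu = max(bmdu, bmd_hat)
    return bmdl, bmdu


# ---------------------------------------------------------------------------
# model averaging and the per-endpoint analysis
# ---------------------------------------------------------------------------

@dataclass
class BmdResult:
    """Model-averaged benchmark dose with its 90% interval."""

    bmr: float
    per_model_bmd: dict[str, tuple[float, float, float]]
    averaged_bmd: float
    ci90: tuple[float, float]
    accepted_models: list[str]
    endpoint_label: str = ""


def model_average(results: dict[str, tuple[float, float, float]],
                  bmr: float = 0.10, endpoint_label: str = "") -> BmdResult:
    """Geometric-mean BMD across accepted models; interval spans the
    smallest BMDL and the largest BMDU."""
    if not results:
        raise NoAcceptedModelError("no accepted models")
    for name, (bmd, bmdl, bmdu) in results.items():
        if not (bmdl <= bmd <= bmdu):
            raise ValueError(f"{name}: BMDL <= BMD <= BMDU violated")
    bmds = np.array([v[0] for v in results.values()])
    averaged = float(np.exp(np.mean(np.log(bmds))))
    ci = (min(v[1] for v in results.values()),
          max(v[2] for v in results.values()))
    return BmdResult(bmr, dict(results), averaged, ci,
                     sorted(results), endpoint_label)


@dataclass
class EndpointBmdReport:
    """Full per-endpoint record: selection, fit diagnostics, BMDs."""

    result: BmdResult | None
    selections: dict[str, "object"]
    gof_pvalues: dict[str, float]
    rejected: dict[str, str]

    def to_dict(self) -> dict:
        out = {
            "accepted_models": self.result.accepted_models if self.result else [],
            "gof_pvalues": self.gof_pvalues,
            "rejected": self.rejected,
        }
        if self.result:
            out.update(
                bmr=self.result.bmr,
                averaged_bmd=self.result.averaged_bmd,
                ci90=list(self.result.ci90),
                per_model={k: list(v) for k, v in self.result.per_model_bmd.items()},
            )
        for fam, sel in self.selections.items():
            out[f"{fam}_selected"] = sel.best.name
            out[f"{fam}_loglik"] = {f.name: f.log_likelihood
                                    for f in sel.fits.values()}
        return out


def benchmark_dose_analysis(
    data: DoseResponseDataset,
    bmr: float = 0.10,
    families: tuple[str, ...] = ("exponential", "hill"),
    alpha: float = 0.05,
    gof_alpha: float = 0.05,
    ci_level: float = 0.90,
) -> EndpointBmdReport:
    """Select a member per family by LRT, screen it by goodness of fit,
    derive BMD and profile bounds, and model-average the survivors.

    ``result`` is None when no family shows an adequate dose-response
    relationship (the outcome reported for flat endpoints).
    """
    selections, gofs, rejected = {}, {}, {}
    accepted: dict[str, tuple[float, float, float]] = {}
    for family in families:
        sel = select_model(data, family, alpha=alpha)
        selections[family] = sel
        if is_constant(sel.best.spec):
            rejected[sel.best.name] = "no dose-response relationship"
            continue
        p_gof = goodness_of_fit(sel.best, data)
        gofs[sel.best.name] = p_gof
        if p_gof <= gof_alpha:
            rejected[sel.best.name] = f"goodness-of-fit p = {p_gof:.3g} <= {gof_alpha}"
            continue
        try:
            bmd = compute_bmd(sel.best, bmr)
            bmdl, bmdu = profile_ci(sel.best, data, bmr, level=ci_level)
        except BmdRangeError as err:
            rejected[sel.best.name] = str(err)
            continue
        accepted[sel.best.name] = (bmd, bmdl, bmdu)
    result = None
    if accepted:
        result = model_average(accepted, bmr=bmr,
                               endpoint_label=data.endpoint_label)
    return EndpointBmdReport(result, selections, gofs, rejected)
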