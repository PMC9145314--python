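"""Maximum-likelihood fitting and likelihood-ratio model selection.

Responses are treated as log-normally distributed around the model curve
with a homoscedastic log-scale SD (standard for positive continuous
toxicology endpoints such as viability % or cytokine pg/mL), so the MLE
of the curve parameters is the least-squares fit on log responses and
the residual SD is profiled out analytically.  Model selection walks the
nesting lattice 1 -> 2 -> {3, 4} -> 5 and keeps an extension only when
the likelihood-ratio test improves the fit at the configured level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import C_BOUNDS, D_BOUNDS, ModelSpec

_LOG_FLOOR = 1e-300
_MIN_SIGMA2 = 1e-18


class FitError(RuntimeError):
    pass


@dataclass
class DoseResponseDataset:
    """Doses with replicate positive responses for one endpoint.

    ``doses`` and ``responses`` are parallel per-observation arrays;
    replicate experiments are pooled, with the experiment identifier
    retained for bookkeeping only (no random effect is modelled).
    """

    doses: np.ndarray
    responses: np.ndarray
    endpoint_label: str = ""
    dose_unit: str = "ug/mL"
    experiment: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must be parallel arrays")
        if np.any(self.doses < 0):
            raise ValueError("doses must be >= 0")
        if np.any(self.responses <= 0):
            raise ValueError(
                "all responses must be > 0 (log-scale likelihood undefined)"
            )
        groups = np.unique(self.doses)
        if len(groups) < 3 or 0.0 not in groups:
            raise ValueError("need >= 3 distinct doses including a dose-0 control")

    @property
    def n_obs(self) -> int:
        return len(self.responses)

    @property
    def dose_groups(self) -> np.ndarray:
        return np.unique(self.doses)

    @property
    def max_dose(self) -> float:
        return float(self.doses.max())

    def group_log_means(self) -> pd.Series:
        logy = pd.Series(np.log(self.responses))
        return logy.groupby(pd.Series(self.doses)).mean()

    @classmethod
    def from_frame(cls, df: pd.DataFrame, endpoint: str | None = None,
                   dose_unit: str = "ug/mL") -> "DoseResponseDataset":
        """Build from a tidy table with columns dose, response and
        optionally replicate/experiment/endpoint."""
        if endpoint is not None and "endpoint" in df.columns:
            df = df[df["endpoint"] == endpoint]
        label = endpoint or (
            str(df["endpoint"].iloc[0]) if "endpoint" in df.columns else ""
        )
        exp = df["experiment"].to_numpy() if "experiment" in df.columns else None
        return cls(
            doses=df["dose"].to_numpy(float),
            responses=df["response"].to_numpy(float),
            endpoint_label=label,
            dose_unit=dose_unit,
            experiment=exp,
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DoseResponseDataset":
        return cls.from_frame(pd.read_csv(path), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"dose": self.doses, "response": self.responses})
        if self.experiment is not None:
            out["experiment"] = self.experiment
        out["endpoint"] = self.endpoint_label
        return out


@dataclass
class FitResult:
    """A fitted family member: estimated spec, log-likelihood, bookkeeping."""

    spec: ModelSpec
    log_likelihood: float
    converged: bool
    n_parameters: int
    n_obs: int
    max_dose: float
    rss_log: float = float("nan")

    @property
    def name(self) -> str:
        return self.spec.name


def log_likelihood_from_rss(rss: float, n: int) -> float:
    """Profiled log-normal log-likelihood given the log-scale RSS."""
    sigma2 = max(rss / n, _MIN_SIGMA2)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


# ---------------------------------------------------------------------------
# parameter packing: optimize (log a, b | log b, c, d) with box bounds
# ---------------------------------------------------------------------------

def _pack(spec: ModelSpec) -> np.ndarray:
    vec = [math.log(spec.a)]
    if spec.level >= 2:
        vec.append(spec.b if spec.family == "exponential" else math.log(spec.b))
    if spec.level >= 4:
        vec.append(spec.c)
    if spec.level in (3, 5):
        vec.append(spec.d)
    return np.array(vec, float)


def _unpack(vec: np.ndarray, family: str, level: int) -> dict:
    out = {"a": math.exp(vec[0])}
    i = 1
    if level >= 2:
        out["b"] = vec[i] if family == "exponential" else math.exp(vec[i])
        i += 1
    if level >= 4:
        out["c"] = float(np.clip(vec[i], *C_BOUNDS))
        i += 1
    if level in (3, 5):
        out["d"] = float(np.clip(vec[i], *D_BOUNDS))
    return out


def _bounds(family: str, level: int) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [-np.inf], [np.inf]
    if level >= 2:
        lo.append(-np.inf)
        hi.append(np.inf)
    if level >= 4:
        lo.append(C_BOUNDS[0])
        hi.append(C_BOUNDS[1])
    if level in (3, 5):
        lo.append(D_BOUNDS[0])
        hi.append(D_BOUNDS[1])
    return np.array(lo), np.array(hi)


def _residuals(vec, family, level, x, logy):
    # hot path: inline curve evaluation on raw transformed parameters
    a = math.exp(vec[0])
    i = 1
    b = c = d = 0.0
    if level >= 2:
        b = vec[i] if family == "exponential" else math.exp(vec[i])
        i += 1
    if level >= 4:
        c = float(np.clip(vec[i], *C_BOUNDS))
        i += 1
    if level in (3, 5):
        d = float(np.clip(vec[i], *D_BOUNDS))
    with np.errstate(over="ignore", invalid="ignore"):
        if family == "exponential":
            if level == 2:
                f = a * np.exp(b * x)
            elif level == 3:
                f = a * np.exp(b * x**d)
            elif level == 4:
                f = a * (c - (c - 1.0) * np.exp(-b * x))
            else:
                f = a * (c - (c - 1.0) * np.exp(-b * x**d))
        else:
            if level == 2:
                f = a * (1.0 - x / (b + x))
            elif level == 3:
                xd = x**d
                f = a * (1.0 - xd / (b**d + xd))
            elif level == 4:
                f = a * (1.0 + (c - 1.0) * x / (b + x))
            else:
                xd = x**d
                f = a * (1.0 + (c - 1.0) * xd / (b**d + xd))
    f = np.where(np.isfinite(f), f, _LOG_FLOOR)
    return logy - np.log(np.maximum(f, _LOG_FLOOR))


def _default_starts(data: DoseResponseDataset, family: str, level: int) -> list[dict]:
    """Deterministic starting points derived from data quantiles."""
    logy = np.log(data.responses)
    x = data.doses
    means = data.group_log_means()
    a0 = math.exp(means.loc[0.0])
    xmax = data.max_dose
    top = math.exp(means.iloc[-1])
    ratio = max(top / a0, 1e-6)
    slope = math.log(ratio) / xmax if xmax > 0 else 0.0
    pos_doses = np.unique(x[x > 0])
    xmid = float(np.median(pos_doses))
    starts: list[dict] = []
    if level == 1:
        return [{"a": a0}]
    if family == "exponential":
        bs = [slope, slope * 0.3, slope * 3.0] if slope != 0 else [0.01 / max(xmax, 1), -0.01 / max(xmax, 1)]
        if level >= 3:
            bs = bs[:1]  # higher levels lean on nested warm starts
        for b in bs:
            st = {"a": a0, "b": b}
            if level >= 4:
                # level 4/5 use exp(-b x): embed sign flip; c from top/bottom ratio
                st["b"] = -b if b != 0 else 1.0 / max(xmax, 1.0)
                st["c"] = float(np.clip(ratio, 0.01, C_BOUNDS[1] - 0.1))
            if level in (3, 5):
                st["d"] = 1.0
            starts.append(st)
            if level in (3, 5):
                st2 = dict(st)
                st2["d"] = 2.0
                starts.append(st2)
    else:
        b_starts = (xmid, xmax / 4.0 + 1e-9, xmax) if level == 2 else (xmid,)
        for b in b_starts:
            st = {"a": a0, "b": max(b, 1e-9)}
            if level >= 4:
                st["c"] = float(np.clip(ratio, 0.01, C_BOUNDS[1] - 0.1))
            if level in (3, 5):
                st["d"] = 1.0
            starts.append(st)
            if level in (3, 5):
                st2 = dict(st)
                st2["d"] = 2.0
                starts.append(st2)
    return starts


def embed_in_level(spec: ModelSpec, level: int) -> dict | None:
    """Parameters of ``spec`` expressed inside a higher nested level,
    used to warm-start the bigger model so the nesting inequality of the
    log-likelihoods survives local optimization."""
    if level <= spec.level:
        return None
    p = {"a": spec.a}
    fam = spec.family
    eps_b = 1e-8
    sub = spec.level
    if fam == "exponential":
        b = spec.b if sub >= 2 else 0.0
        if sub <= 3 and level >= 4:
            b = -b if b != 0 else eps_b  # E2/E3 are E4/E5 with c=0, flipped b
        p["b"] = b if b != 0 else eps_b
        if level >= 4:
            p["c"] = spec.c if sub >= 4 else 0.0
        if level in (3, 5):
            p["d"] = spec.d if sub in (3, 5) and spec.d else 1.0
    else:
        p["b"] = spec.b if sub >= 2 else 1e4 * 1.0
        if level >= 4:
            p["c"] = spec.c if sub >= 4 else 0.0
        if level in (3, 5):
            p["d"] = spec.d if sub in (3, 5) and spec.d else 1.0
    return p


def fit_mle(
    data: DoseResponseDataset,
    spec: ModelSpec | None = None,
    family: str = "exponential",
    level: int = 2,
    extra_starts: list[dict] | None = None,
) -> FitResult:
    """Fit one family member by maximum likelihood (multi-start local
    least squares on log responses).

    ``spec`` may carry just family/level (a template); its parameter
    values, when present, join the deterministic start list.
    """
    if spec is not None:
        family, level = spec.family, spec.level
    x, logy = data.doses, np.log(data.responses)
    n = data.n_obs

    if level == 1:  # closed form: a = geometric mean
        a_hat = float(np.exp(logy.mean()))
        rss = float(np.sum((logy - math.log(a_hat)) ** 2))
        est = ModelSpec(family=family, level=1, a=a_hat,
                        residual_sd=math.sqrt(max(rss / n, 0.0)))
        return FitResult(est, log_likelihood_from_rss(rss, n), True,
                         est.n_parameters, n, data.max_dose, rss)

    starts = _default_starts(data, family, level)
    if extra_starts:
        starts = list(extra_starts) + starts
    lo, hi = _bounds(family, level)
    best_vec, best_rss, success = None, np.inf, False
    for st in starts:
        try:
            v0 = _pack(ModelSpec(family=family, level=level, **st))
        except (ValueError, OverflowError):
            continue
        v0 = np.minimum(np.maximum(v0, lo), hi)
        try:
            res = optimize.least_squares(
                _residuals, v0, args=(family, level, x, logy),
                bounds=(lo, hi), method="trf", xtol=1e-9, ftol=1e-11, gtol=1e-9,
                max_nfev=300,
            )
        except Exception:
            continue
        rss = float(2.0 * res.cost)
        if rss < best_rss - 1e-15 or best_vec is None:
            best_vec, best_rss, success = res.x, rss, bool(res.success)
    if best_vec is None:
        raise FitError(f"all starts failed for {family} level {level}")
    params = _unpack(best_vec, family, level)
    est = ModelSpec(family=family, level=level, **params,
                    residual_sd=math.sqrt(max(best_rss / n, 0.0)))
    return FitResult(est, log_likelihood_from_rss(best_rss, n), success,
                     est.n_parameters, n, data.max_dose, best_rss)


def lrt_pvalue(small: FitResult, big: FitResult) -> float:
    """Likelihood-ratio test of a nested pair; df = parameter-count gap."""
    df = big.n_parameters - small.n_parameters
    if df <= 0:
        raise ValueError("big model must have more parameters")
    stat = max(0.0, 2.0 * (big.log_likelihood - small.log_likelihood))
    return float(stats.chi2.sf(stat, df))


@dataclass
class SelectionResult:
    """Outcome of the likelihood-ratio walk along the nesting lattice."""

    best: FitResult
    fits: dict[int, FitResult]
    lrt_table: pd.DataFrame
    family: str

    @property
    def spec(self) -> ModelSpec:
        return self.best.spec


def fit_family(data: DoseResponseDataset, family: str) -> dict[int, FitResult]:
    """Fit all five members, warm-starting each from its nested
    submodels so the log-likelihood is non-decreasing along the chains."""
    fits: dict[int, FitResult] = {}
    for lvl in (1, 2, 3, 4, 5):
        extra = [e for s in fits.values()
                 if (e := embed_in_level(s.spec, lvl)) is not None]
        fits[lvl] = fit_mle(data, family=family, level=lvl, extra_starts=extra)
    return fits


def select_model(
    data: DoseResponseDataset, family: str, alpha: float = 0.05
) -> SelectionResult:
    """Walk 1 -> 2 -> {3, 4} -> 5, accepting an extension only when the
    LRT is significant at ``alpha``; returns the member that could not be
    significantly improved."""
    fits: dict[int, FitResult] = {}

    def fit_level(lvl: int) -> FitResult:
        if lvl not in fits:
            extra = [e for s in fits.values()
                     if (e := embed_in_level(s.spec, lvl)) is not None]
            fits[lvl] = fit_mle(data, family=family, level=lvl,
                                extra_starts=extra)
        return fits[lvl]

    rows = []
    current = 1
    p12 = lrt_pvalue(fit_level(1), fit_level(2))
    rows.append((1, 2, p12))
    if p12 < alpha:
        current = 2
        winners = []
        for lvl in (3, 4):
            p = lrt_pvalue(fits[2], fit_level(lvl))
            rows.append((2, lvl, p))
            if p < alpha:
                winners.append(lvl)
        if winners:
            current = max(winners, key=lambda l: fits[l].log_likelihood)
            p5 = lrt_pvalue(fits[current], fit_level(5))
            rows.append((current, 5, p5))
            if p5 < alpha:
                current = 5
    table = pd.DataFrame(rows, columns=["from_level", "to_level", "p_value"])
    return SelectionResult(fits[current], fits, table, family)


def goodness_of_fit(fit: FitResult, data: DoseResponseDataset) -> float:
    """Likelihood-ratio test of the fitted curve against the saturated
    "full model" of per-dose-group log means; the curve is adequate when
    p > 0.05.

    With the log-scale SD profiled out, the LR statistic is a monotone
    function of F = ((RSS_fit - RSS_full)/df1) / (RSS_full/df2), so the
    p-value is taken from the exact F(df1, df2) null rather than the
    chi-square approximation, which over-rejects badly at 3 replicates
    per dose group.  Falls back to the asymptotic chi-square only when
    the full model leaves no residual degrees of freedom.
    """
    if not fit.converged:
        raise FitError("goodness of fit requires a converged fit")
    means = data.group_log_means()
    logy = np.log(data.responses)
    fitted_means = means.loc[pd.Series(data.doses)].to_numpy()
    rss_full = float(np.sum((logy - fitted_means) ** 2))
    n = data.n_obs
    k_curve = fit.n_parameters - 1  # curve params; the SD is common
    n_groups = len(means)
    df1 = n_groups - k_curve
    df2 = n - n_groups
    if df1 < 0:
        raise FitError("fewer dose groups than fitted curve parameters")
    rss_fit = fit.rss_log
    if not math.isfinite(rss_fit):
        rss_fit = rss_full + max(0.0, 2.0 * (
            log_likelihood_from_rss(rss_full, n) - fit.log_likelihood))
    if df1 == 0:
        return 1.0 if rss_fit - rss_full < 1e-6 * max(rss_full, 1e-12) else 0.0
    if df2 == 0 or rss_full <= 0:
        # one replicate per dose: no within-group variance, use the
        # asymptotic LRT
        ll_full = log_likelihood_from_rss(rss_full, n)
        stat = max(0.0, 2.0 * (ll_full - fit.log_likelihood))
        return float(stats.chi2.sf(stat, df1))
    f_stat = max(0.0, (rss_fit - rss_full) / df1) / (rss_full / df2)
    return float(stats.f.sf(f_stat, df1, df2))
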