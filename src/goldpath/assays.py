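"""Deterministic plate-assay arithmetic.

Covers the processing around the dose-response modelling: WST-1
viability normalization (A440 - A620 background-corrected ratios), 5PL
ELISA calibration and inversion, LAL endotoxin threshold classification,
particle dose-metric conversion (particle-number nM to Au mass ug/mL and
log2 dose axes), and surface-to-volume geometry of rods and spheres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

ROLE_CELLS_X = "cells_treatment"
ROLE_MEDIUM_X = "medium_treatment"
ROLE_CELLS_C = "cells_control"
ROLE_MEDIUM_C = "medium_control"


class AssayError(ValueError):
    pass


def corrected_absorbance(df: pd.DataFrame) -> pd.Series:
    """Signal = A440 - A620 per well."""
    return df["A440"] - df["A620"]


def viability_percent(plate: pd.DataFrame, treatment: str) -> float:
    """WST-1 viability of a treatment, % of untreated control.

    (A(cells, X) - A(medium, X)) / (A(cells, C) - A(medium, C)) x 100
    with replicate wells averaged before the ratio; A is the
    background-corrected A440 - A620.
    """
    sig = corrected_absorbance(plate)

    def mean_for(role: str, trt: str | None) -> float:
        mask = plate["role"] == role
        if trt is not None:
            mask &= plate["treatment"] == trt
        if not mask.any():
            raise AssayError(f"no wells with role {role!r}"
                             + (f" for treatment {trt!r}" if trt else ""))
        return float(sig[mask].mean())

    num = mean_for(ROLE_CELLS_X, treatment) - mean_for(ROLE_MEDIUM_X, treatment)
    den = mean_for(ROLE_CELLS_C, None) - mean_for(ROLE_MEDIUM_C, None)
    if den <= 0:
        raise AssayError("control signal (denominator) must be > 0")
    return 100.0 * num / den


def viability_table(plate: pd.DataFrame) -> pd.DataFrame:
    """Viability % for every treatment present on the plate."""
    treatments = sorted(
        plate.loc[plate["role"] == ROLE_CELLS_X, "treatment"].unique()
    )
    return pd.DataFrame(
        {"treatment": treatments,
         "viability_percent": [viability_percent(plate, t) for t in treatments]}
    )


# ---------------------------------------------------------------------------
# 5PL ELISA calibration
# ---------------------------------------------------------------------------

@dataclass
class StandardCurve5PL:
    """Asymmetric five-parameter logistic OD(conc) calibration.

    od = lower + (upper - lower) / (1 + (conc/c50)**slope)**asymmetry
    ... written so ``lower`` is the zero-concentration (blank) asymptote
    and ``upper`` the saturating asymptote; ``slope`` < 0 makes the
    curve increase with concentration, as an ELISA does.
    """

    lower: float
    upper: float
    c50: float
    slope: float
    asymmetry: float
    rss: float = float("nan")
    monotone_standards: bool = True

    def eval(self, conc) -> np.ndarray | float:
        x = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(x > 0, (x / self.c50) ** self.slope, np.inf)
        y = self.lower + (self.upper - self.lower) / (1.0 + ratio) ** self.asymmetry
        y = np.where(x == 0, self.lower, y)
        return y if y.ndim else float(y)

    def invert(self, od: float) -> float:
        """Concentration giving this OD (strictly between the asymptotes)."""
        lo, hi = sorted((self.lower, self.upper))
        if not lo < od < hi:
            raise OutOfRangeError(
                f"OD {od:.4g} outside the calibrated range ({lo:.4g}, {hi:.4g})"
            )
        term = ((self.upper - self.lower) / (od - self.lower)) ** (1.0 / self.asymmetry) - 1.0
        return float(self.c50 * term ** (1.0 / self.slope))


class OutOfRangeError(AssayError):
    pass


def _5pl_vector(theta, x):
    lower, upper, log_c50, slope, log_g = theta
    c50, g = math.exp(log_c50), math.exp(log_g)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0, (x / c50) ** slope, np.inf)
        y = lower + (upper - lower) / (1.0 + ratio) ** g
    return np.where(x == 0, lower, y)


def fit_5pl(concentrations, ods) -> StandardCurve5PL:
    """Least-squares 5PL fit to a standard series (blank = conc 0 anchors
    the lower asymptote).  Requires >= 5 distinct standard levels; a
    non-monotone standard series is fitted best-effort and flagged."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(ods, dtype=float)
    if len(np.unique(x[x > 0])) < 5:
        raise AssayError("need >= 5 distinct non-blank standard concentrations")
    order = np.argsort(x)
    mono = bool(np.all(np.diff(y[order]) >= 0) or np.all(np.diff(y[order]) <= 0))

    lower0 = float(y[x == 0].mean()) if np.any(x == 0) else float(y.min())
    upper0 = float(y.max()) * 1.05
    mid = (lower0 + upper0) / 2.0
    c50_0 = float(x[np.argmin(np.abs(y - mid))])
    c50_0 = c50_0 if c50_0 > 0 else float(np.median(x[x > 0]))
    best = None
    for slope0 in (-1.0, -2.0):
        theta0 = np.array([lower0, upper0, math.log(c50_0), slope0, 0.0])
        res = optimize.least_squares(
            lambda t: _5pl_vector(t, x) - y, theta0, method="lm",
            xtol=1e-14, ftol=1e-14, max_nfev=20000,
        )
        if best is None or res.cost < best.cost:
            best = res
    lower, upper, log_c50, slope, log_g = best.x
    return StandardCurve5PL(
        lower=float(lower), upper=float(upper), c50=math.exp(log_c50),
        slope=float(slope), asymmetry=math.exp(log_g),
        rss=float(2 * best.cost), monotone_standards=mono,
    )


def invert_5pl(curve: StandardCurve5PL, od: float, dilution_factor: float = 1) -> float:
    """Back-calculate a sample concentration from its OD, scaled by the
    pre-dilution factor (e.g. 20-fold for IL-1beta supernatants)."""
    return curve.invert(od) * dilution_factor


def fit_5pl_from_plate(plate: pd.DataFrame) -> StandardCurve5PL:
    """Fit from a plate table with columns role/concentration/OD; rows
    with role 'standard' or 'blank' enter the calibration (blank at
    concentration 0), replicate wells averaged."""
    cal = plate[plate["role"].isin(["standard", "blank"])].copy()
    cal.loc[cal["role"] == "blank", "concentration"] = 0.0
    grouped = cal.groupby("concentration")["OD"].mean()
    return fit_5pl(grouped.index.to_numpy(), grouped.to_numpy())


# ---------------------------------------------------------------------------
# endotoxin classification (LAL)
# ---------------------------------------------------------------------------

def endotoxin_threshold(product_conc_ug_ml: float, limit_eu_per_mg: float = 0.5) -> float:
    """Contamination threshold in EU/mL for a product tested at the given
    concentration (0.5 EU/mg at 100 ug/mL = 0.05 EU/mL)."""
    if product_conc_ug_ml <= 0:
        raise AssayError("product concentration must be > 0")
    if limit_eu_per_mg < 0:
        raise AssayError("endotoxin limit must be >= 0")
    return limit_eu_per_mg * product_conc_ug_ml / 1000.0  # ug/mL -> mg/mL


def endotoxin_classify(
    measured_eu_ml: float,
    product_conc_ug_ml: float = 100.0,
    limit_eu_per_mg: float = 0.5,
    interference: bool = False,
) -> str:
    """Classify an LAL measurement: 'A' below the contamination
    threshold, 'B' above it, 'C' when particle interference precludes an
    accurate measurement (regardless of the value)."""
    if measured_eu_ml < 0:
        raise AssayError("measured endotoxin must be >= 0")
    if interference:
        return "C"
    thr = endotoxin_threshold(product_conc_ug_ml, limit_eu_per_mg)
    return "A" if measured_eu_ml < thr else "B"


def spike_recovery_interference(
    unspiked_eu_ml: float, spiked_eu_ml: float, spike_eu_ml: float = 0.5,
    window: tuple[float, float] = (0.5, 2.0),
) -> bool:
    """Optional helper: flag interference when the recovery of a known
    spike falls outside the 50-200% window (standard LAL practice)."""
    if spike_eu_ml <= 0:
        raise AssayError("spike must be > 0")
    recovery = (spiked_eu_ml - unspiked_eu_ml) / spike_eu_ml
    return not (window[0] <= recovery <= window[1])


# ---------------------------------------------------------------------------
# dose metrics and particle geometry
# ---------------------------------------------------------------------------

@dataclass
class ParticleGeometry:
    """Rod (flat-capped cylinder) or sphere geometry with the per-particle
    mass factor converting particle-number nM to Au mass ug/mL."""

    shape: str  # "rod" | "sphere"
    radius_nm: float
    length_nm: float | None = None
    mass_per_nM: float | None = None  # ug/mL corresponding to 1 nM

    def __post_init__(self) -> None:
        if self.shape not in ("rod", "sphere"):
            raise ValueError(f"shape must be rod or sphere, got {self.shape!r}")
        if self.radius_nm <= 0:
            raise ValueError("radius must be > 0")
        if self.shape == "rod" and (self.length_nm is None or self.length_nm <= 0):
            raise ValueError("rods need a positive length")


def dose_convert(number_conc_nM: float, geom: ParticleGeometry) -> float:
    """Particle-number concentration (nM) to Au mass concentration
    (ug/mL) through the particle's mass factor."""
    if number_conc_nM < 0:
        raise ValueError("concentration must be >= 0")
    if geom.mass_per_nM is None or geom.mass_per_nM <= 0:
        raise ValueError("geometry lacks a positive mass_per_nM factor")
    return number_conc_nM * geom.mass_per_nM


def log2_dose(mass_ug_ml: float) -> float:
    """log2 dose axis used for plotting (defined for positive doses only)."""
    if mass_ug_ml <= 0:
        raise ValueError("log2 dose undefined for non-positive dose")
    return math.log2(mass_ug_ml)


def surface_to_volume(geom: ParticleGeometry) -> float:
    """Surface-area-to-volume ratio in nm^-1: 2(r + h)/(r h) for a
    flat-capped cylinder of radius r and length h, 3/r for a sphere."""
    r = geom.radius_nm
    if geom.shape == "sphere":
        return 3.0 / r
    h = geom.length_nm
    return 2.0 * (r + h) / (r * h)
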