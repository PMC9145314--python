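"""Nested exponential and Hill dose-response model families.

Two families of five nested members each, as used in benchmark-dose
practice for continuous toxicology endpoints:

Exponential family                 Hill family
  E1: y = a                          H1: y = a
  E2: y = a exp(b x)                 H2: y = a (1 - x/(b + x))
  E3: y = a exp(b x^d)               H3: y = a (1 - x^d/(b^d + x^d))
  E4: y = a [c - (c-1) exp(-b x)]    H4: y = a (1 + (c-1) x/(b + x))
  E5: y = a [c - (c-1) exp(-b x^d)]  H5: y = a (1 + (c-1) x^d/(b^d + x^d))

``a`` is the background response (the value at dose 0 for every member),
``b`` the potency/sensitivity parameter, ``c`` the asymptote factor
(levels 4-5 plateau at ``a*c`` for the exponential family), and ``d`` a
shape exponent.  The nesting lattice is 1 -> 2 -> {3, 4} -> 5: level 3 is
level 5 with c = 0, level 4 is level 5 with d = 1, and level 2 is level
3 or 4 with the extra parameter at its null value.  The sign of ``b`` is
left free in the exponential family so both decreasing (viability) and
increasing (cytokine) curves are reachable at every level; the Hill
``b`` is a dose-scale parameter and must be positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

FAMILIES = ("exponential", "hill")

#: free curve parameters per level (residual SD comes on top)
LEVEL_PARAMS = {
    1: ("a",),
    2: ("a", "b"),
    3: ("a", "b", "d"),
    4: ("a", "b", "c"),
    5: ("a", "b", "c", "d"),
}

#: direct-nesting relation used by the likelihood-ratio walk
NESTED_IN = {1: (2, 3, 4, 5), 2: (3, 4, 5), 3: (5,), 4: (5,)}

D_BOUNDS = (1.0, 4.0)
C_BOUNDS = (0.0, 20.0)


class ParameterizationError(ValueError):
    """A model parameter is missing or outside its admissible range."""


@dataclass
class ModelSpec:
    """One member of a nested dose-response family with its parameters."""

    family: str
    level: int
    a: float = 1.0
    b: float | None = None
    c: float | None = None
    d: float | None = None
    residual_sd: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterizationError(f"unknown family {self.family!r}")
        if self.level not in LEVEL_PARAMS:
            raise ParameterizationError(f"level must be 1-5, got {self.level}")
        for name in LEVEL_PARAMS[self.level]:
            if getattr(self, name) is None:
                raise ParameterizationError(
                    f"{self.name} requires parameter {name!r}"
                )
        if self.a <= 0:
            raise ParameterizationError("background a must be > 0")
        if self.family == "hill" and "b" in self.free_parameters and self.b <= 0:
            raise ParameterizationError("Hill b must be > 0")
        if "d" in self.free_parameters and self.d < 1.0:
            raise ParameterizationError("shape exponent d must be >= 1")
        if "c" in self.free_parameters and self.c < 0:
            raise ParameterizationError("asymptote factor c must be >= 0")

    @property
    def name(self) -> str:
        return ("E" if self.family == "exponential" else "H") + str(self.level)

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return LEVEL_PARAMS[self.level]

    @property
    def n_parameters(self) -> int:
        """Free parameters including the residual SD."""
        return len(self.free_parameters) + 1

    def with_parameters(self, **kwargs) -> "ModelSpec":
        return replace(self, **kwargs)


def eval_model(spec: ModelSpec, x) -> np.ndarray | float:
    """Mean response of the model at dose(s) ``x`` (every member returns
    ``a`` at x = 0)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("dose must be >= 0")
    a, b, c, d = spec.a, spec.b, spec.c, spec.d
    lvl = spec.level
    if spec.family == "exponential":
        with np.errstate(over="ignore"):  # extreme b during optimization
            if lvl == 1:
                y = np.full_like(x, a)
            elif lvl == 2:
                y = a * np.exp(b * x)
            elif lvl == 3:
                y = a * np.exp(b * x**d)
            elif lvl == 4:
                y = a * (c - (c - 1.0) * np.exp(-b * x))
            else:
                y = a * (c - (c - 1.0) * np.exp(-b * x**d))
    else:
        if lvl == 1:
            y = np.full_like(x, a)
        elif lvl == 2:
            y = a * (1.0 - x / (b + x))
        elif lvl == 3:
            y = a * (1.0 - x**d / (b**d + x**d))
        elif lvl == 4:
            y = a * (1.0 + (c - 1.0) * x / (b + x))
        else:
            y = a * (1.0 + (c - 1.0) * x**d / (b**d + x**d))
    return y if y.ndim else float(y)


def is_constant(spec: ModelSpec, tol: float = 1e-12) -> bool:
    """True when the member degenerates to the flat model y = a."""
    if spec.level == 1:
        return True
    if spec.family == "exponential":
        if spec.level in (2, 3):
            return abs(spec.b) < tol
        return abs(spec.c - 1.0) < tol or abs(spec.b) < tol
    if spec.level in (2, 3):
        return False  # Hill 2/3 always decrease for finite b
    return abs(spec.c - 1.0) < tol


def response_direction(spec: ModelSpec) -> int:
    """+1 for an increasing curve, -1 for decreasing (0 if flat)."""
    if is_constant(spec):
        return 0
    if spec.family == "exponential":
        if spec.level in (2, 3):
            return int(math.copysign(1, spec.b))
        # level 4/5: (y/a - 1) = (c-1)(1 - exp(-b x)); sign depends on b too
        return int(math.copysign(1, (spec.c - 1.0) * spec.b))
    if spec.level in (2, 3):
        return -1
    return int(math.copysign(1, spec.c - 1.0))


def bmd_closed_form(spec: ModelSpec, bmr: float) -> float:
    """Dose at which the mean response differs from background ``a`` by the
    fraction ``bmr``, in the curve's own direction.

    Every family member admits a closed form; raises ``ValueError`` when
    the curve plateaus before reaching the benchmark response.
    """
    if not 0 < bmr < 1:
        raise ValueError("bmr must be in (0, 1)")
    if is_constant(spec):
        raise ValueError("BMD undefined for a constant model")
    s = response_direction(spec)
    b, c, d = spec.b, spec.c, spec.d
    if spec.family == "exponential":
        if spec.level == 2:
            return math.log1p(s * bmr) / b
        if spec.level == 3:
            return (math.log1p(s * bmr) / b) ** (1.0 / d)
        # levels 4/5: exp(-b x^d) = 1 - s*bmr/(c-1)
        arg = 1.0 - s * bmr / (c - 1.0)
        if arg <= 0:
            raise ValueError(
                f"{spec.name} plateaus at a*c before the {bmr:.0%} benchmark response"
            )
        xd = -math.log(arg) / b
        if xd <= 0:
            raise ValueError("benchmark response not reached at a positive dose")
        return xd if spec.level == 4 else xd ** (1.0 / d)
    # Hill family: theta = x^d/(b^d + x^d) in [0, 1)
    if spec.level in (2, 3):
        theta = bmr
    else:
        theta = bmr / abs(c - 1.0)
        if theta >= 1.0:
            raise ValueError(
                f"{spec.name} plateaus before the {bmr:.0%} benchmark response"
            )
    ratio = theta / (1.0 - theta)
    if spec.level in (2, 4):
        return b * ratio
    return b * ratio ** (1.0 / d)


def b_from_bmd(spec: ModelSpec, bmd: float, bmr: float, direction: int) -> float:
    """Invert the closed-form BMD for ``b``: the value of ``b`` that places
    the benchmark dose at ``bmd`` given the member's other parameters.

    This is the reparameterization used by the profile-likelihood CI; the
    background ``a`` never enters because the benchmark response is
    relative.  Raises ``ValueError`` where no such ``b`` exists (the
    asymptote factor ``c`` caps the reachable response change).
    """
    if bmd <= 0:
        raise ValueError("bmd must be > 0")
    s = direction
    c, d = spec.c, spec.d
    if spec.family == "exponential":
        if spec.level == 2:
            return math.log1p(s * bmr) / bmd
        if spec.level == 3:
            return math.log1p(s * bmr) / bmd**d
        arg = 1.0 - s * bmr / (c - 1.0)
        if arg <= 0:
            raise ValueError("asymptote a*c caps the response below the BMR")
        xd = bmd if spec.level == 4 else bmd**d
        return -math.log(arg) / xd
    if spec.level in (2, 3):
        theta = bmr
    else:
        if abs(c - 1.0) <= bmr:
            raise ValueError("asymptote caps the Hill response below the BMR")
        theta = bmr / abs(c - 1.0)
    ratio = (1.0 - theta) / theta
    if spec.level in (2, 4):
        return bmd * ratio
    return bmd * ratio ** (1.0 / d)
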