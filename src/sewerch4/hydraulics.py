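"""Wall-shear stress in partly filled gravity sewers.

The tangential stress F (Pa) that flowing wastewater exerts on the
pipe-wall biofilm is described by a fitted second-order response surface
in three operating variables: the sewer slope I (per-mille, ‰), the
fullness degree n (fraction of the cross-section carrying wastewater)
and the mean flow velocity v (m/s).  The surface was calibrated on a
pilot gravity-sewer system; this module evaluates it, differentiates it,
and inverts it for velocity.

The slope enters the polynomial as the literal per-mille number (the
study's sewers ran at I = 8‰, i.e. I = 8).  Pass
``slope_as_fraction=True`` to supply the dimensionless gradient
(0.008) instead; it is multiplied by 1000 before evaluation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .exceptions import (
    CalibrationWarning,
    InvalidInputError,
    NoPhysicalSolutionError,
    NoSolutionError,
)

__all__ = [
    "SHEAR_COEFFS",
    "HydraulicState",
    "shear_stress",
    "shear_stress_gradient_v",
    "solve_velocity",
]

#: Coefficients of the response surface
#: F = c0 + cI*I + cn*n + cv*v + cnI*n*I + cvI*v*I + cnv*n*v
#:     + cII*I^2 + cnn*n^2 + cvv*v^2
SHEAR_COEFFS = {
    "c0": 0.21941,
    "cI": 0.44146,
    "cn": 1.73331,
    "cv": -0.52041,
    "cnI": 0.13167,
    "cvI": -0.24688,
    "cnv": -1.47281,
    "cII": 0.23833,
    "cnn": -0.12750,
    "cvv": 1.88828,
}

# Calibration envelope of the pilot system; outside it the polynomial is
# an extrapolation and a warning is emitted (never an error).
_ENVELOPE = {"slope": (0.0, 10.0), "fullness": (0.0, 1.0), "velocity": (0.0, 3.0)}


@dataclass(frozen=True)
class HydraulicState:
    """One sewer's flow condition.

    Parameters
    ----------
    slope : float
        Sewer slope I in ‰ (the per-mille number, e.g. 8 for 8‰).
    fullness : float
        Fullness degree n, fraction of wetted depth in [0, 1].
    velocity : float
        Mean flow velocity v in m/s, non-negative.
    """

    slope: float
    fullness: float
    velocity: float

    def __post_init__(self) -> None:
        for name, val in (
            ("slope", self.slope),
            ("fullness", self.fullness),
            ("velocity", self.velocity),
        ):
            if not math.isfinite(val):
                raise InvalidInputError(f"{name} must be finite, got {val!r}")
        if not 0.0 <= self.fullness <= 1.0:
            raise InvalidInputError(
                f"fullness degree must lie in [0, 1], got {self.fullness}"
            )
        if self.velocity < 0:
            raise InvalidInputError(f"velocity must be >= 0, got {self.velocity}")
        if self.slope < 0:
            raise InvalidInputError(f"slope must be >= 0, got {self.slope}")


def _check_envelope(I: float, n: float, v: float) -> None:
    for name, val in (("slope", I), ("fullness", n), ("velocity", v)):
        lo, hi = _ENVELOPE[name]
        if not lo <= val <= hi:
            warnings.warn(
                f"{name}={val} is outside the calibration envelope "
                f"[{lo}, {hi}]; the shear-stress surface is extrapolating",
                CalibrationWarning,
                stacklevel=3,
            )


def shear_stress(
    state: HydraulicState | None = None,
    *,
    slope: float | None = None,
    fullness: float | None = None,
    velocity: float | None = None,
    slope_as_fraction: bool = False,
) -> float:
    """Evaluate the wall-shear-stress response surface, in Pa.

    Accepts either a :class:`HydraulicState` or the three keyword
    arguments.  A negative evaluated stress is returned as-is with a
    :class:`~sewerch4.exceptions.ModelValidityWarning`-style caution
    (the surface is being used outside its calibration), never clamped.

    Examples
    --------
    >>> shear_stress(HydraulicState(slope=0, fullness=0, velocity=0))
    0.21941
    """
    if state is not None:
        I, n, v = state.slope, state.fullness, state.velocity
    else:
        if slope is None or fullness is None or velocity is None:
            raise InvalidInputError(
                "provide a HydraulicState or slope, fullness and velocity"
            )
        # route through the dataclass so invariants are enforced once
        st = HydraulicState(slope=slope, fullness=fullness, velocity=velocity)
        I, n, v = st.slope, st.fullness, st.velocity
    if slope_as_fraction:
        I = I * 1000.0
    _check_envelope(I, n, v)
    c = SHEAR_COEFFS
    F = (
        c["c0"]
        + c["cI"] * I
        + c["cn"] * n
        + c["cv"] * v
        + c["cnI"] * n * I
        + c["cvI"] * v * I
        + c["cnv"] * n * v
        + c["cII"] * I * I
        + c["cnn"] * n * n
        + c["cvv"] * v * v
    )
    if F < 0:
        warnings.warn(
            f"evaluated wall-shear stress is negative ({F:.5f} Pa); the "
            "response surface is outside its calibration range",
            CalibrationWarning,
            stacklevel=2,
        )
    return F


def shear_stress_gradient_v(
    slope: float, fullness: float, velocity: float
) -> float:
    """Partial derivative dF/dv of the response surface (Pa per m/s)."""
    c = SHEAR_COEFFS
    return (
        c["cv"]
        + c["cvI"] * slope
        + c["cnv"] * fullness
        + 2.0 * c["cvv"] * velocity
    )


def solve_velocity(
    target_F: float,
    slope: float,
    fullness: float,
    root_policy: str = "smaller",
    slope_as_fraction: bool = False,
) -> float:
    """Invert the response surface for velocity at fixed slope and fullness.

    The surface is quadratic in v, so at most two real roots exist.
    ``root_policy`` selects ``"smaller"`` (default) or ``"larger"`` when
    both roots are non-negative.

    Raises
    ------
    NoSolutionError
        If the discriminant is negative (target stress below the vertex).
    NoPhysicalSolutionError
        If both real roots are negative velocities.
    """
    if root_policy not in ("smaller", "larger"):
        raise InvalidInputError(f"unknown root_policy {root_policy!r}")
    if not math.isfinite(target_F):
        raise InvalidInputError(f"target shear stress must be finite, got {target_F!r}")
    I = slope * 1000.0 if slope_as_fraction else slope
    n = fullness
    if not math.isfinite(I) or not math.isfinite(n):
        raise InvalidInputError("slope and fullness must be finite")
    if not 0.0 <= n <= 1.0:
        raise InvalidInputError(f"fullness degree must lie in [0, 1], got {n}")
    if I < 0:
        raise InvalidInputError(f"slope must be >= 0, got {I}")

    c = SHEAR_COEFFS
    # a v^2 + b v + k = 0
    a = c["cvv"]
    b = c["cv"] + c["cvI"] * I + c["cnv"] * n
    k = (
        c["c0"]
        + c["cI"] * I
        + c["cn"] * n
        + c["cnI"] * n * I
        + c["cII"] * I * I
        + c["cnn"] * n * n
        - target_F
    )
    disc = b * b - 4.0 * a * k
    if disc < 0:
        raise NoSolutionError(
            f"no real velocity yields F={target_F} Pa at slope={I}‰, "
            f"fullness={n} (discriminant {disc:.3e} < 0)"
        )
    sq = math.sqrt(disc)
    roots = sorted(((-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)))
    # tiny negative from round-off counts as zero
    feasible = [max(r, 0.0) if r > -1e-12 else r for r in roots]
    feasible = [r for r in feasible if r >= 0.0]
    if not feasible:
        raise NoPhysicalSolutionError(
            f"both roots are negative velocities ({roots[0]:.4g}, {roots[1]:.4g}) "
            f"for F={target_F} Pa at slope={I}‰, fullness={n}"
        )
    return feasible[0] if root_policy == "smaller" else feasible[-1]
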