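"""Empirical methane-production models for sewers.

Three empirical forms are implemented:

* two legacy whole-sewer correlations that predict the dissolved CH4
  mass per unit wastewater volume (kg/m³) from the biofilm surface-area to
  volume ratio A/V and the retention time HRT — one without and one with
  the standard sanitary-engineering temperature correction θ^(T−20),
  θ = 1.05;
* the biomass-explicit chain for gravity sewers, in which the wall-shear
  stress F sets the microorganism amount through a concave quadratic

      X(F) = a·F² + b·F + c      (default a = −0.0485, b = 0.161,
                                  c = −0.0142; X in kg, F in Pa)

  and the daily methane production follows

      Q = Y · X · θ^(T−20) · HRT      [mg CH4 per L wastewater per day]

The yield Y is an effective fitted coefficient: with Q in mg/(L·day), X in
kg and HRT in hours, Y absorbs the per-litre and per-hour factors needed
to close the dimensions, and in practice only the composite c* =
Y·θ^(T−20)·HRT is identifiable from production data (see
:mod:`sewerch4.fitting`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .exceptions import InvalidBiomassError, InvalidInputError, ModelValidityWarning
from .hydraulics import HydraulicState, shear_stress

__all__ = [
    "BiomassCurveParams",
    "MethaneModelParams",
    "LegacyModelInput",
    "biomass_from_shear",
    "methane_q5",
    "methane_foley",
    "methane_chaosakul",
    "predict_chain",
    "kg_per_m3_to_mg_per_l",
    "mg_per_l_to_kg_per_m3",
]


@dataclass(frozen=True)
class BiomassCurveParams:
    """Coefficients of the concave biomass-vs-shear quadratic X(F)."""

    a: float = -0.0485
    b: float = 0.161
    c: float = -0.0142

    def __post_init__(self) -> None:
        if self.a >= 0:
            warnings.warn(
                f"a = {self.a} >= 0: the biomass curve is not concave and has "
                "no interior optimum",
                ModelValidityWarning,
                stacklevel=3,
            )

    @property
    def optimum_shear(self) -> float:
        """Shear stress maximizing X, the vertex −b/(2a), in Pa."""
        return -self.b / (2.0 * self.a)

    def validity_range(self) -> tuple[float, float]:
        """Roots of X(F) = 0 — outside them the quadratic goes negative."""
        disc = self.b * self.b - 4.0 * self.a * self.c
        if disc < 0:
            return (math.nan, math.nan)
        sq = math.sqrt(disc)
        r1 = (-self.b + sq) / (2.0 * self.a)
        r2 = (-self.b - sq) / (2.0 * self.a)
        return (min(r1, r2), max(r1, r2))


@dataclass(frozen=True)
class MethaneModelParams:
    """Parameters of the biomass-explicit methane production model.

    yield_Y is the effective yield coefficient (see module docstring);
    theta the dimensionless temperature base (default 1.05); T the
    wastewater temperature in °C; HRT the retention time in hours.
    """

    yield_Y: float
    theta: float = 1.05
    T: float = 20.0
    HRT: float = 1.0

    def __post_init__(self) -> None:
        if self.yield_Y < 0:
            raise InvalidInputError(f"yield_Y must be >= 0, got {self.yield_Y}")
        if self.theta <= 0:
            raise InvalidInputError(f"theta must be > 0, got {self.theta}")
        if self.HRT < 0:
            raise InvalidInputError(f"HRT must be >= 0, got {self.HRT}")

    @property
    def composite_coeff(self) -> float:
        """c* = Y·θ^(T−20)·HRT, the identifiable proportionality Q/X."""
        return self.yield_Y * self.theta ** (self.T - 20.0) * self.HRT


@dataclass(frozen=True)
class LegacyModelInput:
    """Inputs of the legacy whole-sewer correlations."""

    A_over_V: float  # biofilm surface area per wastewater volume, 1/m
    HRT: float  # h
    T: float = 20.0  # °C, used by the temperature-corrected form only

    def __post_init__(self) -> None:
        if self.A_over_V < 0 or self.HRT < 0:
            raise InvalidInputError("A_over_V and HRT must be >= 0")


def biomass_from_shear(
    F: float, params: BiomassCurveParams | None = None
) -> float:
    """Microorganism amount X (kg) at wall-shear stress ``F`` (Pa).

    Evaluates the quadratic a·F² + b·F + c.  Negative results are returned
    as-is with a :class:`ModelValidityWarning` — at the default
    coefficients the curve is positive only for F roughly in
    [0.09, 3.23] Pa.
    """
    if params is None:
        params = BiomassCurveParams()
    if not math.isfinite(F):
        raise InvalidInputError(f"shear stress must be finite, got {F!r}")
    X = params.a * F * F + params.b * F + params.c
    if X < 0:
        lo, hi = params.validity_range()
        warnings.warn(
            f"biomass quadratic is negative ({X:.4g} kg) at F = {F} Pa; the "
            f"model is valid only for F in [{lo:.2f}, {hi:.2f}] Pa",
            ModelValidityWarning,
            stacklevel=2,
        )
    return X


def methane_q5(X: float, params: MethaneModelParams) -> float:
    """Daily methane production Q = Y·X·θ^(T−20)·HRT, mg/(L wastewater·day)."""
    if X < 0:
        raise InvalidBiomassError(
            f"microorganism amount must be >= 0, got {X} kg"
        )
    return params.yield_Y * X * params.theta ** (params.T - 20.0) * params.HRT


def methane_foley(inp: LegacyModelInput) -> float:
    """Legacy rising-main correlation: C = 5.24e−5·(A/V·HRT) + 0.0015 kg/m³."""
    return 5.24e-5 * (inp.A_over_V * inp.HRT) + 0.0015


def methane_chaosakul(inp: LegacyModelInput) -> float:
    """Temperature-corrected legacy correlation for gravity sewers.

    C = 6e−5 · 1.05^(T−20) · (A/V·HRT) + 0.0015, kg CH4 per m³ wastewater.
    """
    return 6e-5 * 1.05 ** (inp.T - 20.0) * (inp.A_over_V * inp.HRT) + 0.0015


def kg_per_m3_to_mg_per_l(c: float) -> float:
    """kg/m³ → mg/L (×1000) for cross-model comparison."""
    return c * 1000.0


def mg_per_l_to_kg_per_m3(c: float) -> float:
    """mg/L → kg/m³ (÷1000)."""
    return c / 1000.0


def predict_chain(
    state: HydraulicState | None = None,
    *,
    F: float | None = None,
    biomass_params: BiomassCurveParams | None = None,
    methane_params: MethaneModelParams,
    clamp_negative_biomass: bool = False,
) -> dict:
    """Full hydraulics → biomass → methane prediction.

    Either a :class:`HydraulicState` (shear stress is computed from it) or
    the shear stress ``F`` directly must be supplied.  Returns a dict with
    the three stage outputs ``{"F": Pa, "X": kg, "Q": mg/(L·day)}``.

    A negative biomass raises :class:`InvalidBiomassError` unless
    ``clamp_negative_biomass`` is set, in which case X is clamped to 0
    (and Q = 0) with a warning.
    """
    if (state is None) == (F is None):
        raise InvalidInputError("supply exactly one of state or F")
    if state is not None:
        F = shear_stress(state)
    assert F is not None
    X = biomass_from_shear(F, biomass_params)
    if X < 0:
        if clamp_negative_biomass:
            warnings.warn(
                f"clamping negative biomass ({X:.4g} kg) to 0 at F = {F:.3g} Pa",
                ModelValidityWarning,
                stacklevel=2,
            )
            X = 0.0
        else:
            raise InvalidBiomassError(
                f"biomass quadratic is negative ({X:.4g} kg) at F = {F:.3g} Pa; "
                "outside the model's validity range"
            )
    Q = methane_q5(X, methane_params)
    return {"F": float(F), "X": float(X), "Q": float(Q)}
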