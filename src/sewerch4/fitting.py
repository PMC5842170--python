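"""Model fitting and validation statistics.

Two fitted forms link wall-shear stress F to the measured quantities:

* ``QuadraticBiomassModel`` — ordinary least squares for the concave
  biomass curve X(F) = a·F² + b·F + c;
* ``ProportionalMethaneModel`` — the one-parameter through-origin fit of
  the daily methane rate to the biomass curve, Q = c*·X(F), whose
  closed-form solution is c* = ΣXQ / ΣX².

Both are statsmodels-style: construct the model from data, call
:meth:`fit`, and read estimates, standard errors, R² and the
percent-difference validation band off the returned Results object.

Because the experiment's temperature and retention time are not
separately observable from production data, the proportionality
c* = Y·θ^(T−20)·HRT — not the yield Y alone — is the primary estimand;
:meth:`ProportionalMethaneResults.yield_coefficient` decomposes it when
T and HRT are known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DegenerateFitError, InvalidBiomassError, InvalidInputError
from .methane import BiomassCurveParams

__all__ = [
    "PairedSeries",
    "QuadraticBiomassModel",
    "QuadraticBiomassResults",
    "ProportionalMethaneModel",
    "ProportionalMethaneResults",
    "fit_quadratic",
    "fit_proportional",
    "r_squared",
    "pct_diff_range",
]


@dataclass(frozen=True)
class PairedSeries:
    """Matched (shear stress, response) observations across sewers."""

    f_values: tuple[float, ...]
    y_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.f_values) != len(self.y_values):
            raise InvalidInputError("f_values and y_values must be equal length")
        if len(self.f_values) < 1:
            raise InvalidInputError("need at least one (F, y) pair")

    @classmethod
    def from_arrays(cls, f, y) -> "PairedSeries":
        return cls(tuple(float(v) for v in f), tuple(float(v) for v in y))

    @property
    def f(self) -> np.ndarray:
        return np.asarray(self.f_values, dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.y_values, dtype=float)


# ---------------------------------------------------------------------------
# validation statistics


def r_squared(obs, pred, centering: str = "centered") -> float:
    """Coefficient of determination.

    ``centered``: 1 − Σ(o−p)²/Σ(o−ō)²;  ``uncentered``: 1 − Σ(o−p)²/Σo².
    Returns NaN when the denominator is zero (undefined).
    """
    if centering not in ("centered", "uncentered"):
        raise InvalidInputError(
            f"centering must be 'centered' or 'uncentered', got {centering!r}"
        )
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape:
        raise InvalidInputError("obs and pred must have the same length")
    if o.size < 2:
        raise InvalidInputError("need at least 2 observations")
    ss_res = float(np.sum((o - p) ** 2))
    ss_tot = float(np.sum((o - o.mean()) ** 2) if centering == "centered"
                   else np.sum(o ** 2))
    if ss_tot == 0.0:
        return math.nan
    return 1.0 - ss_res / ss_tot


def pct_diff_range(obs, pred) -> tuple[float, float]:
    """(min, max) of the per-point percent difference 100·|obs − pred|/obs.

    The difference is referenced to the measurement, matching how model
    validation against held-out observations is usually reported.
    """
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape:
        raise InvalidInputError("obs and pred must have the same length")
    if o.size == 0:
        raise InvalidInputError("need at least one observation")
    if np.any(o == 0):
        raise InvalidInputError("percent difference undefined for zero observations")
    d = 100.0 * np.abs(o - p) / np.abs(o)
    return float(d.min()), float(d.max())


def _summary_table(title: str, rows: list[tuple[str, str]]) -> str:
    width = max(len(k) for k, _ in rows)
    lines = [title, "=" * len(title)]
    lines += [f"{k:<{width}}  {v}" for k, v in rows]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# quadratic biomass model


class QuadraticBiomassModel:
    """OLS model X = a·F² + b·F + c for biomass vs wall-shear stress.

    Parameters
    ----------
    shear : array-like
        Wall-shear stresses, Pa (at least 3 distinct values).
    biomass : array-like
        Observed microorganism amounts, kg (same length).
    """

    def __init__(self, shear, biomass) -> None:
        self.data = PairedSeries.from_arrays(shear, biomass)
        if len(self.data.f_values) < 3:
            raise InvalidInputError("quadratic fit needs at least 3 observations")
        if len(set(self.data.f_values)) < 3:
            raise DegenerateFitError(
                "quadratic fit needs at least 3 distinct shear values, got "
                f"{sorted(set(self.data.f_values))}"
            )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, shear_col: str = "shear_pa",
        y_col: str = "biomass_kg",
    ) -> "QuadraticBiomassModel":
        return cls(df[shear_col].to_numpy(), df[y_col].to_numpy())

    def fit(self) -> "QuadraticBiomassResults":
        F = self.data.f
        y = self.data.y
        design = np.column_stack([F ** 2, F, np.ones_like(F)])
        res = sm.OLS(y, design).fit()
        a, b, c = (float(v) for v in res.params)
        fitted = design @ res.params
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        # zero total variance (constant response): R² is 0 by convention
        r2 = r_squared(y, fitted) if ss_tot > 0 else 0.0
        return QuadraticBiomassResults(
            model=self,
            params=BiomassCurveParams(a=a, b=b, c=c),
            bse=tuple(float(v) for v in res.bse),
            fittedvalues=fitted,
            r_squared=float(r2),
        )


@dataclass
class QuadraticBiomassResults:
    """Fit results for the biomass quadratic."""

    model: QuadraticBiomassModel
    params: BiomassCurveParams
    bse: tuple[float, float, float]
    fittedvalues: np.ndarray
    r_squared: float

    @property
    def residuals(self) -> np.ndarray:
        return self.model.data.y - self.fittedvalues

    @property
    def pct_diff_range(self) -> tuple[float, float]:
        return pct_diff_range(self.model.data.y, self.fittedvalues)

    def predict(self, shear) -> np.ndarray:
        F = np.asarray(shear, dtype=float)
        return self.params.a * F ** 2 + self.params.b * F + self.params.c

    def summary(self) -> str:
        p, se = self.params, self.bse
        rows = [
            ("a (F², kg/Pa²)", f"{p.a:.5f} (se {se[0]:.5f})"),
            ("b (F, kg/Pa)", f"{p.b:.5f} (se {se[1]:.5f})"),
            ("c (const, kg)", f"{p.c:.5f} (se {se[2]:.5f})"),
            ("optimum shear (Pa)", f"{p.optimum_shear:.4f}"),
            ("R² (centered)", f"{self.r_squared:.4f}"),
            ("n", f"{len(self.model.data.f_values)}"),
        ]
        return _summary_table("Quadratic biomass model  X(F) = a·F² + b·F + c", rows)

    def plot_fit(self, ax=None):
        """Observed points and fitted curve on a shear-stress axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        F = self.model.data.f
        grid = np.linspace(F.min(), F.max(), 200)
        ax.plot(F, self.model.data.y, "o", label="observed")
        ax.plot(grid, self.predict(grid), "-", label="fit")
        ax.set_xlabel("wall-shear stress F (Pa)")
        ax.set_ylabel("microorganism amount X (kg)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# proportional methane model


class ProportionalMethaneModel:
    """Through-origin model Q = c*·X(F) for methane rate vs shear stress.

    X(F) comes from a fixed biomass quadratic (default: the published
    coefficients); only the proportionality c* is estimated, by least
    squares through the origin.
    """

    def __init__(self, shear, methane, biomass_params: BiomassCurveParams | None = None) -> None:
        self.data = PairedSeries.from_arrays(shear, methane)
        self.biomass_params = biomass_params or BiomassCurveParams()
        p = self.biomass_params
        X = p.a * self.data.f ** 2 + p.b * self.data.f + p.c
        if np.all(X <= 0):
            raise InvalidBiomassError(
                "biomass curve is non-positive at every supplied shear stress"
            )
        self.biomass = X

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, shear_col: str = "shear_pa",
        q_col: str = "methane_mg_l_day",
        biomass_params: BiomassCurveParams | None = None,
    ) -> "ProportionalMethaneModel":
        return cls(df[shear_col].to_numpy(), df[q_col].to_numpy(), biomass_params)

    def fit(self, centering: str = "centered") -> "ProportionalMethaneResults":
        X = self.biomass
        Q = self.data.y
        cstar = float(np.sum(X * Q) / np.sum(X * X))
        fitted = cstar * X
        n = len(Q)
        if n >= 2:
            r2 = r_squared(Q, fitted, centering=centering)
            sigma2 = float(np.sum((Q - fitted) ** 2)) / (n - 1)
            se = math.sqrt(sigma2 / float(np.sum(X * X)))
        else:
            r2 = math.nan  # undefined for a single pair
            se = math.nan
        return ProportionalMethaneResults(
            model=self,
            cstar=cstar,
            bse=se,
            fittedvalues=fitted,
            r_squared=float(r2),
            centering=centering,
        )


@dataclass
class ProportionalMethaneResults:
    """Fit results for the through-origin methane model."""

    model: ProportionalMethaneModel
    cstar: float
    bse: float
    fittedvalues: np.ndarray
    r_squared: float
    centering: str = "centered"

    @property
    def residuals(self) -> np.ndarray:
        return self.model.data.y - self.fittedvalues

    @property
    def pct_diff_range(self) -> tuple[float, float]:
        return pct_diff_range(self.model.data.y, self.fittedvalues)

    def yield_coefficient(self, T: float, HRT: float, theta: float = 1.05) -> float:
        """Recover Y = c*/(θ^(T−20)·HRT) when T (°C) and HRT (h) are known."""
        if HRT <= 0:
            raise InvalidInputError("HRT must be > 0 to recover the yield")
        return self.cstar / (theta ** (T - 20.0) * HRT)

    def predict(self, shear) -> np.ndarray:
        F = np.asarray(shear, dtype=float)
        p = self.model.biomass_params
        return self.cstar * (p.a * F ** 2 + p.b * F + p.c)

    def validate(self, shear, methane) -> dict:
        """Validation statistics of this fit against held-out observations.

        Returns R² (same centering as the fit), the percent-difference
        range, and the residual table.
        """
        F = np.asarray(shear, dtype=float)
        Q = np.asarray(methane, dtype=float)
        pred = self.predict(F)
        return {
            "r_squared": r_squared(Q, pred, centering=self.centering),
            "pct_diff_range": pct_diff_range(Q, pred),
            "residuals": pd.DataFrame(
                {"shear_pa": F, "observed": Q, "predicted": pred,
                 "residual": Q - pred}
            ),
        }

    def summary(self) -> str:
        lo, hi = self.pct_diff_range
        rows = [
            ("c* = Y·θ^(T−20)·HRT", f"{self.cstar:.4f} (se {self.bse:.4f})"),
            (f"R² ({self.centering})", f"{self.r_squared:.4f}"),
            ("pct diff range (%)", f"{lo:.1f} – {hi:.1f}"),
            ("n", f"{len(self.model.data.f_values)}"),
        ]
        return _summary_table("Proportional methane model  Q = c*·X(F)", rows)

    def plot_fit(self, ax=None):
        """Observed rates and fitted curve on a shear-stress axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        F = self.model.data.f
        grid = np.linspace(F.min(), F.max(), 200)
        ax.plot(F, self.model.data.y, "o", label="observed")
        ax.plot(grid, self.predict(grid), "-", label="fit")
        ax.set_xlabel("wall-shear stress F (Pa)")
        ax.set_ylabel("methane production Q (mg L⁻¹ d⁻¹)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# functional wrappers


def fit_quadratic(data: PairedSeries | Sequence | None = None, *, shear=None,
                  biomass=None) -> QuadraticBiomassResults:
    """Fit the biomass quadratic; thin wrapper over QuadraticBiomassModel."""
    if isinstance(data, PairedSeries):
        shear, biomass = data.f, data.y
    elif data is not None:
        shear, biomass = zip(*data)
    return QuadraticBiomassModel(shear, biomass).fit()


def fit_proportional(
    data: PairedSeries | Sequence | None = None, *, shear=None, methane=None,
    biomass_params: BiomassCurveParams | None = None,
    centering: str = "centered",
) -> ProportionalMethaneResults:
    """Fit the through-origin methane model; wrapper over ProportionalMethaneModel."""
    if isinstance(data, PairedSeries):
        shear, methane = data.f, data.y
    elif data is not None:
        shear, methane = zip(*data)
    return ProportionalMethaneModel(shear, methane, biomass_params).fit(
        centering=centering
    )
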