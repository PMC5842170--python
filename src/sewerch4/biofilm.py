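"""Reduction of raw sewer-biofilm measurements.

Three measured quantities feed the methane model chain:

* thickness time series (mm, mean of nine points per chip) -> the day the
  biofilm matures, i.e. growth and sloughing reach equilibrium;
* dissolved-oxygen microprofiles (mg/L vs depth, 100-µm steps) -> the
  oxygen penetration depth delimiting the aerobic layer;
* density, mature thickness, wetted area and EPS -> the microorganism
  amount X (kg), the TS-based biomass with the non-cellular EPS matrix
  removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InconsistentEPSError, InvalidInputError

__all__ = [
    "ThicknessRecord",
    "ThicknessSeries",
    "DOProfile",
    "BiofilmState",
    "NOT_MATURE",
    "NOT_REACHED",
    "maturity_day",
    "penetration_depth",
    "microorganism_amount",
    "read_thickness_csv",
    "read_do_profiles_csv",
    "read_biofilm_state_csv",
]

#: Sentinel returned by :func:`maturity_day` when the series never stabilizes.
NOT_MATURE = None
#: Sentinel returned by :func:`penetration_depth` when DO never reaches the
#: threshold.
NOT_REACHED = None


@dataclass(frozen=True)
class ThicknessRecord:
    day: int
    mean_thickness: float  # mm
    point_thicknesses: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.day < 0:
            raise InvalidInputError(f"day must be >= 0, got {self.day}")
        if self.mean_thickness < 0:
            raise InvalidInputError("thickness must be >= 0")


@dataclass(frozen=True)
class ThicknessSeries:
    """Biofilm thickness over time for one sewer.

    ``mean_thickness`` is the plain arithmetic mean of the per-chip point
    readings (nine typical points per chip) when points are present.
    """

    sewer_id: str
    records: tuple[ThicknessRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        days = [r.day for r in self.records]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise InvalidInputError(
                f"days must be strictly increasing, got {days}"
            )
        for r in self.records:
            if r.point_thicknesses:
                m = float(np.mean(r.point_thicknesses))
                if not math.isclose(m, r.mean_thickness, rel_tol=1e-9, abs_tol=1e-9):
                    raise InvalidInputError(
                        f"day {r.day}: mean_thickness {r.mean_thickness} does not "
                        f"equal the mean of the point readings ({m})"
                    )

    @classmethod
    def from_points(
        cls, sewer_id: str, days: Sequence[int], points: Sequence[Sequence[float]]
    ) -> "ThicknessSeries":
        recs = tuple(
            ThicknessRecord(
                day=int(d),
                mean_thickness=float(np.mean(p)),
                point_thicknesses=tuple(float(x) for x in p),
            )
            for d, p in zip(days, points)
        )
        return cls(sewer_id=sewer_id, records=recs)

    @classmethod
    def from_means(
        cls, sewer_id: str, days: Sequence[int], means: Sequence[float]
    ) -> "ThicknessSeries":
        recs = tuple(
            ThicknessRecord(day=int(d), mean_thickness=float(m))
            for d, m in zip(days, means)
        )
        return cls(sewer_id=sewer_id, records=recs)

    @property
    def days(self) -> np.ndarray:
        return np.array([r.day for r in self.records])

    @property
    def means(self) -> np.ndarray:
        return np.array([r.mean_thickness for r in self.records])


@dataclass(frozen=True)
class DOProfile:
    """Dissolved-oxygen microprofile through a biofilm.

    Depths are µm below the biofilm surface, strictly increasing, nominally
    on a 100-µm grid; concentrations are mg/L, non-negative.
    """

    depths: tuple[float, ...]
    do_conc: tuple[float, ...]
    sewer_id: str = ""

    def __post_init__(self) -> None:
        if len(self.depths) != len(self.do_conc):
            raise InvalidInputError("depths and do_conc must have equal length")
        d = self.depths
        if any(b <= a for a, b in zip(d, d[1:])):
            raise InvalidInputError("depths must be strictly increasing")
        if any(c < 0 for c in self.do_conc):
            raise InvalidInputError("DO concentrations must be >= 0")

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[float, float]], sewer_id: str = ""
    ) -> "DOProfile":
        return cls(
            depths=tuple(p[0] for p in pairs),
            do_conc=tuple(p[1] for p in pairs),
            sewer_id=sewer_id,
        )


@dataclass(frozen=True)
class BiofilmState:
    """Mature-biofilm bulk quantities for the microorganism-amount formula.

    Parameters
    ----------
    density : float
        Mean TS-based biomass density ρ, kg/m³.
    thickness : float
        Mean mature biofilm thickness δ, mm.
    area : float
        Wetted biofilm-growth surface area A, m².
    eps_mass : float, optional
        EPS mass to subtract, kg.  Mutually exclusive with ``eps_fraction``.
    eps_fraction : float, optional
        EPS as a fraction of TS mass, in [0, 1).
    """

    density: float
    thickness: float
    area: float
    eps_mass: float = 0.0
    eps_fraction: float | None = None

    def __post_init__(self) -> None:
        for name, val in (
            ("density", self.density),
            ("thickness", self.thickness),
            ("area", self.area),
            ("eps_mass", self.eps_mass),
        ):
            if val < 0:
                raise InvalidInputError(f"{name} must be >= 0, got {val}")
        if self.eps_fraction is not None:
            if not 0.0 <= self.eps_fraction < 1.0:
                raise InvalidInputError(
                    f"eps_fraction must lie in [0, 1), got {self.eps_fraction}"
                )
            if self.eps_mass:
                raise InvalidInputError(
                    "supply eps_mass or eps_fraction, not both"
                )


def maturity_day(
    series: ThicknessSeries, window: float = 10.0, rel_tol: float = 0.05
):
    """Earliest observation day from which the thickness is stable.

    The biofilm is considered mature from day ``d`` when, over the window
    ``[d, d + window]``, every mean thickness deviates from the window mean
    by at most ``rel_tol`` (growth and sloughing in equilibrium).  Returns
    :data:`NOT_MATURE` (``None``) if no such day exists.

    The default 10-day window and 5% tolerance reproduce a ~45-day
    maturation on the package's default synthetic growth curves.
    """
    if len(series.records) < 3:
        raise InvalidInputError("need at least 3 thickness records")
    days = series.days
    means = series.means
    for i, d in enumerate(days):
        mask = (days >= d) & (days <= d + window)
        w = means[mask]
        if len(w) < 2:
            continue
        wmean = w.mean()
        if wmean == 0:
            if np.all(w == 0):
                return int(d)
            continue
        if np.all(np.abs(w - wmean) <= rel_tol * wmean):
            return int(d)
    return NOT_MATURE


def penetration_depth(
    profile: DOProfile, threshold: float = 0.0, atol: float = 0.05
):
    """Depth (µm) at which dissolved oxygen first falls to ``threshold``.

    Finds the shallowest record with DO <= ``threshold + atol`` and linearly
    interpolates between it and the previous record to the exact threshold
    crossing.  Returns :data:`NOT_REACHED` (``None``) when the profile never
    reaches the threshold.
    """
    if len(profile.depths) == 0:
        raise InvalidInputError("empty DO profile")
    depths = np.asarray(profile.depths, dtype=float)
    conc = np.asarray(profile.do_conc, dtype=float)
    hit = np.nonzero(conc <= threshold + atol)[0]
    if len(hit) == 0:
        return NOT_REACHED
    i = int(hit[0])
    if i == 0:
        return float(depths[0])
    d0, d1 = depths[i - 1], depths[i]
    c0, c1 = conc[i - 1], conc[i]
    if c0 == c1 or c0 <= threshold:
        return float(d1 if c0 > threshold else d0)
    # linear crossing of the threshold between the bracketing records
    t = (c0 - threshold) / (c0 - c1)
    t = min(max(t, 0.0), 1.0)
    return float(d0 + t * (d1 - d0))


def microorganism_amount(state: BiofilmState) -> float:
    """Microorganism amount X in kg.

    X = ρ · δ · A − EPS, with δ converted from mm to m; equivalently
    X = ρ·δ·A·(1 − eps_fraction) when EPS is given as a fraction of TS.
    The TS mass with EPS removed represents the microorganisms themselves.
    """
    gross = state.density * (state.thickness * 1e-3) * state.area
    if state.eps_fraction is not None:
        return gross * (1.0 - state.eps_fraction)
    if state.eps_mass > gross * (1.0 + 1e-12):
        raise InconsistentEPSError(
            f"EPS mass {state.eps_mass} kg exceeds total biofilm mass "
            f"{gross:.6g} kg"
        )
    return max(gross - state.eps_mass, 0.0)


# ---------------------------------------------------------------------------
# CSV readers

def read_thickness_csv(path) -> dict[str, ThicknessSeries]:
    """Read thickness series from CSV.

    Expected columns: ``sewer_id``, ``day``, and either ``point_1..point_9``
    or ``mean_mm``.  Returns one series per sewer.
    """
    df = pd.read_csv(path)
    point_cols = [c for c in df.columns if c.startswith("point_")]
    out: dict[str, ThicknessSeries] = {}
    for sid, grp in df.groupby("sewer_id", sort=False):
        grp = grp.sort_values("day")
        if point_cols:
            out[str(sid)] = ThicknessSeries.from_points(
                str(sid), grp["day"].tolist(), grp[point_cols].to_numpy()
            )
        else:
            out[str(sid)] = ThicknessSeries.from_means(
                str(sid), grp["day"].tolist(), grp["mean_mm"].tolist()
            )
    return out


def read_do_profiles_csv(path) -> dict[str, DOProfile]:
    """Read DO microprofiles from CSV with columns sewer_id, depth_um, do_mg_l."""
    df = pd.read_csv(path)
    out: dict[str, DOProfile] = {}
    for sid, grp in df.groupby("sewer_id", sort=False):
        grp = grp.sort_values("depth_um")
        out[str(sid)] = DOProfile(
            depths=tuple(grp["depth_um"].astype(float)),
            do_conc=tuple(grp["do_mg_l"].astype(float)),
            sewer_id=str(sid),
        )
    return out


def read_biofilm_state_csv(path) -> dict[str, BiofilmState]:
    """Read bulk biofilm states from CSV.

    Columns: sewer_id, density_kg_m3, thickness_mm, area_m2 and optionally
    eps_kg or eps_fraction.
    """
    df = pd.read_csv(path)
    out: dict[str, BiofilmState] = {}
    for _, row in df.iterrows():
        kwargs = dict(
            density=float(row["density_kg_m3"]),
            thickness=float(row["thickness_mm"]),
            area=float(row["area_m2"]),
        )
        if "eps_kg" in row and not pd.isna(row.get("eps_kg")):
            kwargs["eps_mass"] = float(row["eps_kg"])
        if "eps_fraction" in row and not pd.isna(row.get("eps_fraction")):
            kwargs["eps_fraction"] = float(row["eps_fraction"])
        out[str(row["sewer_id"])] = BiofilmState(**kwargs)
    return out
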