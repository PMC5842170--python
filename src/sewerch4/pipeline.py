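"""End-to-end analysis of a seven-sewer experiment bundle.

Reads the observation tables written by :func:`sewerch4.simulate.gen_experiment`
(or real data in the same schema), reduces them per sewer — maturity day,
mature thickness, mean mature density, oxygen penetration depth,
microorganism amount — and fits the biomass quadratic and the proportional
methane model.  The truth file of a synthetic bundle is never consulted:
the fit is blind.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .biofilm import (
    BiofilmState,
    DOProfile,
    ThicknessSeries,
    maturity_day,
    microorganism_amount,
    penetration_depth,
    read_do_profiles_csv,
    read_thickness_csv,
)
from .exceptions import InvalidInputError
from .fitting import (
    ProportionalMethaneResults,
    QuadraticBiomassResults,
    fit_proportional,
    fit_quadratic,
)

__all__ = ["SewerSummary", "ExperimentAnalysis", "analyze_experiment",
           "mature_thickness"]

#: Density records earlier than this are still in the colonisation ramp and
#: are excluded from the mature-density average.
DENSITY_STABLE_FROM_DAY = 10


def mature_thickness(series: ThicknessSeries, window: float = 10.0,
                     rel_tol: float = 0.05) -> tuple[int | None, float]:
    """(maturity day, mature thickness in mm) for one sewer.

    The mature thickness is the median of the record means from the
    maturity day onwards — the median resists contamination when the
    stability criterion fires a little early on a noisy series.  Falls
    back to the median of the last three records if the series never
    stabilizes.
    """
    m = maturity_day(series, window=window, rel_tol=rel_tol)
    means = series.means
    if m is None:
        return None, float(np.median(means[-3:]))
    return m, float(np.median(means[series.days >= m]))


@dataclass
class SewerSummary:
    """Reduced observables for one sewer."""

    sewer_id: str
    shear_pa: float
    maturity_day: int | None
    thickness_mm: float
    density_kg_m3: float
    do_penetration_um: float | None
    biomass_kg: float
    methane_mg_l_day: float


@dataclass
class ExperimentAnalysis:
    """Per-sewer summaries plus the two model fits."""

    sewers: pd.DataFrame
    biomass_fit: QuadraticBiomassResults
    methane_fit: ProportionalMethaneResults

    def summary(self) -> str:
        parts = [
            self.sewers.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
            self.biomass_fit.summary(),
            "",
            self.methane_fit.summary(),
        ]
        return "\n".join(parts)


def analyze_experiment(path, window: float = 10.0, rel_tol: float = 0.05
                       ) -> ExperimentAnalysis:
    """Reduce and fit one experiment directory.

    Expects thickness.csv, density.csv, do_profiles.csv, methane.csv and
    sewers.csv in the schemas the generator writes.
    """
    p = Path(path)
    sewers = pd.read_csv(p / "sewers.csv")
    thickness = read_thickness_csv(p / "thickness.csv")
    density = pd.read_csv(p / "density.csv")
    profiles = read_do_profiles_csv(p / "do_profiles.csv")
    methane = pd.read_csv(p / "methane.csv")

    rows: list[SewerSummary] = []
    for _, s in sewers.iterrows():
        sid = str(s["sewer_id"])
        if sid not in thickness:
            raise InvalidInputError(f"no thickness series for sewer {sid!r}")
        mday, delta = mature_thickness(thickness[sid], window=window,
                                       rel_tol=rel_tol)
        dens = density.loc[
            (density["sewer_id"] == sid)
            & (density["day"] >= DENSITY_STABLE_FROM_DAY),
            "density_kg_m3",
        ]
        rho = float(dens.mean())
        prof: DOProfile | None = profiles.get(sid)
        depth = penetration_depth(prof) if prof is not None else None
        X = microorganism_amount(BiofilmState(
            density=rho, thickness=delta, area=float(s["area_m2"]),
            eps_fraction=float(s.get("eps_fraction", 0.0)),
        ))
        q = float(methane.loc[methane["sewer_id"] == sid,
                              "methane_mg_l_day"].mean())
        rows.append(SewerSummary(
            sewer_id=sid, shear_pa=float(s["shear_pa"]), maturity_day=mday,
            thickness_mm=delta, density_kg_m3=rho, do_penetration_um=depth,
            biomass_kg=X, methane_mg_l_day=q,
        ))

    df = pd.DataFrame([r.__dict__ for r in rows])
    biomass_fit = fit_quadratic(shear=df["shear_pa"], biomass=df["biomass_kg"])
    methane_fit = fit_proportional(shear=df["shear_pa"],
                                   methane=df["methane_mg_l_day"])
    return ExperimentAnalysis(sewers=df, biomass_fit=biomass_fit,
                              methane_fit=methane_fit)
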