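"""Virtual seven-sewer experiments.

Generates complete synthetic datasets with the statistical structure the
analysis chain assumes — seven parallel gravity sewers at fixed wall-shear
stresses, each yielding a biofilm thickness time series (nine jittered
points per chip every 5 days), a biomass-density time series, a
dissolved-oxygen microprofile through the mature biofilm, six days of
daily methane rates, and an archaeal community column — so that every
pipeline stage (data reduction, model fitting, validation) is testable
end to end with known ground truth.

Deterministic skeletons follow the published anchors: mature thickness
2.4/2.7/2.2 mm and density 51/62/80 kg/m³ at 0.8/1.29/2.0 Pa, oxygen
penetration 2050/1850/1450 µm, methane Q = c*·X(F) with the published
biomass quadratic.  Noise is Gaussian (relative for methane, absolute for
thickness points, density records and DO readings) around those skeletons;
community columns are Dirichlet perturbations of the interpolated
reference composition.  All randomness flows from one seeded generator,
so equal seeds give byte-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biofilm import DOProfile, ThicknessSeries
from .community import AbundanceTable
from .datasets import (
    DENSITY_ANCHORS_KG_M3,
    DO_PENETRATION_ANCHORS_UM,
    STUDY_SHEAR_STRESSES,
    THICKNESS_ANCHORS_MM,
    archaea_table,
)
from .exceptions import InvalidInputError
from .methane import BiomassCurveParams

__all__ = [
    "NoiseConfig",
    "ExperimentConfig",
    "plateau_thickness_mm",
    "density_kg_m3",
    "do_penetration_um",
    "gen_thickness_series",
    "gen_do_profile",
    "gen_methane_series",
    "gen_community",
    "gen_experiment",
]

# anchors used only for interpolation; keep the three-representative-sewer
# pattern (the 1.45 Pa thickness/density values sit off these line segments
# and are not interpolation anchors)
_THICK_ANCHORS = ((0.8, 2.4), (1.29, 2.7), (2.0, 2.2))
_DENS_ANCHORS = ((0.8, 51.0), (1.29, 62.0), (2.0, 80.0))
_DO_ANCHORS = ((0.8, 2050.0), (1.29, 1850.0), (2.0, 1450.0))


def _interp_extrap(F: float, anchors) -> float:
    """Piecewise-linear interpolation with linear end-segment extrapolation."""
    xs = [a[0] for a in anchors]
    ys = [a[1] for a in anchors]
    if F <= xs[0]:
        i = 0
    elif F >= xs[-1]:
        i = len(xs) - 2
    else:
        i = max(j for j in range(len(xs) - 1) if xs[j] <= F)
    x0, x1, y0, y1 = xs[i], xs[i + 1], ys[i], ys[i + 1]
    return y0 + (F - x0) * (y1 - y0) / (x1 - x0)


def plateau_thickness_mm(F: float) -> float:
    """Default mature (plateau) biofilm thickness at shear stress F, mm."""
    return _interp_extrap(F, _THICK_ANCHORS)


def density_kg_m3(F: float) -> float:
    """Default mature biomass density at shear stress F, kg/m³."""
    return _interp_extrap(F, _DENS_ANCHORS)


def do_penetration_um(F: float) -> float:
    """Default oxygen penetration depth at shear stress F, µm."""
    return _interp_extrap(F, _DO_ANCHORS)


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise magnitudes, all standard deviations.

    thickness_sd is per chip point (mm): the nine-point heterogeneity plus
    reading error.  density_sd is per gravimetric record (kg/m³).
    methane_rel_sd is the relative scatter of a daily rate.  do_sd is per
    microprofile reading (mg/L).  community_conc is the Dirichlet
    concentration scale of a community draw (None disables perturbation).
    """

    thickness_sd: float = 0.1
    density_sd: float = 4.0
    methane_rel_sd: float = 0.05
    do_sd: float = 0.2
    community_conc: float | None = 300.0

    def __post_init__(self) -> None:
        for name in ("thickness_sd", "density_sd", "methane_rel_sd", "do_sd"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0, None)


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of one virtual experiment.

    Defaults reproduce the pilot study's conditions: seven sewers at
    0.5–2.5 Pa, the published biomass quadratic as truth, the
    proportionality c* refitted from the published rates (16.55), θ = 1.05
    at the mid-range temperature 22.5 °C with a 2 h retention time, 60-day
    growth monitoring sampled every 5 days, and 6 days of methane
    collection.
    """

    shear_stresses: tuple[float, ...] = STUDY_SHEAR_STRESSES
    biomass_params: BiomassCurveParams = field(default_factory=BiomassCurveParams)
    composite_coeff: float = 16.55
    theta: float = 1.05
    T: float = 22.5
    HRT: float = 2.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    duration_days: int = 60
    sample_every: int = 5
    methane_days: int = 6
    do_surface: float = 8.0
    eps_fraction: float = 0.15
    seed: int = 0

    # growth-curve shape (relative to the mature plateau): logistic rise
    # reaching a 25% overshoot at peak_day, a short hold at the maximum,
    # then a linear slough of 20% of the peak back to the plateau.  The
    # shape keeps every pre-plateau window unstable under the 10-day/5%
    # maturity criterion, so detected maturity lands at the first plateau
    # sample (~day 40)
    peak_ratio: float = 1.25
    rise_midpoint_day: float = 16.0
    rise_scale_days: float = 3.0
    peak_day: float = 25.0
    slough_start_day: float = 30.0
    slough_end_day: float = 39.0

    def __post_init__(self) -> None:
        if self.duration_days <= 0 or self.sample_every <= 0:
            raise InvalidInputError("duration_days and sample_every must be > 0")
        if self.methane_days < 1:
            raise InvalidInputError("methane_days must be >= 1")
        if not 0.0 <= self.eps_fraction < 1.0:
            raise InvalidInputError("eps_fraction must lie in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_seed(self, seed: int) -> "ExperimentConfig":
        return replace(self, seed=seed)

    def biomass_truth(self, F: float) -> float:
        p = self.biomass_params
        return p.a * F * F + p.b * F + p.c

    def wetted_area_m2(self, F: float) -> float:
        """Biofilm growth area consistent with the biomass truth.

        Chosen so that density × mature thickness × area × (1 − EPS
        fraction) equals the generating quadratic X(F); the resulting
        areas (~0.5 m²) match the wetted perimeter of an 8 m pilot pipe.
        """
        X = self.biomass_truth(F)
        if X <= 0:
            raise InvalidInputError(
                f"biomass truth is non-positive at F = {F} Pa; "
                "choose shear stresses inside the quadratic's validity range"
            )
        rho = density_kg_m3(F)
        delta_m = plateau_thickness_mm(F) * 1e-3
        return X / (rho * delta_m * (1.0 - self.eps_fraction))


def _thickness_skeleton(t: float, config: ExperimentConfig) -> float:
    """Relative thickness (plateau = 1) at day t."""
    P = config.peak_ratio

    def logistic(x: float) -> float:
        return 1.0 / (1.0 + math.exp(-(x - config.rise_midpoint_day)
                                     / config.rise_scale_days))

    if t <= config.peak_day:
        # normalized so the rise meets the peak exactly at peak_day
        return P * logistic(t) / logistic(config.peak_day)
    if t <= config.slough_start_day:
        return P
    if t >= config.slough_end_day:
        return 1.0
    frac = (t - config.slough_start_day) / (
        config.slough_end_day - config.slough_start_day)
    return P + frac * (1.0 - P)


def gen_thickness_series(
    F: float, config: ExperimentConfig, rng: np.random.Generator,
    sewer_id: str | None = None,
) -> ThicknessSeries:
    """Thickness time series for one sewer: rise, slough, plateau.

    Nine chip points per sampling day, jittered with ``thickness_sd``;
    the record mean is the plain average of the points.
    """
    sid = sewer_id or f"F={F:g} Pa"
    plateau = plateau_thickness_mm(F)
    days = list(range(0, config.duration_days + 1, config.sample_every))
    points = []
    for d in days:
        base = plateau * _thickness_skeleton(float(d), config)
        pts = base + rng.normal(0.0, config.noise.thickness_sd, size=9)
        points.append(np.clip(pts, 0.0, None))
    return ThicknessSeries.from_points(sid, days, points)


def gen_do_profile(
    F: float, config: ExperimentConfig, rng: np.random.Generator,
    sewer_id: str | None = None,
) -> DOProfile:
    """Mature-biofilm DO microprofile: linear decline to zero at depth L(F).

    Readings sit on the 100-µm instrument grid plus the exact penetration
    depth; noisy profiles are re-monotonized (running minimum) and clipped
    at zero so the profile stays a valid microgradient.
    """
    sid = sewer_id or f"F={F:g} Pa"
    L = do_penetration_um(F)
    depths = np.append(np.arange(0.0, L, 100.0), L)
    conc = config.do_surface * (1.0 - depths / L)
    if config.noise.do_sd > 0:
        noisy = conc + rng.normal(0.0, config.noise.do_sd, size=conc.size)
        noisy[-1] = 0.0  # anoxic base of the profile
        conc = np.minimum.accumulate(np.clip(noisy, 0.0, None))
    return DOProfile(depths=tuple(depths), do_conc=tuple(conc), sewer_id=sid)


def gen_methane_series(
    F: float, config: ExperimentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Daily methane rates Q_true·(1 + ε), mg/(L·day); negatives redrawn."""
    X = config.biomass_truth(F)
    if X <= 0:
        raise InvalidInputError(
            f"biomass truth is non-positive at F = {F} Pa; methane rate undefined"
        )
    q_true = config.composite_coeff * X
    out = np.empty(config.methane_days)
    for i in range(config.methane_days):
        q = q_true * (1.0 + rng.normal(0.0, config.noise.methane_rel_sd))
        while q < 0:
            q = q_true * (1.0 + rng.normal(0.0, config.noise.methane_rel_sd))
        out[i] = q
    return out


def gen_density_series(
    F: float, config: ExperimentConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Biomass-density records: ramp to the mature value by day 10, then flat."""
    rho = density_kg_m3(F)
    days = list(range(0, config.duration_days + 1, config.sample_every))
    base = np.array([rho * min(1.0, 0.5 + 0.05 * d) for d in days])
    vals = np.clip(base + rng.normal(0.0, config.noise.density_sd, size=len(days)), 0.0, None)
    return pd.DataFrame({"day": days, "density_kg_m3": vals})


def gen_community(
    F: float, config: ExperimentConfig, rng: np.random.Generator
) -> pd.Series:
    """One community column (%, summing to 100) at shear stress F.

    The base composition interpolates the renormalized reference columns
    (anchored at 0.8, 1.29 and 2.0 Pa); F outside that range is an error.
    The Dirichlet perturbation keeps zero taxa at zero and renormalizes.
    """
    anchors = [0.8, 1.29, 2.0]
    if not anchors[0] <= F <= anchors[-1]:
        raise InvalidInputError(
            f"F = {F} Pa is outside the community interpolation range "
            f"[{anchors[0]}, {anchors[-1]}] Pa"
        )
    ref = archaea_table().renormalized().data
    cols = ["F=0.8 Pa", "F=1.29 Pa", "F=2.0 Pa"]
    lo = max(i for i in range(len(anchors) - 1) if anchors[i] <= F)
    t = (F - anchors[lo]) / (anchors[lo + 1] - anchors[lo])
    base = (1.0 - t) * ref[cols[lo]] + t * ref[cols[lo + 1]]
    conc = config.noise.community_conc
    if conc is None:
        drawn = base.to_numpy()
    else:
        alpha = conc * base.to_numpy() / 100.0
        g = np.where(alpha > 0, rng.gamma(np.clip(alpha, 1e-300, None)), 0.0)
        drawn = 100.0 * g / g.sum()
    out = pd.Series(drawn, index=ref.index, name=f"F={F:g} Pa")
    return out * (100.0 / out.sum())


def gen_experiment(config: ExperimentConfig, out_dir) -> dict[str, Path]:
    """Write one complete virtual experiment under ``out_dir``.

    Produces thickness.csv, density.csv, do_profiles.csv, methane.csv,
    sewers.csv (design: shear stress, wetted area, EPS fraction),
    community.tsv and truth.yaml (the generating parameters — kept out of
    any fitting path).  Community columns exist for the sewers inside the
    reference interpolation range; outside it the nearest anchor
    composition is used (extrapolation by clamping).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = config.rng()

    thick_rows, dens_rows, do_rows, ch4_rows, sewer_rows = [], [], [], [], []
    comm_cols = {}
    for F in config.shear_stresses:
        sid = f"F={F:g} Pa"
        ts = gen_thickness_series(F, config, rng, sewer_id=sid)
        for rec in ts.records:
            row = {"sewer_id": sid, "day": rec.day}
            row.update({f"point_{i+1}": p for i, p in enumerate(rec.point_thicknesses)})
            thick_rows.append(row)
        dens = gen_density_series(F, config, rng)
        for _, r in dens.iterrows():
            dens_rows.append({"sewer_id": sid, "day": int(r["day"]),
                              "density_kg_m3": r["density_kg_m3"]})
        prof = gen_do_profile(F, config, rng, sewer_id=sid)
        for z, c in zip(prof.depths, prof.do_conc):
            do_rows.append({"sewer_id": sid, "depth_um": z, "do_mg_l": c})
        for day, q in enumerate(gen_methane_series(F, config, rng), start=1):
            ch4_rows.append({"sewer_id": sid, "day": day, "methane_mg_l_day": q})
        sewer_rows.append({
            "sewer_id": sid, "shear_pa": F,
            "area_m2": config.wetted_area_m2(F),
            "eps_fraction": config.eps_fraction,
        })
        F_comm = min(max(F, 0.8), 2.0)  # clamp to the community anchor range
        comm_cols[sid] = gen_community(F_comm, config, rng).rename(sid)

    paths = {
        "thickness": out / "thickness.csv",
        "density": out / "density.csv",
        "do_profiles": out / "do_profiles.csv",
        "methane": out / "methane.csv",
        "sewers": out / "sewers.csv",
        "community": out / "community.tsv",
        "truth": out / "truth.yaml",
    }
    pd.DataFrame(thick_rows).to_csv(paths["thickness"], index=False)
    pd.DataFrame(dens_rows).to_csv(paths["density"], index=False)
    pd.DataFrame(do_rows).to_csv(paths["do_profiles"], index=False)
    pd.DataFrame(ch4_rows).to_csv(paths["methane"], index=False)
    pd.DataFrame(sewer_rows).to_csv(paths["sewers"], index=False)
    comm = pd.DataFrame(comm_cols)
    comm.index.name = "taxon"
    comm.to_csv(paths["community"], sep="\t")

    p = config.biomass_params
    truth = {
        "biomass_params": {"a": p.a, "b": p.b, "c": p.c},
        "composite_coeff": config.composite_coeff,
        "theta": config.theta,
        "T": config.T,
        "HRT": config.HRT,
        "yield_Y": config.composite_coeff
        / (config.theta ** (config.T - 20.0) * config.HRT),
        "eps_fraction": config.eps_fraction,
        "do_surface": config.do_surface,
        "seed": config.seed,
        "noise": asdict(config.noise),
        "shear_stresses": list(config.shear_stresses),
    }
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    return paths
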