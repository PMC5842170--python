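"""Biofilm data reduction: maturity, oxygen penetration, microorganism amount."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sewerch4.biofilm import (
    NOT_MATURE,
    NOT_REACHED,
    BiofilmState,
    DOProfile,
    ThicknessSeries,
    maturity_day,
    microorganism_amount,
    penetration_depth,
    read_biofilm_state_csv,
    read_do_profiles_csv,
    read_thickness_csv,
)
from sewerch4.exceptions import InconsistentEPSError, InvalidInputError


def brute_force_maturity(days, means, window=10.0, rel_tol=0.05):
    """Exhaustive scan over all candidate start days (independent oracle)."""
    days = np.asarray(days)
    means = np.asarray(means)
    for d in days:
        w = means[(days >= d) & (days <= d + window)]
        if len(w) < 2:
            continue
        m = w.mean()
        if m > 0 and np.all(np.abs(w - m) <= rel_tol * m):
            return int(d)
        if m == 0 and np.all(w == 0):
            return int(d)
    return None


class TestMaturityDay:
    def test_constant_series_matures_immediately(self):
        s = ThicknessSeries.from_means("s", [0, 5, 10, 15], [2.4] * 4)
        assert maturity_day(s) == 0

    def test_rise_slough_plateau_curve(self):
        # peaks at day 22, sloughs, holds 2.4 mm from day 35 onwards
        days = [0, 4, 8, 12, 16, 20, 22, 26, 30, 35, 40, 45, 50, 55, 60]
        mm = [0.1, 0.4, 0.9, 1.6, 2.3, 2.9, 3.0, 2.8, 2.6, 2.4, 2.4, 2.4,
              2.4, 2.4, 2.4]
        s = ThicknessSeries.from_means("s", days, mm)
        assert maturity_day(s) == 35
        assert brute_force_maturity(days, mm) == 35

    def test_strictly_increasing_never_matures(self):
        # constant 20% growth per sample: no window ever stabilizes
        s = ThicknessSeries.from_means("s", list(range(0, 60, 5)),
                                       [0.2 * 1.2**i for i in range(12)])
        assert maturity_day(s) is NOT_MATURE

    def test_unsorted_days_rejected(self):
        with pytest.raises(InvalidInputError):
            ThicknessSeries.from_means("s", [0, 10, 5], [1, 2, 3])

    def test_too_short_series_rejected(self):
        s = ThicknessSeries.from_means("s", [0, 5], [1.0, 1.0])
        with pytest.raises(InvalidInputError):
            maturity_day(s)

    def test_agrees_with_brute_force_on_random_series(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = rng.integers(3, 15)
            days = np.cumsum(rng.integers(1, 8, size=n))
            means = rng.uniform(0.5, 3.0, size=n)
            if rng.random() < 0.5:  # half the series get a real plateau
                k = rng.integers(1, n)
                means[k:] = means[k]
            s = ThicknessSeries.from_means("s", days.tolist(), means.tolist())
            assert maturity_day(s) == brute_force_maturity(days, means)


class TestPenetrationDepth:
    def test_exact_grid_hit(self):
        p = DOProfile.from_pairs([(0, 4.0), (1000, 2.0), (2000, 0.0)])
        assert penetration_depth(p) == 2000.0

    def test_interpolated_crossing_at_zero_threshold(self):
        p = DOProfile.from_pairs([(1700, 1.0), (1800, 0.5), (1900, 0.0)])
        assert penetration_depth(p) == 1900.0

    def test_interpolated_crossing_at_positive_threshold(self):
        p = DOProfile.from_pairs([(1700, 1.0), (1800, 0.4), (1900, 0.0)])
        assert penetration_depth(p, threshold=0.2) == pytest.approx(1850.0)

    def test_all_positive_profile_not_reached(self):
        p = DOProfile.from_pairs([(0, 6.0), (100, 5.0), (200, 4.0)])
        assert penetration_depth(p) is NOT_REACHED

    def test_empty_profile_rejected(self):
        with pytest.raises(InvalidInputError):
            penetration_depth(DOProfile(depths=(), do_conc=()))

    def test_invalid_profiles_rejected(self):
        with pytest.raises(InvalidInputError):
            DOProfile.from_pairs([(100, 1.0), (100, 0.5)])
        with pytest.raises(InvalidInputError):
            DOProfile.from_pairs([(0, 1.0), (100, -0.5)])

    @settings(derandomize=True, max_examples=100)
    @given(
        t1=st.floats(0.0, 3.0),
        t2=st.floats(0.0, 3.0),
        seed=st.integers(0, 10_000),
    )
    def test_monotone_in_threshold(self, t1, t2, seed):
        """A larger threshold is crossed at a shallower (or equal) depth."""
        rng = np.random.default_rng(seed)
        conc = np.sort(rng.uniform(0, 8, size=12))[::-1]
        conc[-1] = 0.0
        p = DOProfile(depths=tuple(range(0, 1200, 100)), do_conc=tuple(conc))
        lo, hi = sorted((t1, t2))
        d_hi = penetration_depth(p, threshold=hi)
        d_lo = penetration_depth(p, threshold=lo)
        if d_lo is not None:
            assert d_hi is not None
            assert d_hi <= d_lo + 1e-9


class TestMicroorganismAmount:
    def test_hand_product(self):
        st_ = BiofilmState(density=74.0, thickness=2.4, area=1.0)
        assert microorganism_amount(st_) == pytest.approx(0.1776)

    def test_eps_fraction_halves_result(self):
        base = microorganism_amount(BiofilmState(74.0, 2.4, 1.0))
        half = microorganism_amount(
            BiofilmState(74.0, 2.4, 1.0, eps_fraction=0.5)
        )
        assert half == pytest.approx(base / 2)

    def test_full_eps_fraction_rejected(self):
        with pytest.raises(InvalidInputError):
            BiofilmState(74.0, 2.4, 1.0, eps_fraction=1.0)

    def test_zero_density_gives_zero(self):
        assert microorganism_amount(BiofilmState(0.0, 2.4, 1.0)) == 0.0

    def test_eps_mass_exceeding_total_rejected(self):
        with pytest.raises(InconsistentEPSError):
            microorganism_amount(BiofilmState(74.0, 2.4, 1.0, eps_mass=1.0))

    def test_linear_in_each_factor(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            rho, delta, area = rng.uniform(0.1, 100, size=3)
            k = rng.uniform(0.1, 5)
            x0 = microorganism_amount(BiofilmState(rho, delta, area))
            assert microorganism_amount(
                BiofilmState(k * rho, delta, area)
            ) == pytest.approx(k * x0)
            assert microorganism_amount(
                BiofilmState(rho, k * delta, area)
            ) == pytest.approx(k * x0)
            assert microorganism_amount(
                BiofilmState(rho, delta, k * area)
            ) == pytest.approx(k * x0)


class TestReaders:
    def test_thickness_points_round_trip(self, tmp_path):
        df = pd.DataFrame({
            "sewer_id": ["a"] * 2, "day": [0, 5],
            **{f"point_{i+1}": [2.0 + 0.1 * i, 2.5 + 0.1 * i]
               for i in range(9)},
        })
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        series = read_thickness_csv(path)["a"]
        assert len(series.records) == 2
        assert series.means[0] == pytest.approx(
            np.mean([2.0 + 0.1 * i for i in range(9)])
        )

    def test_do_and_state_readers(self, tmp_path):
        pd.DataFrame({
            "sewer_id": ["a"] * 3, "depth_um": [0, 100, 200],
            "do_mg_l": [4.0, 2.0, 0.0],
        }).to_csv(tmp_path / "do.csv", index=False)
        prof = read_do_profiles_csv(tmp_path / "do.csv")["a"]
        assert penetration_depth(prof) == 200.0

        pd.DataFrame({
            "sewer_id": ["a"], "density_kg_m3": [74.0],
            "thickness_mm": [2.4], "area_m2": [1.0], "eps_kg": [0.0],
        }).to_csv(tmp_path / "b.csv", index=False)
        state = read_biofilm_state_csv(tmp_path / "b.csv")["a"]
        assert microorganism_amount(state) == pytest.approx(0.1776)
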