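import math
import warnings

import numpy as np
import pytest

from lakeburial.geochron import (
    LAMBDA_PB210,
    CoreInterval,
    CoreProfile,
    cic_date,
    crs_date,
    cumulative_inventory,
    excess_pb210,
)
from lakeburial.synth import CoreScenario, make_core

from conftest import make_simple_profile


class TestExcess:
    def test_direct_subtraction_and_equilibrium(self):
        prof = make_simple_profile([50.0, 20.0, 18.0], ra=20.0)
        raw, flagged = excess_pb210(prof, clamp=False)
        assert raw.tolist() == [30.0, 0.0, -2.0]
        assert flagged.tolist() == [False, True, True]

    def test_negative_excess_clamped_to_floor_and_flagged(self):
        prof = make_simple_profile([50.0, 20.0, 18.0], ra=20.0)
        excess, flagged = excess_pb210(prof)
        assert excess[0] == 30.0
        # floor = 0.1% of surface excess, applied to both the zero and the
        # negative interval
        assert excess[1] == excess[2] == pytest.approx(0.001 * 30.0)
        assert flagged.tolist() == [False, True, True]

    def test_missing_activity_rejected_with_index(self):
        prof = make_simple_profile([50.0, 40.0, 32.0])
        prof.intervals[1].ra226 = float("nan")
        with pytest.raises(ValueError, match="index 1"):
            excess_pb210(prof)


class TestInventory:
    def test_zero_excess_gives_zero_inventory(self, simple_profile):
        inv = cumulative_inventory(
            simple_profile, np.zeros(len(simple_profile)), tail=False
        )
        assert np.all(inv.below_top == 0.0)
        assert inv.total == 0.0

    def test_slab_contribution_unit_arithmetic(self):
        # 100 Bq/kg = 0.1 Bq/g over a 2-cm slab of 1 g/cm3 -> 0.2 Bq/cm2
        prof = make_simple_profile([120.0, 120.0, 120.0], ra=20.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-decaying tail is irrelevant here
            inv = cumulative_inventory(prof, np.full(3, 100.0), tail=True)
        assert inv.contributions == pytest.approx([0.2, 0.2, 0.2])
        assert inv.total == pytest.approx(0.6 + inv.tail)

    def test_exponential_profile_matches_analytic_integral(self):
        # slab-averaged excess of C(m) = C0 exp(-k m): rectangular sums then
        # equal the closed-form integral of the continuous profile
        c0, k, rho, dz = 200.0, 0.2, 1.0, 2.0
        n = 30
        edges = np.arange(n + 1) * rho * dz
        slab_avg = (
            c0 / k * (np.exp(-k * edges[:-1]) - np.exp(-k * edges[1:])) / (rho * dz)
        )
        prof = make_simple_profile(slab_avg + 20.0, ra=20.0, rho=rho, thickness=dz)
        inv = cumulative_inventory(prof, slab_avg, tail=True)
        analytic_total = c0 * 1e-3 / k  # Bq/cm2, integral 0..inf
        assert inv.total == pytest.approx(analytic_total, rel=0.01)
        analytic_below_top = c0 * 1e-3 / k * np.exp(-k * edges[:-1])
        assert inv.below_top == pytest.approx(analytic_below_top, rel=0.01)

    def test_incomplete_inventory_without_tail(self):
        prof = make_simple_profile([220.0, 120.0, 70.0], ra=20.0)
        excess, _ = excess_pb210(prof)
        with pytest.raises(ValueError, match="incomplete inventory"):
            cumulative_inventory(prof, excess, tail=False)

    def test_inventory_conservation(self, ideal_core):
        profile, _ = ideal_core
        excess, _ = excess_pb210(profile)
        inv = cumulative_inventory(profile, excess)
        assert inv.total == pytest.approx(inv.contributions.sum() + inv.tail)
        # inventory below depth is non-increasing
        assert np.all(np.diff(inv.below_top) < 0)


class TestCrs:
    def test_surface_age_zero_and_half_inventory_identity(self, ideal_dated):
        dated, truth = ideal_dated
        # age at the very surface (full inventory) is 0 by construction;
        # the first slab midpoint is only a few years old
        assert dated.intervals[0].age == pytest.approx(
            truth["age_yr"].iloc[0], abs=0.3
        )
        # at the depth where the below inventory is half the total, the age
        # is one 210Pb half-life (22.3 yr)
        inv = np.array([iv.inventory_below for iv in dated.intervals])
        age_at_half = np.interp(
            dated.total_inventory / 2.0, inv[::-1], dated.ages[::-1]
        )
        assert age_at_half == pytest.approx(math.log(2) / LAMBDA_PB210, rel=0.01)

    @pytest.mark.parametrize("mar", [0.03, 0.05, 0.08, 0.12, 0.2])
    def test_recovers_constant_mar_within_1pct(self, mar):
        profile, truth = make_core(CoreScenario(mar_history=mar, flux=mar * 0.25))
        dated = crs_date(profile)
        n = len(dated.intervals)
        rel = np.abs(dated.mars / truth["mar"].to_numpy()[:n] - 1.0)
        assert rel.max() < 0.01

    def test_ages_non_decreasing_even_with_noise(self):
        profile, _ = make_core(CoreScenario(noise_cv=0.10, seed=11))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dated = crs_date(profile)
        assert np.all(np.diff(dated.ages) > 0)

    def test_scale_invariance_of_ages(self, ideal_core):
        profile, _ = ideal_core
        doubled = CoreProfile(
            profile.lake_id,
            [
                CoreInterval(
                    iv.top_depth,
                    iv.thickness,
                    iv.dry_bulk_density,
                    2.0 * iv.pb210_total,
                    2.0 * iv.ra226,
                    iv.oc_percent,
                )
                for iv in profile.intervals
            ],
            profile.collection_year,
        )
        a1 = crs_date(profile).ages
        a2 = crs_date(doubled).ages
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_old_ages_flagged(self):
        profile, _ = make_core(
            CoreScenario(mar_history=0.04, flux=0.01, core_length_cm=80.0)
        )
        dated = crs_date(profile)
        deep = [iv for iv in dated.intervals if iv.age > 150.0]
        assert deep and all("beyond_pb210_range" in iv.flags for iv in deep)


class TestCic:
    def test_exact_age_recovery_from_known_decay(self):
        # excess built as e0*exp(-lambda*t) at known ages, anchored at the
        # first slab: CIC returns those ages exactly
        t_true = np.array([0.0, 7.0, 19.0, 33.0, 61.0, 88.0])
        e0 = 300.0
        totals = e0 * np.exp(-LAMBDA_PB210 * t_true) + 20.0
        prof = make_simple_profile(totals, ra=20.0)
        dated = cic_date(prof, surface="first")
        assert dated.ages == pytest.approx(t_true, abs=1e-9)

    def test_constant_excess_gives_age_zero(self):
        prof = make_simple_profile([120.0, 120.0, 120.0], ra=20.0)
        dated = cic_date(prof, surface="first")
        assert dated.ages == pytest.approx([0.0, 0.0, 0.0])

    def test_agrees_with_crs_on_ideal_core(self, ideal_core):
        profile, _ = ideal_core
        crs = crs_date(profile)
        cic = cic_date(profile)
        n = len(crs.intervals)
        sel = crs.ages <= 100.0
        diff = np.abs(cic.ages[:n][sel] - crs.ages[sel])
        assert np.all(diff <= np.maximum(0.02 * crs.ages[sel], 0.2))

    def test_inversions_monotonized_with_warning(self):
        prof = make_simple_profile([120.0, 80.0, 110.0, 60.0, 45.0], ra=20.0)
        with pytest.warns(UserWarning, match="monotonized"):
            dated = cic_date(prof, surface="first")
        assert np.all(np.diff(dated.ages) >= 0)


class TestProfileValidation:
    def test_requires_three_intervals(self):
        with pytest.raises(ValueError, match=">= 3 intervals"):
            make_simple_profile([50.0, 40.0])

    def test_requires_contiguity(self):
        ivs = [
            CoreInterval(0.0, 2.0, 1.0, 50.0, 20.0, 5.0),
            CoreInterval(3.0, 2.0, 1.0, 40.0, 20.0, 5.0),
            CoreInterval(5.0, 2.0, 1.0, 30.0, 20.0, 5.0),
        ]
        with pytest.raises(ValueError, match="contiguous"):
            CoreProfile("x", ivs)

    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            CoreInterval(0.0, -2.0, 1.0, 50.0, 20.0, 5.0)
        with pytest.raises(ValueError):
            CoreInterval(0.0, 2.0, 1.0, 50.0, 20.0, 150.0)
        with pytest.raises(ValueError):
            CoreInterval(0.0, 2.0, 1.0, -50.0, 20.0, 5.0)
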