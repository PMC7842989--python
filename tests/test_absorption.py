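"""Diffusivity chain, series absorption function, dose bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from mucoclear.absorption import (
    AbsorptionResult,
    DiffusionConstants,
    GelLayer,
    SoluteSpec,
    absorption_fraction,
    absorption_radius_sweep,
    concentration_profile,
    diffusivity_mucus,
    diffusivity_water,
    dosage,
    particle_absorption,
    regional_absorption_summary,
)
from mucoclear.clearance import ClearanceResult, RegionPassage
from mucoclear.domain import DEFAULT_REGIONS, REGION_IDS

GEL = GelLayer()
CONSTANTS = DiffusionConstants()


class TestDiffusivity:
    def test_stokes_einstein_scaling(self):
        assert diffusivity_water(20.0) == pytest.approx(diffusivity_water(10.0) / 2)

    @pytest.mark.parametrize(
        "r_nm,expected",
        [
            # k_B T / (6 pi mu0 r), evaluated independently
            (90.0, 3.651e-12),
            (1.0, 3.286e-10),
        ],
    )
    def test_stokes_einstein_values(self, r_nm, expected):
        assert diffusivity_water(r_nm, CONSTANTS) == pytest.approx(expected, rel=1e-3)

    def test_obstruction_factor_at_mesh_size(self):
        # r_s = r_g makes the size ratio exactly 1 -> factor exp(-pi/4)
        d0 = diffusivity_water(50.0, CONSTANTS)
        assert diffusivity_mucus(50.0, d0, CONSTANTS) / d0 == pytest.approx(
            np.exp(-np.pi / 4)
        )

    def test_obstruction_factor_small_solute_limit(self):
        r = 1e-9  # nm; practically zero
        d0 = diffusivity_water(r, CONSTANTS)
        factor = diffusivity_mucus(r, d0, CONSTANTS) / d0
        rf, rg = CONSTANTS.fibre_radius_nm, CONSTANTS.mesh_spacing_nm
        assert factor == pytest.approx(np.exp(-(np.pi / 4) * (rf / (rg + rf)) ** 2))
        assert factor == pytest.approx(0.9966, abs=5e-4)

    def test_gel_diffusivity_strictly_decreasing_in_radius(self):
        radii = np.arange(1.0, 111.0)
        d = np.array([diffusivity_mucus(r, constants=CONSTANTS) for r in radii])
        assert (np.diff(d) < 0).all()

    def test_non_positive_radius_rejected(self):
        with pytest.raises(ValueError):
            diffusivity_water(0.0)


class TestAbsorptionFunction:
    def test_zero_time_is_exactly_zero(self):
        assert absorption_fraction(0.0, 1e-12, GEL) == 0.0

    def test_long_time_limit_is_one(self):
        d = 1e-12
        # beta = 20 leaves a first-term remainder of (4/pi) e^-20 ~ 3e-9
        t = 20 * 4 * GEL.thickness_m**2 / (np.pi**2 * d)
        assert absorption_fraction(t, d, GEL) == pytest.approx(1.0, abs=1e-8)
        assert absorption_fraction(2 * t, d, GEL) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_time_and_diffusivity(self):
        ts = np.linspace(0, 2000, 60)
        a1 = absorption_fraction(ts, 1e-13, GEL)
        a2 = absorption_fraction(ts, 3e-13, GEL)
        assert (np.diff(a1) >= 0).all()
        assert (a2 >= a1).all()

    def test_slow_solute_reaches_97_percent_at_500s(self):
        d_g = diffusivity_mucus(90.0, constants=CONSTANTS)
        assert absorption_fraction(500.0, d_g, GEL) == pytest.approx(0.97, abs=0.02)

    def test_fast_solute_complete_within_10s(self):
        d_g = diffusivity_mucus(10.0, constants=CONSTANTS)
        assert absorption_fraction(10.0, d_g, GEL) >= 0.999

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            absorption_fraction(-1.0, 1e-12, GEL)


class TestConcentrationProfile:
    def test_absorbing_boundary_is_zero(self):
        assert concentration_profile(GEL.thickness_m, 5.0, 1e-12, GEL) == pytest.approx(
            0.0, abs=1e-9
        )

    @pytest.mark.parametrize("tau", [0.05, 0.2, 0.8])
    def test_integral_equals_one_minus_absorbed(self, tau):
        d = 3e-13
        t = tau * GEL.thickness_m**2 / d
        integral, _ = quad(
            lambda x: concentration_profile(x, t, d, GEL), 0, GEL.thickness_m,
            limit=200,
        )
        assert integral == pytest.approx(1.0 - absorption_fraction(t, d, GEL), abs=1e-6)

    def test_x_outside_layer_rejected(self):
        with pytest.raises(ValueError):
            concentration_profile(2 * GEL.thickness_m, 1.0, 1e-12, GEL)


def _passage(intervals, status="cleared", pid=0):
    return RegionPassage(particle_id=pid, intervals=intervals, status=status)


class TestParticleAccounting:
    def test_infinite_residence_absorbs_everything(self):
        d_g = diffusivity_mucus(10.0, constants=CONSTANTS)
        t_end = 1e5  # effectively infinite for this diffusivity
        p = _passage([(REGION_IDS["septum"], 0.0, t_end)], status="in_transit")
        row = particle_absorption(
            p, 2.0, SoluteSpec(10.0), GEL, DEFAULT_REGIONS, d_g
        )
        assert row.absorbed_by_region_kg[REGION_IDS["septum"]] == pytest.approx(2.0)
        assert row.residual_kg == pytest.approx(0.0, abs=1e-12)

    def test_vestibule_residence_is_lost_not_absorbed(self):
        d_g = diffusivity_mucus(50.0, constants=CONSTANTS)
        horizon = 600.0
        p = _passage([(REGION_IDS["vestibule"], 0.0, horizon)], status="in_transit")
        row = particle_absorption(p, 1.0, SoluteSpec(50.0), GEL, DEFAULT_REGIONS, d_g)
        assert row.absorbed_kg == 0.0
        expected_lost = absorption_fraction(horizon, d_g, GEL)
        assert row.lost_vestibule_kg == pytest.approx(expected_lost, abs=1e-12)

    def test_increments_match_fine_grained_accumulation(self):
        d_g = diffusivity_mucus(70.0, constants=CONSTANTS)
        intervals = [
            (REGION_IDS["vestibule"], 0.0, 137.0),
            (REGION_IDS["septum"], 137.0, 411.5),
            (REGION_IDS["main_passage"], 411.5, 900.0),
        ]
        p = _passage(intervals, status="cleared")
        row = particle_absorption(p, 1.0, SoluteSpec(70.0), GEL, DEFAULT_REGIONS, d_g)
        # brute force: accumulate dA over 1 ms substeps, credited by region
        buckets = {rid: 0.0 for rid, _, _ in intervals}
        for rid, a, b in intervals:
            ts = np.linspace(a, b, 2001)
            vals = absorption_fraction(ts, d_g, GEL)
            buckets[rid] += float(vals[-1] - vals[0])
        assert row.lost_vestibule_kg == pytest.approx(
            buckets[REGION_IDS["vestibule"]], abs=1e-9
        )
        assert row.absorbed_by_region_kg[REGION_IDS["septum"]] == pytest.approx(
            buckets[REGION_IDS["septum"]], abs=1e-9
        )
        assert row.cleared_unabsorbed_kg == pytest.approx(
            1.0 - absorption_fraction(900.0, d_g, GEL), abs=1e-12
        )

    @settings(max_examples=30, deadline=None)
    @given(
        r_nm=st.floats(1.0, 110.0),
        t1=st.floats(0.1, 600.0),
        t2=st.floats(0.1, 600.0),
        cleared=st.booleans(),
    )
    def test_mass_conservation_property(self, r_nm, t1, t2, cleared):
        d_g = diffusivity_mucus(r_nm, constants=CONSTANTS)
        intervals = [
            (REGION_IDS["vestibule"], 0.0, t1),
            (REGION_IDS["septum"], t1, t1 + t2),
        ]
        p = _passage(intervals, status="cleared" if cleared else "in_transit")
        row = particle_absorption(p, 3.0, SoluteSpec(r_nm), GEL, DEFAULT_REGIONS, d_g)
        assert row.conservation_error() < 1e-10

    def test_non_contiguous_intervals_rejected(self):
        p = _passage(
            [(REGION_IDS["septum"], 0.0, 10.0), (REGION_IDS["olfactory"], 11.0, 20.0)]
        )
        with pytest.raises(ValueError, match="contiguous"):
            particle_absorption(p, 1.0, SoluteSpec(10.0), GEL, DEFAULT_REGIONS, 1e-12)


class TestSummaryAndDose:
    def test_single_fully_absorbed_particle(self):
        d_g = diffusivity_mucus(10.0, constants=CONSTANTS)
        p = _passage([(REGION_IDS["septum"], 0.0, 1e5)], status="in_transit")
        row = particle_absorption(p, 1.0, SoluteSpec(10.0), GEL, DEFAULT_REGIONS, d_g)
        summary = regional_absorption_summary(
            AbsorptionResult(10.0, [row], total_solute_kg=1.0)
        )
        assert summary.total_absorbed_pct == pytest.approx(100.0)
        assert summary.regional_pct["septum"] == pytest.approx(100.0)
        assert summary.contribution_pct["septum"] == pytest.approx(100.0)

    def test_half_absorbed_half_cleared(self):
        d_g = diffusivity_mucus(10.0, constants=CONSTANTS)
        full = particle_absorption(
            _passage([(REGION_IDS["septum"], 0.0, 1e5)], "in_transit", 0),
            1.0, SoluteSpec(10.0), GEL, DEFAULT_REGIONS, d_g,
        )
        gone = particle_absorption(
            _passage([(REGION_IDS["main_passage"], 0.0, 1e-9)], "cleared", 1),
            1.0, SoluteSpec(10.0), GEL, DEFAULT_REGIONS, d_g,
        )
        summary = regional_absorption_summary(
            AbsorptionResult(10.0, [full, gone], total_solute_kg=2.0)
        )
        assert summary.total_absorbed_pct == pytest.approx(50.0, abs=1e-6)
        assert summary.cleared_unabsorbed_pct == pytest.approx(50.0, abs=1e-6)

    def test_dosage_zero_concentration(self):
        assert dosage([0.5, 1.0], [1e-6, 2e-6], 0.0) == 0.0

    def test_dosage_single_full_droplet_is_sphere_volume_times_c(self):
        r = 2e-6
        assert dosage([1.0], [r], 3.0) == pytest.approx(3.0 * 4 / 3 * np.pi * r**3)

    def test_dosage_two_droplets_hand_expansion(self):
        # (4/3) pi [0.5 (1 um)^3 + 0.25 (2 um)^3] with c = 1
        expected = 4 / 3 * np.pi * (0.5 * 1e-18 + 0.25 * 8e-18)
        assert dosage([0.5, 0.25], [1e-6, 2e-6], 1.0) == pytest.approx(expected)


class TestRadiusSweep:
    def _toy_clearance(self):
        passages = [
            _passage([(REGION_IDS["septum"], 0.0, 300.0)], "cleared", 0),
            _passage(
                [
                    (REGION_IDS["vestibule"], 0.0, 400.0),
                    (REGION_IDS["main_passage"], 400.0, 1200.0),
                ],
                "cleared",
                1,
            ),
        ]
        return ClearanceResult(
            passages=passages,
            snapshot_times_s=(),
            snapshots_x_mm=np.zeros((0, 2)),
            snapshots_y_mm=np.zeros((0, 2)),
            cleared_time_s=np.array([300.0, 1200.0]),
            deposition_region_id=np.array(
                [REGION_IDS["septum"], REGION_IDS["vestibule"]]
            ),
            horizon_s=1800.0,
        )

    def test_single_radius_sweep_matches_particle_accounting(self):
        clr = self._toy_clearance()
        sweep = absorption_radius_sweep(clr, [1.0, 1.0], [60.0], GEL, CONSTANTS)
        d_g = diffusivity_mucus(60.0, constants=CONSTANTS)
        rows = [
            particle_absorption(p, 1.0, SoluteSpec(60.0), GEL, DEFAULT_REGIONS, d_g)
            for p in clr.passages
        ]
        expected = 100.0 * sum(r.absorbed_kg for r in rows) / 2.0
        assert sweep["total_pct"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_cleared_region_absorption_decreases_with_radius(self):
        # all passages end by clearance, so regional absorption falls as the
        # gel diffusivity falls (larger solutes)
        clr = self._toy_clearance()
        sweep = absorption_radius_sweep(clr, [1.0, 1.0], [20.0, 60.0, 100.0], GEL, CONSTANTS)
        septum = sweep["absorbed_septum_pct"].to_numpy()
        assert (np.diff(septum) < 0).all()

    def test_row_sums_conserve_dose(self):
        clr = self._toy_clearance()
        sweep = absorption_radius_sweep(clr, [2.0, 3.0], [10.0, 90.0], GEL, CONSTANTS)
        sums = (
            sweep["total_pct"]
            + sweep["lost_vestibule_pct"]
            + sweep["cleared_unabsorbed_pct"]
            + sweep["residual_pct"]
        )
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_empty_radius_list_rejected(self):
        with pytest.raises(ValueError):
            absorption_radius_sweep(self._toy_clearance(), [1.0, 1.0], [], GEL, CONSTANTS)
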