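"""Capacitive coupling: Ve formula limits and motion sensitivities."""

import numpy as np
import pytest

from cecglead import (CapacitiveElectrode, GeometryError, SurfaceFieldMap,
                      artifact_susceptibility, displacement_sensitivity,
                      electrode_coupling, electrode_potential,
                      plate_capacitance)
from cecglead.electrode_model import EPSILON_0
from cecglead.thorax_model import planar_disc_surface


@pytest.fixture(scope="module")
def disc():
    """Fine flat disc: discretization error well below the tolerances."""
    return planar_disc_surface(0.08, 0.0025)


def field_on(surface, V, E=None):
    if E is None:
        E = np.zeros((surface.n_vertices, 3))
    return SurfaceFieldMap(surface, V, E)


def linear_field(surface, gradient):
    g = np.asarray(gradient, float)
    V = surface.vertices @ g
    E = np.tile(-g, (surface.n_vertices, 1))
    return SurfaceFieldMap(surface, V, E)


class TestPlateCapacitance:
    def test_two_centimetre_electrode_at_one_millimetre(self):
        c = plate_capacitance(np.pi * 0.01**2, 1.0e-3, 1.0)
        assert c == pytest.approx(2.781e-12, rel=1e-3)

    @pytest.mark.parametrize("factor,what", [(2.0, "gap"), (2.0, "eps")])
    def test_proportionalities(self, factor, what):
        base = plate_capacitance(1e-4, 1e-3, 1.0)
        if what == "gap":
            assert plate_capacitance(1e-4, factor * 1e-3, 1.0) == \
                pytest.approx(base / factor)
        else:
            assert plate_capacitance(1e-4, 1e-3, factor) == \
                pytest.approx(base * factor)

    def test_nonpositive_gap_rejected(self):
        with pytest.raises(ValueError):
            plate_capacitance(1e-4, 0.0, 1.0)


class TestElectrodeCoupling:
    def test_uniform_gap_on_flat_patch_gives_uniform_ce(self, disc):
        cp = electrode_coupling(disc, CapacitiveElectrode((0, 0, 0), 0.03))
        assert np.allclose(cp.ce, EPSILON_0 / 1.0e-3)
        assert np.allclose(cp.gap_profile, 1.0e-3)

    def test_total_capacitance_matches_plate_formula(self, disc):
        cp = electrode_coupling(disc, CapacitiveElectrode((0, 0, 0), 0.03))
        plate = plate_capacitance(np.pi * 0.03**2, 1.0e-3, 1.0)
        assert cp.total_capacitance == pytest.approx(plate, rel=0.05)

    def test_capacitance_shrinks_monotonically_with_radius(self, disc):
        radii = (0.05, 0.03, 0.02, 0.01)
        caps = [electrode_coupling(
            disc, CapacitiveElectrode((0, 0, 0), r)).total_capacitance
            for r in radii]
        assert all(a > b for a, b in zip(caps, caps[1:]))

    def test_far_electrode_rejected(self, disc):
        with pytest.raises(GeometryError, match="no coupling"):
            electrode_coupling(disc, CapacitiveElectrode((0, 0, 0.5), 0.02))

    def test_large_gap_records_validity_warning(self, disc):
        cp = electrode_coupling(
            disc, CapacitiveElectrode((0, 0, 0), 0.01, gap=0.05))
        assert any("validity" in w for w in cp.warnings)


class TestElectrodePotential:
    def test_equipotential_body_fixes_ve(self, disc):
        cp = electrode_coupling(disc, CapacitiveElectrode((0, 0, 0), 0.03))
        fm = field_on(disc, np.full(disc.n_vertices, 5.0))
        assert electrode_potential(fm, cp) == pytest.approx(5.0, rel=1e-12)

    def test_uniform_coupling_reduces_to_area_weighted_mean(self, disc):
        cp = electrode_coupling(disc, CapacitiveElectrode((0, 0, 0), 0.03))
        rng = np.random.default_rng(0)
        V = rng.normal(size=disc.n_vertices)
        fm = field_on(disc, V)
        idx, w = cp.patch.vertex_idx, cp.patch.weights
        assert electrode_potential(fm, cp) == pytest.approx(
            (V[idx] * w).sum() / w.sum(), rel=1e-12)

    def test_linear_potential_recovers_centre_value(self, disc):
        fm = linear_field(disc, (2.0, -1.0, 0.0))
        cp = electrode_coupling(disc, CapacitiveElectrode((0.02, 0.01, 0), 0.03))
        centre_value = 2.0 * 0.02 - 1.0 * 0.01
        assert electrode_potential(fm, cp) == pytest.approx(
            centre_value, abs=0.01 * abs(centre_value))

    def test_ve_bounded_by_patch_extremes(self, disc):
        rng = np.random.default_rng(1)
        V = rng.normal(size=disc.n_vertices)
        fm = field_on(disc, V)
        cp = electrode_coupling(disc, CapacitiveElectrode((0, 0, 0), 0.025))
        ve = electrode_potential(fm, cp)
        vp = V[cp.patch.vertex_idx]
        assert vp.min() <= ve <= vp.max()

    def test_ve_independent_of_frequency(self, disc):
        V = disc.vertices[:, 0] ** 2
        fm = field_on(disc, V)
        ves = [electrode_potential(fm, electrode_coupling(
            disc, CapacitiveElectrode((0, 0, 0), 0.03, omega=w)))
            for w in (1.0, 2 * np.pi * 50, 1e6)]
        assert ves[0] == ves[1] == ves[2]


class TestDisplacementSensitivity:
    def test_both_sensitivities_vanish_on_equipotential_surface(self, disc):
        cp = electrode_coupling(disc, CapacitiveElectrode((0, 0, 0), 0.03))
        fm = field_on(disc, np.full(disc.n_vertices, 2.5))
        normal = displacement_sensitivity(fm, cp, "normal")
        tang = displacement_sensitivity(fm, cp, "tangential",
                                        direction=(1, 0, 0))
        assert abs(normal) < 1e-8
        assert abs(tang) < 1e-8

    def test_uniform_gap_normal_sensitivity_cancels_exactly(self, disc):
        """A uniform Ce rescaling drops out of the Ve ratio even when the
        potential varies under the plate."""
        fm = linear_field(disc, (3.0, 0.0, 0.0))
        cp = electrode_coupling(disc, CapacitiveElectrode((0, 0, 0), 0.03))
        ve0 = electrode_potential(fm, cp)
        ve1 = electrode_potential(fm, cp.scaled_ce(0.37))
        assert ve1 == pytest.approx(ve0, rel=1e-14)
        assert displacement_sensitivity(fm, cp, "normal") == \
            pytest.approx(0.0, abs=1e-10)

    def test_tangential_sensitivity_tracks_mean_tangential_field(self, disc):
        x = disc.vertices[:, 0]
        V = 3.0 * x**2 + 1.5 * x
        E = np.column_stack([-(6.0 * x + 1.5), np.zeros_like(x),
                             np.zeros_like(x)])
        fm = SurfaceFieldMap(disc, V, E)
        cp = electrode_coupling(disc, CapacitiveElectrode((0, 0, 0), 0.03))
        sens = displacement_sensitivity(fm, cp, "tangential",
                                        direction=(1, 0, 0), step=0.003)
        w = cp.ce * cp.patch.weights
        mean_e = (fm.tangential[cp.patch.vertex_idx, 0] * w).sum() / w.sum()
        assert sens == pytest.approx(-mean_e, rel=0.10)

    def test_shift_off_the_surface_rejected(self, disc):
        fm = linear_field(disc, (1.0, 0.0, 0.0))
        cp = electrode_coupling(disc, CapacitiveElectrode((0.077, 0, 0), 0.002))
        with pytest.raises(GeometryError):
            displacement_sensitivity(fm, cp, "tangential",
                                     direction=(1, 0, 0), step=0.05)


class TestArtifactSusceptibility:
    def test_zero_on_uniform_potential(self, disc):
        cp = electrode_coupling(disc, CapacitiveElectrode((0, 0, 0), 0.03))
        fm = field_on(disc, np.full(disc.n_vertices, 1.0))
        assert artifact_susceptibility(fm, cp) == 0.0

    def test_invariant_under_uniform_ce_scaling(self, disc):
        fm = linear_field(disc, (2.0, 1.0, 0.0))
        cp = electrode_coupling(disc, CapacitiveElectrode((0, 0, 0), 0.03))
        s0 = artifact_susceptibility(fm, cp)
        s1 = artifact_susceptibility(fm, cp.scaled_ce(10.0))
        assert s1 == pytest.approx(s0, rel=1e-12)
        assert s0 == pytest.approx(np.hypot(2.0, 1.0), rel=1e-6)

    def test_equatorial_electrode_more_susceptible_than_polar(
            self, sphere_mesh, sphere_fieldmap):
        b = sphere_mesh.boundary
        pole = b.vertices[np.argmax(b.vertices[:, 2])]
        equator = b.vertices[np.argmin(np.abs(b.vertices[:, 2]))]
        s_pole = artifact_susceptibility(sphere_fieldmap, electrode_coupling(
            b, CapacitiveElectrode(tuple(pole), 0.02)))
        s_eq = artifact_susceptibility(sphere_fieldmap, electrode_coupling(
            b, CapacitiveElectrode(tuple(equator), 0.02)))
        assert s_eq > s_pole

    def test_ve_error_on_curved_potential_grows_with_electrode_size(
            self, disc):
        """On a quadratic potential the averaged Ve deviates from the
        centre point value increasingly with radius (the size effect
        motivating small electrodes)."""
        x, y = disc.vertices[:, 0], disc.vertices[:, 1]
        fm = field_on(disc, x**2 + y**2)
        devs = []
        for r in (0.01, 0.02, 0.04):
            cp = electrode_coupling(disc, CapacitiveElectrode((0, 0, 0), r))
            devs.append(abs(electrode_potential(fm, cp)))  # centre value is 0
        assert devs[0] < devs[1] < devs[2]
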