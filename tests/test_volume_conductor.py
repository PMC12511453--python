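"""Volume-conductor solver: analytic oracles, conservation, disc model."""

import numpy as np
import pytest

from tiskit.tot_analysis import ActivatingAmplitudePair, tot_closed_form
from tiskit.volume_conductor import (
    ElectrodePatch,
    ElectrodeSetup,
    FieldSolution,
    TissueLayer,
    TissueModel,
    _iso,
    activating_amplitude,
    default_crossed_pairs,
    disc_compare,
    solve_pair,
    tot_map,
    write_vtk_structured_grid,
)
from conftest import HALFSPACE_I_MA, HALFSPACE_SIGMA, HALFSPACE_SNK_X, HALFSPACE_SRC_X


def pair_potential(x, y, z):
    """Analytic half-space potential of the +/- point pair, volts (mm in)."""
    k = HALFSPACE_I_MA * 1e-3 / (2 * np.pi * HALFSPACE_SIGMA)
    r1 = np.sqrt((x - HALFSPACE_SRC_X) ** 2 + y**2 + z**2) * 1e-3
    r2 = np.sqrt((x - HALFSPACE_SNK_X) ** 2 + y**2 + z**2) * 1e-3
    return k * (1 / r1 - 1 / r2)


def small_homogeneous_setup():
    tissue = TissueModel(
        extent_x_mm=80.0, extent_y_mm=80.0, extent_z_mm=40.0,
        layers=(
            TissueLayer("a", 8.0, _iso(0.3), _iso(0.0)),
            TissueLayer("b", 8.0, _iso(0.3), _iso(0.0)),
            TissueLayer("bulk", np.inf, _iso(0.3), _iso(0.0)),
        ),
        frequency_hz=2500.0, nerve_depth_mm=20.0, dx_mm=8.0,
        nz_per_layer=(2, 2, 0), muscle_dz_min_mm=4.0, muscle_dz_max_mm=8.0,
    )
    setup = ElectrodeSetup(
        patches=(
            ElectrodePatch(-24.0, -16.0, 8.0, pair=1, polarity=+1),
            ElectrodePatch(24.0, 16.0, 8.0, pair=1, polarity=-1),
            ElectrodePatch(-24.0, 16.0, 8.0, pair=2, polarity=+1),
            ElectrodePatch(24.0, -16.0, 8.0, pair=2, polarity=-1),
        ),
        current_1_ma=3.0, current_2_ma=2.0,
    )
    return tissue, setup


class TestSolver:
    def test_matches_halfspace_analytic_potential(self, halfspace_solution):
        sol = halfspace_solution
        xc, yc, zc = sol.x_centers_mm, sol.y_centers_mm, sol.z_centers_mm
        ix = np.argmin(np.abs(xc - HALFSPACE_SRC_X))
        iy = np.argmin(np.abs(yc - 0.0))
        # reference point deep in the medium removes the pinned-gauge offset
        ixr, iyr = np.argmin(np.abs(xc)), np.argmin(np.abs(yc))
        kzr = np.argmin(np.abs(zc - 120.0))
        v_ref_num = sol.potential[ixr, iyr, kzr].real
        v_ref_ana = pair_potential(xc[ixr], yc[iyr], zc[kzr])
        worst = 0.0
        for k, z in enumerate(zc):
            if not (8.0 <= z <= 31.0):  # ~3-12 grid cells below the patch
                continue
            num = sol.potential[ix, iy, k].real - v_ref_num
            ana = pair_potential(xc[ix], yc[iy], z) - v_ref_ana
            worst = max(worst, abs(num - ana) / abs(ana))
        assert worst < 0.05

    def test_prescribed_currents_conserved(self, halfspace_solution):
        got = halfspace_solution.electrode_currents_ma.real
        assert got[0] == pytest.approx(HALFSPACE_I_MA, rel=1e-3)
        assert got[1] == pytest.approx(-HALFSPACE_I_MA, rel=1e-3)

    def test_superposition_of_pairs(self):
        tissue, setup = small_homogeneous_setup()
        s1 = solve_pair(tissue, setup, 1)
        s2 = solve_pair(tissue, setup, 2)
        both = solve_pair(tissue, setup, None)
        diff = both.potential - (s1.potential + s2.potential)
        assert np.max(np.abs(diff)) <= 1e-10 * np.max(np.abs(both.potential))

    def test_inactive_pair_carries_no_net_current(self):
        tissue, setup = small_homogeneous_setup()
        s1 = solve_pair(tissue, setup, 1)
        assert np.all(np.abs(s1.electrode_currents_ma[2:]) < 1e-9)

    def test_solution_scales_linearly_with_current(self):
        tissue, setup = small_homogeneous_setup()
        s1 = solve_pair(tissue, setup, 1)
        setup2 = ElectrodeSetup(
            patches=setup.patches, current_1_ma=6.0, current_2_ma=2.0
        )
        s2 = solve_pair(tissue, setup2, 1)
        assert np.allclose(s2.potential, 2.0 * s1.potential, atol=1e-12)

    def test_thin_layer_rejected(self):
        with pytest.raises(ValueError, match="2 cells"):
            TissueModel(nz_per_layer=(1, 4, 0)).z_edges_mm()

    def test_unknown_pair_rejected(self):
        tissue, setup = small_homogeneous_setup()
        with pytest.raises(ValueError, match="pair"):
            solve_pair(tissue, setup, 3)

    def test_montage_validation(self):
        with pytest.raises(ValueError, match="overlap"):
            ElectrodeSetup(
                patches=(
                    ElectrodePatch(0.0, 0.0, 20.0, pair=1, polarity=+1),
                    ElectrodePatch(5.0, 5.0, 20.0, pair=1, polarity=-1),
                )
            )
        with pytest.raises(ValueError, match=r"\+ and one -"):
            ElectrodeSetup(
                patches=(
                    ElectrodePatch(-30.0, 0.0, 10.0, pair=1, polarity=+1),
                    ElectrodePatch(30.0, 0.0, 10.0, pair=1, polarity=+1),
                )
            )

    def test_grid_convergence_of_activating_map(self):
        # halving the grid spacing moves the window-averaged nerve-plane
        # activating amplitude by only a few percent; both grids place a
        # cell centre exactly on the nerve depth (10 mm) and values are
        # interpolated onto a common probe window between the electrodes
        from scipy.interpolate import RegularGridInterpolator

        z_coarse = (0, 0.75, 1.5, 4, 6.5, 9, 11, 13, 15.5, 18.5, 22, 26, 30)
        z_fine = (0, 0.375, 0.75, 1.125, 1.5, 2.75, 4, 5.25, 6.5, 7.5, 8.5,
                  9.5, 10.5, 11.5, 12.5, 13.75, 15, 16.5, 18, 20, 22, 24,
                  26, 28, 30)
        patches = (
            ElectrodePatch(-12.0, 0.0, 8.0, pair=1, polarity=+1),
            ElectrodePatch(+12.0, 0.0, 8.0, pair=1, polarity=-1),
        )
        px = np.arange(-10, 10.1, 2.0)
        py = np.arange(-6, 6.1, 2.0)
        probes = np.array([(a, b) for a in px for b in py])
        vals = []
        for dx, ze in ((2.0, z_coarse), (1.0, z_fine)):
            half = 26.0 + dx / 2  # keeps a cell centred at x = y = 0
            edges = tuple(np.arange(-half, half + dx / 2, dx))
            tissue = TissueModel(
                extent_x_mm=2 * half, extent_y_mm=2 * half, extent_z_mm=30.0,
                layers=(
                    TissueLayer("skin", 1.5, _iso(0.0015), _iso(0.0)),
                    TissueLayer("fat", 5.0, _iso(0.024), _iso(0.0)),
                    TissueLayer("muscle", np.inf, (0.6, 0.35, 0.35), _iso(0.0)),
                ),
                x_edges_override_mm=edges, y_edges_override_mm=edges,
                z_edges_override_mm=ze,
            )
            setup = ElectrodeSetup(patches=patches, current_1_ma=1.0,
                                   current_2_ma=1.0)
            sol = solve_pair(tissue, setup, 1)
            x, y, a1 = activating_amplitude(sol)
            interp = RegularGridInterpolator((x, y), a1)
            vals.append(float(np.mean(interp(probes))))
        assert abs(vals[1] - vals[0]) / vals[1] < 0.05


class TestActivatingAmplitude:
    def make_solution(self, v_of_x):
        x = np.linspace(-20, 20, 41)
        y = np.array([0.0])
        z = np.array([5.0, 12.0])
        V = np.zeros((41, 1, 2), dtype=complex)
        V[:, 0, :] = v_of_x(x)[:, None]
        tissue = TissueModel(
            extent_x_mm=40.0, extent_y_mm=4.0, extent_z_mm=20.0,
            layers=(
                TissueLayer("a", 4.0, _iso(0.3), _iso(0.0)),
                TissueLayer("bulk", np.inf, _iso(0.3), _iso(0.0)),
            ),
            nz_per_layer=(2, 0), nerve_depth_mm=12.0,
        )
        return FieldSolution(
            tissue=tissue, setup=None, x_centers_mm=x, y_centers_mm=y,
            z_centers_mm=z, potential=V, gel_potentials=np.array([]),
            electrode_currents_ma=np.array([]), active_pair=1, residual=0.0,
        )

    def test_linear_ramp_gives_zero(self):
        sol = self.make_solution(lambda x: 3.0 * x)
        _, _, a = activating_amplitude(sol, 12.0)
        assert np.allclose(a, 0.0, atol=1e-6)

    def test_quadratic_gives_constant_second_derivative(self):
        # V = a x^2 (x in mm) -> d2V/dx2 = 2a * 1e6 in SI
        sol = self.make_solution(lambda x: 0.5 * x**2)
        _, _, a = activating_amplitude(sol, 12.0)
        assert np.allclose(a, 1.0e6, rtol=1e-9)

    def test_nerve_plane_must_be_in_muscle(self, halfspace_solution):
        with pytest.raises(ValueError, match="muscle"):
            activating_amplitude(halfspace_solution, 5.0)
        with pytest.raises(ValueError, match="outside"):
            activating_amplitude(halfspace_solution, 1000.0)

    def test_matches_analytic_second_derivative(self, halfspace_solution):
        sol = halfspace_solution
        x, y, a = activating_amplitude(sol, 25.0)
        iy = np.argmin(np.abs(y - 0.0))
        k = np.argmin(np.abs(sol.z_centers_mm - 25.0))
        z = sol.z_centers_mm[k]

        def d2(x0, y0):
            h = 0.25  # mm, analytic central difference
            return abs(
                pair_potential(x0 - h, y0, z)
                - 2 * pair_potential(x0, y0, z)
                + pair_potential(x0 + h, y0, z)
            ) / (h * 1e-3) ** 2

        for x0 in (-20.0, -10.0, 0.0):
            ix = np.argmin(np.abs(x - x0))
            assert a[ix, iy] == pytest.approx(d2(x[ix], y[iy]), rel=0.05)


class TestTotMap:
    def test_small_currents_give_silent_map(self, forearm_fields):
        f = forearm_fields
        tot, labels = tot_map(0.01 * f["a1"], 0.01 * f["a2"], 1000.0)
        assert np.all(tot == 0.0)
        assert np.all(labels == "subthreshold")

    def test_equal_suprathreshold_currents_are_bimodal(self, forearm_fields):
        f = forearm_fields
        ix = np.argmin(np.abs(f["x"])); iy = np.argmin(np.abs(f["y"]))
        a1m, a2m = f["a1"][ix, iy], f["a2"][ix, iy]
        i_ma = 1.5 * 1000.0 / (a1m + a2m)  # equal currents, sum = 1.5 A_T
        tot, labels = tot_map(i_ma * f["a1"], i_ma * f["a2"], 1000.0)
        assert 0.0 < tot[ix, iy] < 1.0  # nerve midpoint fires with the beat
        assert np.sum(labels == "tonic") > 0  # shells near the electrodes

    def test_current_steering_makes_nerve_tonic(self, forearm_fields):
        f = forearm_fields
        ix = np.argmin(np.abs(f["x"])); iy = np.argmin(np.abs(f["y"]))
        a1m, a2m = f["a1"][ix, iy], f["a2"][ix, iy]
        base = 1.5 * 1000.0 / (a1m + a2m)
        # same total current, split 1:9 between the pairs
        i1, i2 = 0.2 * base, 1.8 * base
        while abs(i1 * a1m - i2 * a2m) <= 1000.0:
            i1 *= 1.3
            i2 *= 1.3
        tot = tot_closed_form(ActivatingAmplitudePair(i1 * a1m, i2 * a2m, 1000.0))
        assert tot == 1.0

    def test_vtk_export_is_readable_text(self, forearm_fields, tmp_path):
        path = tmp_path / "field.vtk"
        write_vtk_structured_grid(forearm_fields["s1"], path)
        text = path.read_text()
        assert text.startswith("# vtk DataFile")
        assert "STRUCTURED_GRID" in text and "V_abs" in text


class TestDisc:
    def test_center_envelope_equal_between_modes(self):
        tis = disc_compare("tis_4_electrode")
        am = disc_compare("am_2_electrode")
        assert tis.center_envelope == pytest.approx(am.center_envelope, rel=0.01)

    def test_two_electrode_am_is_monomodal(self):
        am = disc_compare("am_2_electrode")
        assert np.allclose(am.modulation_index, 1.0)
        assert np.allclose(am.e_scaled_min, 0.0)

    def test_tis_is_bimodal(self):
        tis = disc_compare("tis_4_electrode")
        # interior points where the unmodulated floor beats the hotspot
        assert np.any(tis.e_scaled_min > tis.center_envelope)
        # but the centre itself is fully modulated (the index decays
        # away from the exact midpoint as the pair fields dealign)
        assert np.min(tis.modulation_index[0]) > 0.95

    def test_scaled_field_independent_of_physical_parameters(self):
        a = disc_compare("tis_4_electrode")
        b = disc_compare(
            "tis_4_electrode", per_channel_current=2.0, conductivity=2.0,
            diameter=2.0,
        )
        assert np.array_equal(a.e_scaled_max, b.e_scaled_max)
        assert np.array_equal(a.e_scaled_min, b.e_scaled_min)

    def test_matches_analytic_log_potential(self):
        # one diametral pair on the rim: V = -(1/pi) ln(|z-a|/|z-b|)
        # per unit (sigma * thickness * current), insulated elsewhere
        from tiskit.volume_conductor import _disc_solve, _TIS_PAIRS

        th_a, th_b = _TIS_PAIRS[2]
        V, rc, dr, dth = _disc_solve(80, 320, [(th_a, 1.0), (th_b, -1.0)])
        R = 0.5
        za = R * np.exp(1j * th_a)
        zb = R * np.exp(1j * th_b)
        th = (np.arange(320) + 0.5) * dth
        worst = 0.0
        for i in (10, 25, 40):
            for j in range(0, 320, 40):
                zz = rc[i] * np.exp(1j * th[j])
                ana = -(1 / np.pi) * np.log(np.abs(zz - za) / np.abs(zz - zb))
                num = V[i, j] - V[len(rc) // 2, 0]
                ref = -(1 / np.pi) * np.log(
                    np.abs(rc[len(rc) // 2] * np.exp(1j * th[0]) - za)
                    / np.abs(rc[len(rc) // 2] * np.exp(1j * th[0]) - zb)
                )
                worst = max(worst, abs((num - (ana - ref))))
        assert worst < 0.02

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            disc_compare("bipolar")
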