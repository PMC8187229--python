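"""Unit tests of the curvature program, phase field, energy cap and triggers."""

import numpy as np
import pytest

from ciliaswim import beat as bp
from ciliaswim import swimmer as sw
from ciliaswim.integrator import relax_damped


@pytest.fixture
def program():
    return bp.StrokeProgram(tau_p=6.0, tau_r=12.0)


class TestPhaseField:
    def test_origin_has_zero_phase(self):
        assert bp.phase_field(0.0, 0.0, bp.WavePattern(3, 1.7)) == 0.0

    def test_equator_neighbor_lag(self):
        # neighbors spaced 360/N_eq: lag k_phi * 360 / N_eq
        n_eq, k_phi = 7, 3
        pat = bp.WavePattern(k_phi, 0.0)
        lag = bp.phase_field(360.0 / n_eq, 0.0, pat) - bp.phase_field(0, 0, pat)
        assert lag == pytest.approx(k_phi * 360.0 / n_eq)

    def test_half_mode_gives_antiphase_neighbors(self):
        n_eq = 8
        pat = bp.WavePattern(n_eq // 2, 0.0)
        lag = bp.phase_field(360.0 / n_eq, 0.0, pat)
        assert lag == pytest.approx(180.0)

    def test_latitude_bounds_and_integer_wavenumber(self):
        with pytest.raises(ValueError):
            bp.phase_field(0.0, 90.0, bp.WavePattern(0, 1.0))
        with pytest.raises(ValueError):
            bp.WavePattern(0.5, 1.0)


class TestWaveClassification:
    @pytest.mark.parametrize("k_phi,chi,expected", [
        (0, -77.0, "antiplectic"),
        (0, 50.0, "symplectic"),
        (0, 0.0, "synchronous"),
        (1, 45.0, "dexioplectic"),
        (2, -45.0, "laeoplectic"),
    ])
    def test_classification(self, k_phi, chi, expected):
        assert bp.classify_wave(bp.WavePattern.from_chi(chi, k_phi)) == expected

    def test_chi_maps_to_k_theta_through_ring_spacing(self):
        pat = bp.WavePattern.from_chi(-77.0)
        assert pat.k_theta * 45.0 == pytest.approx(-77.0)


class TestCurvatureProgram:
    def test_power_stroke_stays_extended(self, program):
        L = 10.0
        s = np.linspace(0, L, 40)
        for u in (0.05, 0.4, 0.9):
            c = bp.target_curvature(s, bp.POWER, u, program, L)
            assert (np.abs(c) * L <= program.c0_L + 1e-12).all()
            assert program.c0_L < 1.0

    def test_recovery_bend_travels_monotonically_to_tip(self, program):
        L = 10.0
        s = np.linspace(0, L, 200)
        peaks = [s[np.argmax(np.abs(
            bp.target_curvature(s, bp.RECOVERY, u, program, L)))]
            for u in np.linspace(0.15, 0.85, 8)]
        # base -> tip, non-decreasing (the bump center saturates at the tip)
        assert (np.diff(peaks) >= -1e-12).all()
        assert peaks[0] < 0.5 * L and peaks[-1] > 0.9 * L

    def test_cycle_closes_smoothly(self, program):
        L = 10.0
        s = np.linspace(0, L, 50)
        end = bp.target_curvature(s, bp.RECOVERY, 1.0, program, L)
        start = bp.target_curvature(s, bp.POWER, 0.0, program, L)
        np.testing.assert_allclose(end, start, atol=1e-12)
        assert bp.base_angle(bp.RECOVERY, 1.0, program) == pytest.approx(
            bp.base_angle(bp.POWER, 0.0, program))

    def test_subsurface_segment_not_bent(self, program):
        c = bp.target_curvature(np.array([-0.5, -0.1]), bp.RECOVERY, 0.3,
                                program, 10.0)
        np.testing.assert_array_equal(c, 0.0)


class TestStrokeClock:
    def test_cycle_start_is_power_stroke(self, program):
        assert bp.stroke_clock_deterministic(0.0, 0.0, program) == (bp.POWER, 0.0)

    def test_half_cycle_phase_offset(self, program):
        stroke, u = bp.stroke_clock_deterministic(0.0, 180.0, program)
        # local time is tau_b/2 = 9 -> 3 into the recovery stroke
        assert stroke == bp.RECOVERY
        assert u == pytest.approx(3.0 / 12.0)

    def test_switch_at_power_stroke_end(self, program):
        eps = 1e-6
        assert bp.stroke_clock_deterministic(6.0 - eps, 0.0, program)[0] == bp.POWER
        assert bp.stroke_clock_deterministic(6.0 + eps, 0.0, program)[0] == bp.RECOVERY

    def test_beat_is_periodic(self, program):
        for t in (0.3, 5.0, 11.7):
            s1, u1 = bp.stroke_clock_deterministic(t, 37.0, program)
            s2, u2 = bp.stroke_clock_deterministic(t + program.tau_b, 37.0,
                                                   program)
            assert s1 == s2 and u1 == pytest.approx(u2)


class TestTriggers:
    rule = bp.TriggerRule(critical_curvature=0.15, max_axis_angle_deg=30.0)

    def straight(self):
        return np.linspace([0, 0, 1], [0, 0, 9], 12)

    def test_straight_radial_cilium_does_not_switch(self):
        normal = np.array([0.0, 0.0, 1.0])
        assert not bp.stroke_trigger_selforganized(
            bp.POWER, 0.5, self.straight(), normal, self.rule)
        assert not bp.stroke_trigger_selforganized(
            bp.RECOVERY, 0.5, self.straight(), normal, self.rule)

    def test_axis_angle_threshold_triggers_recovery(self):
        normal = np.array([0.0, 0.0, 1.0])
        ang = np.deg2rad(31.0)
        tilted = np.linspace([0, 0, 0], [8 * np.sin(ang), 0, 8 * np.cos(ang)],
                             12)
        tilted[:, 2] += 1.0
        assert bp.stroke_trigger_selforganized(bp.POWER, 0.5, tilted, normal,
                                               self.rule)

    def test_curled_cilium_triggers_power(self):
        # half circle of radius 4 -> curvature 0.25 > critical
        t = np.linspace(0, np.pi, 16)
        curled = np.stack([4 * np.sin(t), np.zeros_like(t), 4 * np.cos(t)],
                          axis=1)
        assert bp.stroke_trigger_selforganized(
            bp.RECOVERY, 0.5, curled, np.array([0.0, 0.0, 1.0]), self.rule)

    def test_fresh_stroke_cannot_retrigger(self):
        t = np.linspace(0, np.pi, 16)
        curled = np.stack([4 * np.sin(t), np.zeros_like(t), 4 * np.cos(t)],
                          axis=1)
        assert not bp.stroke_trigger_selforganized(
            bp.RECOVERY, 0.1, curled, np.array([0.0, 0.0, 1.0]), self.rule)

    def test_degenerate_axis_raises(self):
        pts = np.zeros((5, 3))
        with pytest.raises(ValueError, match="degenerate"):
            bp.stroke_trigger_selforganized(bp.POWER, 0.5, pts,
                                            np.array([0.0, 0.0, 1.0]),
                                            self.rule)


# --------------------------------------------------------------------------
# rest-length update and energy cap
# --------------------------------------------------------------------------

def one_cilium_assembly():
    mesh = sw.build_body(3.0, 42)
    c = sw.build_cilium(3.0, 4.125, 8, (0.0, 0.0))
    sw.anchor_cilium(c, mesh)
    return sw.assemble(mesh, [c])


class TestRestlengthUpdate:
    def test_zero_curvature_zero_sweep_is_identity(self):
        asm = one_cilium_assembly()
        prog = bp.StrokeProgram(tau_p=6, tau_r=12, c0_L=0.0, beta_max_deg=0.0)
        rest = asm.spring_rest.copy()
        w = bp.restlength_update(asm.positions, rest, asm.spring_i,
                                 asm.spring_j, asm.spring_k, asm.cilia[0],
                                 bp.POWER, 0.5, prog)
        np.testing.assert_allclose(rest, asm.spring_rest, atol=1e-12)
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_per_cilium_energy_injection_capped(self):
        """A jump that would add >> eps_max is scaled to add exactly eps_max."""
        asm = one_cilium_assembly()
        prog = bp.StrokeProgram(tau_p=6, tau_r=12, eps_max=1.0,
                                cap_granularity="cilium")
        rest = asm.spring_rest.copy()
        slot = asm.cilia[0]
        # jump straight into mid-recovery from the as-built configuration
        w = bp.restlength_update(asm.positions, rest, asm.spring_i,
                                 asm.spring_j, asm.spring_k, slot,
                                 bp.RECOVERY, 0.5, prog)
        assert w <= prog.eps_max + 1e-9
        assert w == pytest.approx(prog.eps_max, rel=1e-6)
        # the unconstrained update would have injected much more
        prog_big = bp.StrokeProgram(tau_p=6, tau_r=12, eps_max=1e9)
        rest2 = asm.spring_rest.copy()
        w_free = bp.restlength_update(asm.positions, rest2, asm.spring_i,
                                      asm.spring_j, asm.spring_k, slot,
                                      bp.RECOVERY, 0.5, prog_big)
        assert w_free > 3.0

    def test_per_bond_energy_injection_capped(self):
        """Default granularity: no single modulated spring gains > eps_max."""
        asm = one_cilium_assembly()
        prog = bp.StrokeProgram(tau_p=6, tau_r=12, eps_max=0.05)
        slot = asm.cilia[0]
        rest = asm.spring_rest.copy()
        idx = np.concatenate([slot.mod_springs, slot.anchor_springs])
        old = rest[idx].copy()
        d = np.linalg.norm(asm.positions[asm.spring_i[idx]]
                           - asm.positions[asm.spring_j[idx]], axis=1)
        e_before = 0.5 * asm.spring_k[idx] * (d - old) ** 2
        bp.restlength_update(asm.positions, rest, asm.spring_i, asm.spring_j,
                             asm.spring_k, slot, bp.RECOVERY, 0.5, prog)
        e_after = 0.5 * asm.spring_k[idx] * (d - rest[idx]) ** 2
        assert (e_after - e_before <= prog.eps_max + 1e-9).all()
        assert np.max(e_after - e_before) == pytest.approx(prog.eps_max,
                                                           rel=1e-6)

    def test_excessive_curvature_rejected(self):
        asm = one_cilium_assembly()
        slot = asm.cilia[0]
        prog = bp.StrokeProgram(tau_p=6, tau_r=12,
                                c1_L=3.0 / ((np.sqrt(3) / 2) * slot.side)
                                * slot.L / slot.L)
        prog.c1_L = 1.1 * slot.L / ((np.sqrt(3) / 2) * slot.side)
        with pytest.raises(ValueError, match="curvature too large"):
            bp.restlength_update(asm.positions, asm.spring_rest.copy(),
                                 asm.spring_i, asm.spring_j, asm.spring_k,
                                 slot, bp.RECOVERY, 0.5, prog)

    def test_imposed_constant_curvature_relaxes_to_circular_arc(self):
        """Free prism with constant target curvature relaxes to an arc of
        that curvature (within 5%) — validates the curvature->rest-length map."""
        c_target = 0.05
        cil = sw.build_cilium(8.0, 11.0, 26, (0.0, 0.0))
        pos = cil.flat_positions().copy()
        rest = cil.bond_rest0.copy()
        axial = cil.mod_axial * (1.0 - c_target * cil.mod_arm)
        rest[cil.mod_springs] = np.sqrt(axial ** 2 + cil.mod_trans ** 2)
        relax_damped(pos, cil.bonds[:, 0], cil.bonds[:, 1], cil.bond_k,
                     rest, total_time=400.0)
        center = pos.reshape(3, cil.n_beads, 3).mean(axis=0)
        kappa = _fitted_curvature(center)
        assert kappa == pytest.approx(c_target, rel=0.05)


def _fitted_curvature(points):
    """Algebraic circle fit (Kasa) in the plane of the bent centerline."""
    # project onto the dominant plane through the centroid
    q = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    xy = q @ vt[:2].T
    a = np.column_stack([2 * xy, np.ones(len(xy))])
    b = (xy ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    radius = np.sqrt(sol[2] + sol[0] ** 2 + sol[1] ** 2)
    return 1.0 / radius
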