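"""Z-values, D-values, the steady-state solver and its dynamic check."""

import numpy as np
import pytest

import climfate as cf
from climfate.chemicals import Chemical
from climfate.fugacity import FateSystem, compute_z_values
from climfate.world import Compartment


def _chem(logKAW=0.0, dU_AW=0.0, **kw):
    """Chemical with controllable air-water behaviour (triangle maintained)."""
    logKOA = kw.pop("logKOA", 6.0)
    dU_OW = kw.pop("dU_OW", -20.0)
    return Chemical(name="t", logKOW_ref=logKAW + logKOA, logKAW_ref=logKAW,
                    logKOA_ref=logKOA, dU_OW=dU_OW, dU_OA=dU_OW - dU_AW,
                    dU_AW=dU_AW, **kw)


class TestZValues:
    def test_pure_air_capacity(self):
        comp = Compartment("air", volume=1.0, temperature=298.15)
        z = compute_z_values(_chem(), comp, T=298.15)
        assert z.air == pytest.approx(4.034179016935928e-4, rel=1e-12)

    def test_equipartition_at_unit_kaw(self):
        comp = Compartment("freshwater", volume=1.0, temperature=283.0)
        z = compute_z_values(_chem(logKAW=0.0, dU_AW=0.0), comp)
        assert z.water == pytest.approx(z.air, rel=1e-12)

    def test_bulk_water_without_particles_is_pure_water(self):
        comp = Compartment("freshwater", volume=1.0, temperature=283.0,
                           frac_particles=0.0, f_oc=0.2)
        z = compute_z_values(_chem(logKAW=-2.0), comp)
        assert z.bulk == pytest.approx(z.water, rel=1e-12)

    def test_hydrophobic_soil_capacity_exceeds_water(self):
        comp = Compartment("soil", volume=1.0, temperature=288.0,
                           frac_air=0.2, frac_water=0.3, frac_solids=0.5,
                           f_oc=0.02)
        z = compute_z_values(_chem(logKAW=-2.0, logKOA=9.0), comp)
        assert z.bulk > z.water


class TestDValues:
    def test_rain_terms_vanish_without_rain(self, pcb):
        dry = cf.default_world(4, geometry={"rain_rate_m_h": 0.0})
        em = cf.build_emission_map(dry)
        a = cf.compute_d_values(pcb, dry, em,
                                cf.TransportParams(scavenging_ratio=2e5))
        b = cf.compute_d_values(pcb, dry, em,
                                cf.TransportParams(scavenging_ratio=0.0,
                                                   soil_water_runoff_frac=0.0))
        # without rain the scavenging ratio and rain-runoff are inert
        assert np.allclose(a.matrix, b.matrix)

    def test_gain_topology_follows_flows(self, world, pcb, emissions):
        sys = cf.compute_d_values(pcb, world, emissions)
        i = sys.index("ARC", "air")
        j = sys.index("NEU", "air")
        k = sys.index("SAF", "air")
        assert sys.matrix[i, j] < 0           # ARC gains from NEU
        assert sys.matrix[i, k] == 0.0        # no direct ARC-SAF link

    def test_degradation_d_linear_in_rate(self, world, emissions, pcb):
        from dataclasses import replace
        fast = replace(pcb, halflife_ref={m: v / 2 for m, v in
                                          pcb.halflife_ref.items()})
        a = cf.compute_d_values(pcb, world, emissions)
        b = cf.compute_d_values(fast, world, emissions)
        assert np.allclose(b.deg_d, 2.0 * a.deg_d, rtol=1e-12)


def _toy_system(matrix, emissions):
    n = len(emissions)
    return FateSystem(labels=[("R", f"m{i}") for i in range(n)],
                      matrix=np.array(matrix, dtype=float),
                      emissions=np.array(emissions, dtype=float),
                      z_bulk=np.ones(n), z_water=np.ones(n),
                      volumes=np.ones(n), deg_d=np.zeros(n),
                      burial_d=np.zeros(n))


class TestSteadyStateSolver:
    def test_single_compartment_closed_form(self):
        sys = _toy_system([[4.0]], [8.0])
        sys.deg_d = np.array([4.0])
        res = cf.solve_steady_state(sys)
        assert res.fugacity[0] == pytest.approx(2.0)
        assert res.mass_balance_residual < 1e-12

    def test_two_compartment_cramer_oracle(self, rng):
        # random exchange networks against the hand-written 2x2 inverse
        for _ in range(25):
            d12, d21 = rng.uniform(0.1, 5.0, 2)      # transfers
            l1, l2 = rng.uniform(0.1, 5.0, 2)        # degradation losses
            E = rng.uniform(0.0, 10.0, 2)
            A = np.array([[l1 + d12, -d21], [-d12, l2 + d21]])
            det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
            f_oracle = np.array([
                (E[0] * A[1, 1] - A[0, 1] * E[1]) / det,
                (A[0, 0] * E[1] - E[0] * A[1, 0]) / det])
            sys = _toy_system(A, E)
            sys.deg_d = np.array([l1, l2])
            res = cf.solve_steady_state(sys)
            assert np.allclose(res.fugacity, f_oracle, rtol=1e-10)

    def test_three_compartment_inversion_oracle(self, rng):
        for _ in range(25):
            gains = rng.uniform(0.0, 2.0, (3, 3))
            np.fill_diagonal(gains, 0.0)
            deg = rng.uniform(0.5, 3.0, 3)
            A = np.diag(deg + gains.sum(axis=0)) - gains
            E = rng.uniform(0.0, 5.0, 3)
            sys = _toy_system(A, E)
            sys.deg_d = deg.copy()
            res = cf.solve_steady_state(sys)
            assert np.allclose(res.fugacity, np.linalg.inv(A) @ E,
                               rtol=1e-9, atol=1e-12)
            assert res.mass_balance_residual < 1e-9

    def test_zero_emission_gives_zero_everywhere(self, world, pcb):
        sys = cf.compute_d_values(pcb, world, None)
        res = cf.solve_steady_state(sys)
        assert np.all(res.fugacity == 0.0)
        assert res.inventory == 0.0

    def test_singular_system_rejected(self):
        with pytest.raises(ValueError):
            cf.solve_steady_state(_toy_system([[1.0, -1.0], [-1.0, 1.0]],
                                              [1.0, 1.0]))


class TestFullWorldProperties:
    def test_mass_balance_closes(self, world, emissions, pcb):
        res = cf.solve_steady_state(cf.compute_d_values(pcb, world, emissions))
        assert res.mass_balance_residual < 1e-9
        assert np.all(res.fugacity >= 0.0)
        assert np.all(res.masses >= 0.0)

    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_linearity_in_emissions(self, world, emissions, pcb, c):
        base = cf.solve_steady_state(
            cf.compute_d_values(pcb, world, emissions))
        scaled = cf.solve_steady_state(
            cf.compute_d_values(pcb, world, emissions.scaled(c)))
        assert np.allclose(scaled.conc_bulk, c * base.conc_bulk, rtol=1e-12)

    def test_persistence_monotone_in_halflives(self, world, emissions, pcb):
        from dataclasses import replace
        slow = replace(pcb, halflife_ref={m: 2 * v for m, v in
                                          pcb.halflife_ref.items()})
        p_fast = cf.solve_steady_state(
            cf.compute_d_values(pcb, world, emissions)).p_ov
        p_slow = cf.solve_steady_state(
            cf.compute_d_values(slow, world, emissions)).p_ov
        assert p_slow > p_fast


class TestDynamicSolver:
    def _system(self):
        A = np.array([[2.0, -0.5], [-1.0, 1.5]])
        sys = _toy_system(A, [4.0, 1.0])
        sys.deg_d = np.array([1.0, 1.0])
        return sys

    def test_long_time_limit_matches_steady_state(self):
        sys = self._system()
        ss = cf.solve_steady_state(sys)
        traj = cf.dynamic_solve(sys, horizon=40.0, step=0.01)
        final = traj.iloc[-1, 1:].to_numpy(dtype=float)
        ss_mass = ss.conc_bulk * sys.volumes
        assert np.allclose(final, ss_mass, rtol=1e-3)

    def test_pure_decay_is_monotone_and_nonnegative(self):
        sys = self._system()
        sys.emissions = np.zeros(2)
        M0 = np.array([5.0, 3.0])
        traj = cf.dynamic_solve(sys, horizon=10.0, step=0.01, M0=M0)
        masses = traj.iloc[:, 1:].to_numpy(dtype=float)
        totals = masses.sum(axis=1)
        assert np.all(np.diff(totals) <= 1e-12)
        assert np.all(masses >= 0.0)
        assert totals[-1] < 1e-3 * totals[0]

    def test_oversized_step_rejected(self):
        with pytest.raises(ValueError, match="step"):
            cf.dynamic_solve(self._system(), horizon=10.0, step=5.0)


def test_result_export(world, emissions, pcb, tmp_path):
    res = cf.solve_steady_state(cf.compute_d_values(pcb, world, emissions))
    path = tmp_path / "fate.csv"
    from climfate.fugacity import export_result_csv
    export_result_csv(res, path)
    text = path.read_text()
    assert text.startswith("region,medium,fugacity_Pa")
    assert len(text.strip().splitlines()) == 22   # header + 20 + summary
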