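"""MD engine: integrator correctness, conservation laws, thermostat and
barostat behavior, neighbor-list equivalence, determinism."""

import math

import numpy as np
import pytest

from amphimem.constants import KB
from amphimem.engine import (Frame, IntegratorConfig, SingularityError, System,
                             berendsen_lambda, compute_forces,
                             kinetic_temperature, maxwell_velocities,
                             run_md, run_replicates)
from amphimem.forcefield import BondParam, NonbondedConfig
from amphimem.library import build_molecule_topology
from amphimem.topology import Bead, BeadTopology


def _two_bead_system(r, types=("P4", "P4"), charges=(0.0, 0.0), bond=None,
                     box=8.0):
    beads = [Bead(name=f"B{i}", bead_type=t,
                  charge=q, molecule=i) for i, (t, q) in
             enumerate(zip(types, charges))]
    bonds = [(0, 1, bond)] if bond else []
    top = BeadTopology(beads, bonds, [], [], ["a", "b"])
    pos = np.array([[1.0, 1.0, 1.0], [1.0 + r, 1.0, 1.0]])
    frame = Frame(pos, np.zeros_like(pos), np.full(3, float(box)))
    return System(top, frame)


class TestForces:
    def test_neutral_beads_beyond_cutoff_no_force(self):
        sys_ = _two_bead_system(1.3)
        forces, bd, _ = compute_forces(sys_.frame, sys_)
        assert np.allclose(forces, 0.0)
        assert bd["potential"] == 0.0

    def test_stretched_bond_closed_form(self):
        # kb = 1250, stretch 0.1 nm -> 125 kJ/mol/nm on each bead, opposed
        sys_ = _two_bead_system(0.57, types=("C1", "C1"),
                                bond=BondParam(0.47, 1250.0))
        forces, bd, _ = compute_forces(sys_.frame, sys_)
        assert forces[0, 0] == pytest.approx(125.0, rel=1e-9)
        assert forces[1, 0] == pytest.approx(-125.0, rel=1e-9)
        assert bd["bond"] == pytest.approx(6.25, rel=1e-9)

    def test_newtons_third_law_random_frame(self):
        rng = np.random.default_rng(0)
        beads = [Bead(name=f"B{i}", bead_type="P4", molecule=i)
                 for i in range(50)]
        top = BeadTopology(beads, [], [], [], ["w"] * 50)
        # non-overlapping positions on a jittered grid
        g = np.stack(np.meshgrid(*[np.arange(4)] * 3), -1).reshape(-1, 3)[:50]
        pos = g * 0.7 + 0.05 * rng.standard_normal((50, 3))
        sys_ = System(top, Frame(pos, np.zeros_like(pos), np.full(3, 2.8)))
        forces, _, _ = compute_forces(sys_.frame, sys_)
        assert np.abs(forces.sum(axis=0)).max() < 1e-8

    def test_overlapping_beads_raise_singularity(self):
        sys_ = _two_bead_system(1e-8)
        with pytest.raises(SingularityError):
            compute_forces(sys_.frame, sys_)

    def test_energy_breakdown_reports_terms_separately(self):
        # opposite charges (nonbonded) plus a separate stretched bond;
        # directly bonded pairs are excluded from the nonbonded sum
        beads = [Bead(name="A", bead_type="Qa", charge=-1.0, molecule=0),
                 Bead(name="B", bead_type="Qd", charge=1.0, molecule=1),
                 Bead(name="C", bead_type="C1", molecule=1)]
        top = BeadTopology(beads, [(1, 2, BondParam(0.47, 1250.0))], [], [],
                           ["a", "b"])
        pos = np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0], [2.07, 1.0, 1.0]])
        sys_ = System(top, Frame(pos, np.zeros_like(pos), np.full(3, 8.0)))
        _, bd, _ = compute_forces(sys_.frame, sys_)
        assert bd["coulomb"] < 0 and bd["lj"] != 0
        assert bd["bond"] == pytest.approx(6.25, rel=1e-9)
        assert bd["potential"] == pytest.approx(
            bd["bond"] + bd["lj"] + bd["coulomb"], rel=1e-12)

    def test_neighbor_list_matches_brute_force(self, water_box):
        """List-built forces equal all-pairs forces when the skin holds."""
        pairs_list = water_box.neighbor_list(list_cutoff=1.4)
        n = water_box.n_beads
        ii, jj = np.triu_indices(n, k=1)
        f_list, _, _ = compute_forces(water_box.frame, water_box, pairs_list)
        f_all, _, _ = compute_forces(water_box.frame, water_box,
                                     (ii.astype(np.int64), jj.astype(np.int64)))
        assert np.allclose(f_list, f_all, atol=1e-12)


class TestBerendsen:
    def test_lambda_fixed_point(self):
        cfg = IntegratorConfig()
        assert berendsen_lambda(310.0, cfg) == 1.0

    def test_lambda_closed_form(self):
        cfg = IntegratorConfig(dt=0.01, tau_T=1.0, T0=310.0)
        assert berendsen_lambda(620.0, cfg) == pytest.approx(
            math.sqrt(1 + 0.01 * (0.5 - 1)), rel=1e-12)  # sqrt(0.995)

    def test_lambda_monotone_decreasing(self):
        cfg = IntegratorConfig()
        ts = [100.0, 200.0, 310.0, 400.0, 800.0]
        lams = [berendsen_lambda(t, cfg) for t in ts]
        assert all(a > b for a, b in zip(lams, lams[1:]))

    def test_zero_temperature_skips_scaling(self):
        assert berendsen_lambda(0.0, IntegratorConfig()) == 1.0


class TestKineticTemperature:
    def test_zero_velocities(self):
        top = build_molecule_topology("water")
        fr = Frame(np.zeros((1, 3)), np.zeros((1, 3)), np.ones(3))
        assert kinetic_temperature(fr, top) == 0.0

    def test_maxwell_boltzmann_sampling(self):
        beads = [Bead(name="W", bead_type="P4", molecule=i) for i in range(1000)]
        top = BeadTopology(beads, [], [], [], ["w"] * 1000)
        v = maxwell_velocities(top, 310.0, seed=4)
        fr = Frame(np.zeros_like(v), v, np.ones(3))
        assert kinetic_temperature(fr, top) == pytest.approx(310.0, abs=15.0)

    def test_doubling_speeds_quadruples_temperature(self):
        beads = [Bead(name="W", bead_type="P4", molecule=i) for i in range(100)]
        top = BeadTopology(beads, [], [], [], ["w"] * 100)
        v = maxwell_velocities(top, 200.0, seed=1)
        t1 = kinetic_temperature(Frame(np.zeros_like(v), v, np.ones(3)), top)
        t2 = kinetic_temperature(Frame(np.zeros_like(v), 2 * v, np.ones(3)), top)
        assert t2 == pytest.approx(4 * t1, rel=1e-12)


class TestIntegrator:
    def test_zero_forces_zero_velocities_static(self):
        sys_ = _two_bead_system(2.0)
        p0 = sys_.frame.positions.copy()
        run_md(sys_, IntegratorConfig(ensemble="NVE"), 50, stride=50)
        assert np.allclose(sys_.frame.positions, p0)

    def test_zero_steps_returns_initial_frame_only(self):
        sys_ = _two_bead_system(2.0)
        traj = run_md(sys_, IntegratorConfig(), 0, stride=10)
        assert len(traj) == 1 and traj.frames[0].time == 0.0

    def test_single_bond_nve_matches_harmonic_oscillator(self):
        # 10^4 steps at dt = 0.01 ps: drift below 1% of potential amplitude
        sys_ = _two_bead_system(0.57, types=("C1", "C1"),
                                bond=BondParam(0.47, 1250.0),
                                box=20.0)
        cfg = IntegratorConfig(ensemble="NVE", nb_update_interval=10 ** 9)
        traj = run_md(sys_, cfg, 10_000, stride=10_000, log_interval=100)
        tot = traj.log["total"].to_numpy()
        amplitude = 6.25  # initial potential energy, kJ/mol
        assert np.abs(tot - tot[0]).max() < 0.01 * amplitude
        # analytic oscillator: amplitude envelope preserved; the
        # velocity-Verlet frequency error accumulates a small phase shift
        # over ~90 periods, so the pointwise tolerance is looser
        omega = math.sqrt(1250.0 / 36.0)
        r01 = sys_.frame.positions[1] - sys_.frame.positions[0]
        expected = 0.47 + 0.1 * math.cos(omega * sys_.frame.time)
        assert abs(np.linalg.norm(r01) - 0.47) <= 0.1 + 1e-6
        assert np.linalg.norm(r01) == pytest.approx(expected, abs=2e-2)

    def test_same_seed_bitwise_identical(self, water_box_state):
        top, frame = water_box_state
        outs = []
        for _ in range(2):
            sys_ = System(top, frame.copy())
            sys_.frame.velocities = maxwell_velocities(top, 310.0, 9)
            traj = run_md(sys_, IntegratorConfig(ensemble="NVT", seed=9),
                          200, stride=100)
            outs.append(traj.frames[-1].positions.copy())
        assert np.array_equal(outs[0], outs[1])

    def test_replicates_run_in_one_call(self, water_box_state):
        top, frame = water_box_state
        sys_ = System(top, frame.copy())
        trajs = run_replicates(sys_, IntegratorConfig(ensemble="NVT"), 50, 50,
                               seeds=range(3))
        assert len(trajs) == 3
        assert not np.array_equal(trajs[0].frames[-1].positions,
                                  trajs[1].frames[-1].positions)

    def test_nvt_heats_cold_start_toward_target(self, water_box_state):
        """A built (unminimized) box started at T=0 thermalizes to ~310 K."""
        top, frame = water_box_state
        sys_ = System(top, frame.copy())
        sys_.frame.velocities[:] = 0.0
        traj = run_md(sys_, IntegratorConfig(ensemble="NVT", seed=0),
                      3000, stride=3000, log_interval=200)
        final_t = traj.log["temperature"].iloc[-1]
        assert 240.0 < final_t < 380.0


class TestConservationAndCoupling:
    def test_nve_energy_conservation_on_bilayer(self, bilayer_system):
        traj = run_md(bilayer_system, IntegratorConfig(ensemble="NVE"),
                      1000, stride=1000, log_interval=100)
        tot = traj.log["total"].to_numpy()
        drift = np.abs(tot - tot[0]).max() / bilayer_system.n_beads
        assert drift < 0.01  # kJ/mol per bead

    def test_momentum_conservation_nve(self, bilayer_system):
        run_md(bilayer_system, IntegratorConfig(ensemble="NVE"), 300, stride=300)
        m = bilayer_system.masses
        vcom = np.average(bilayer_system.frame.velocities, axis=0, weights=m)
        assert np.abs(vcom).max() < 1e-8

    def test_thermostat_regulates_to_310(self, water_box):
        water_box.frame.velocities = maxwell_velocities(
            water_box.topology, 260.0, 5)
        traj = run_md(water_box, IntegratorConfig(ensemble="NVT", seed=5),
                      10_000, stride=10_000, log_interval=100)
        log = traj.log
        mean_t = log[log["time"] >= 50.0]["temperature"].mean()
        assert mean_t == pytest.approx(310.0, abs=15.0)

    def test_barostat_relaxes_water_box_pressure(self, water_box):
        water_box.frame.velocities = maxwell_velocities(
            water_box.topology, 310.0, 6)
        v0 = float(np.prod(water_box.frame.box))
        traj = run_md(water_box, IntegratorConfig(ensemble="NPT", seed=6),
                      8000, stride=8000, log_interval=100)
        log = traj.log
        late = log[log["time"] >= log["time"].iloc[-1] - 40.0]
        # mean within the fluctuation-limited band around the 1 bar target
        assert abs(late["pressure"].mean() - 1.0) < 30.0
        assert float(np.prod(water_box.frame.box)) != v0

    def test_semi_isotropic_box_scales_axes_independently(self, bilayer_system):
        cfg = IntegratorConfig(ensemble="NPT", semi_isotropic=True)
        b0 = bilayer_system.frame.box.copy()
        run_md(bilayer_system, IntegratorConfig(ensemble="NVT", seed=2),
               100, stride=100)
        run_md(bilayer_system, cfg, 500, stride=500)
        b1 = bilayer_system.frame.box
        assert b1[0] == b1[1]
        assert (b1[0] / b0[0]) != pytest.approx(b1[2] / b0[2], rel=1e-9)
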