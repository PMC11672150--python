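"""Coarse-grained model tests: topology construction, pair potential,
thermostat oracles and energy bookkeeping."""

import numpy as np
import pytest
from scipy import integrate

from idrscope import cgsim, ensana
from idrscope.cgsim import (
    ANGLE_K,
    BOND_K,
    BOND_R0,
    DEFAULT_DYE_SPECS,
    KB,
    CGTopology,
    FRETConstruct,
    HPSParameterSet,
    TopologyError,
    build_topology,
    debye_length_nm,
    fret_from_trajectory,
    pair_energy,
    potential_energy_reference,
    run_langevin,
    total_potential_energy,
)
from conftest import neutral_homopolymer


class TestTopology:
    def test_bare_chain_bead_and_bond_count(self):
        seq = "GSGSC" + "K" * 57 + "CTLGPR"
        top = build_topology(FRETConstruct(seq, 4, 62), with_dyes=False)
        assert top.n_beads == 68
        assert len(top.bonds) == 67
        assert len(top.angles) == 0

    def test_dye_attachment_counts_and_angles(self):
        seq = "GSGSC" + "G" * 57 + "CTLGPR"
        con = FRETConstruct(seq, 4, 62, dye1="Cy3B", dye2="CF660R")
        bare = build_topology(con, with_dyes=False)
        top = build_topology(con)
        n_dye = (len(DEFAULT_DYE_SPECS["Cy3B"]["beads"])
                 + len(DEFAULT_DYE_SPECS["CF660R"]["beads"]))
        assert top.n_beads == bare.n_beads + n_dye
        assert len(top.bonds) == len(bare.bonds) + n_dye
        # angle terms exist, and never center on a linker bead
        assert len(top.angles) > 0
        for _, b, _c in top.angles:
            assert top.bead_types[b] != "dye_lin"

    def test_dye_charges_match_spec(self):
        for name, net in (("Alexa488", -2), ("Alexa594", -2),
                          ("Cy3B", 0), ("CF660R", -1)):
            spec = DEFAULT_DYE_SPECS[name]
            assert sum(b["charge"] for b in spec["beads"]) == net

    def test_non_cys_site_warns(self):
        with pytest.warns(UserWarning, match="not Cys"):
            build_topology(FRETConstruct("GGGG", 0, 3))

    def test_yaml_roundtrip(self, tmp_path):
        seq = "GSGSC" + "A" * 10 + "CTLGPR"
        top = build_topology(FRETConstruct(seq, 4, 15))
        path = tmp_path / "topology.yaml"
        top.to_yaml(path)
        back = CGTopology.from_yaml(path)
        assert back.bead_types == top.bead_types
        np.testing.assert_array_equal(back.bonds, top.bonds)
        np.testing.assert_array_equal(back.angles, top.angles)
        np.testing.assert_allclose(back.angle_theta0, top.angle_theta0)
        assert back.dye_center_beads == top.dye_center_beads


class TestPairEnergy:
    def test_lj_minimum_at_full_stickiness(self, default_params):
        sig = default_params.sigma["F"]
        rmin = 2 ** (1 / 6) * sig
        u = pair_energy(rmin, "F", "F", default_params)
        assert u == pytest.approx(-default_params.epsilon, rel=1e-12)

    def test_zero_stickiness_is_pure_wca(self, neutral_params):
        sig = neutral_params.sigma["A"]
        r = np.linspace(0.8 * sig, 3.0, 200)
        u = pair_energy(r, "A", "A", neutral_params)
        assert np.all(u >= -1e-12)
        assert np.all(np.abs(u[r >= 2 ** (1 / 6) * sig]) < 1e-12)

    @pytest.mark.parametrize("lam", [0.0, 0.3, 0.7, 1.0, 1.5])
    def test_continuity_at_crossover(self, lam):
        p = HPSParameterSet.default()
        p.lam["A"] = lam
        rmin = 2 ** (1 / 6) * p.sigma["A"]
        left = pair_energy(rmin * (1 - 1e-13), "A", "A", p)
        right = pair_energy(rmin * (1 + 1e-13), "A", "A", p)
        assert abs(left - right) < 1e-12

    def test_zero_distance_rejected(self, default_params):
        with pytest.raises(ValueError):
            pair_energy(0.0, "A", "A", default_params)

    def test_debye_length_value(self):
        # 1:1 electrolyte at 300 K: ~0.78 nm at 150 mM
        assert debye_length_nm(150.0) == pytest.approx(0.795, abs=0.02)


class TestLangevin:
    def test_equipartition_single_bead(self, neutral_params):
        top = neutral_homopolymer(1)
        traj = run_langevin(top, neutral_params, n_steps=1_000_000, seed=2,
                            stride=100)
        ke = traj.kinetic.mean()
        assert ke == pytest.approx(1.5 * KB * 300.0, rel=0.02)

    def test_harmonic_dimer_bond_distribution(self, neutral_params):
        """Bond length follows the Boltzmann distribution of the 481.4
        kJ/nm^2/mol spring at 300 K: P(r) ~ r^2 exp(-k(r-r0)^2/2kT)."""
        top = neutral_homopolymer(2)
        traj = run_langevin(top, neutral_params, n_steps=400_000, seed=3,
                            stride=20)
        r = np.linalg.norm(traj.frames[:, 1] - traj.frames[:, 0], axis=1)
        kT = KB * 300.0
        f = lambda x: x ** 2 * np.exp(-BOND_K * (x - BOND_R0) ** 2 / (2 * kT))
        z, _ = integrate.quad(f, 0, 2)
        m1, _ = integrate.quad(lambda x: x * f(x), 0, 2)
        m2, _ = integrate.quad(lambda x: x * x * f(x), 0, 2)
        mean_exact = m1 / z
        std_exact = np.sqrt(m2 / z - mean_exact ** 2)
        assert r.mean() == pytest.approx(mean_exact, rel=0.01)
        assert r.std() == pytest.approx(std_exact, rel=0.05)

    def test_identical_seed_bit_identical(self, neutral_params):
        top = neutral_homopolymer(10)
        t1 = run_langevin(top, neutral_params, n_steps=20_000, seed=7,
                          stride=100)
        t2 = run_langevin(top, neutral_params, n_steps=20_000, seed=7,
                          stride=100)
        assert np.array_equal(t1.frames, t2.frames)

    def test_seed_mandatory(self, neutral_params):
        with pytest.raises(ValueError, match="seed"):
            run_langevin(neutral_homopolymer(5), neutral_params,
                         n_steps=100, seed=None)

    def test_energy_bookkeeping_matches_double_loop(self, default_params):
        """Simulator potential equals an independent O(N^2) evaluation."""
        seq = "GSGSC" + "KEKAGE" * 3 + "CTLGPR"
        top = build_topology(FRETConstruct(seq, 4, len(seq) - 6))
        traj = run_langevin(top, default_params, n_steps=20_000, seed=5,
                            stride=2000)
        for frame, e_sim in zip(traj.frames, traj.potential):
            e_kernel = total_potential_energy(frame, top, default_params)
            e_ref = potential_energy_reference(frame, top, default_params)
            assert e_kernel == pytest.approx(e_ref, rel=1e-8)
            assert e_sim == pytest.approx(e_ref, rel=1e-8)

    def test_polyelectrolyte_expands_vs_neutral_twin(self, neutral_params):
        """All +1 charges at 165 mM ionic strength swell the chain."""
        top_q = neutral_homopolymer(40, aa="K")
        top_q.bead_charges[:] = 1.0
        top_0 = neutral_homopolymer(40, aa="K")
        r_q = run_langevin(top_q, neutral_params, n_steps=600_000, seed=8,
                           stride=500)
        r_0 = run_langevin(top_0, neutral_params, n_steps=600_000, seed=8,
                           stride=500)
        ree_q = ensana.shape_metrics(r_q.equilibrated())["Ree"]
        ree_0 = ensana.shape_metrics(r_0.equilibrated())["Ree"]
        assert ree_q > 1.15 * ree_0


class TestFRETObservable:
    def test_distance_at_r0_gives_half(self):
        frames = np.zeros((5, 2, 3))
        frames[:, 1, 0] = 6.0
        e_mean, e = fret_from_trajectory(frames, (0, 1), 6.0)
        assert e_mean == pytest.approx(0.5)

    def test_two_frame_mean(self):
        frames = np.zeros((2, 2, 3))
        frames[0, 1, 0] = 3.0          # 0.5 R0
        frames[1, 1, 0] = 12.0         # 2 R0
        e_mean, e = fret_from_trajectory(frames, (0, 1), 6.0)
        assert e[0] == pytest.approx(1 / (1 + 0.5 ** 6))
        assert e[1] == pytest.approx(1 / (1 + 2.0 ** 6))
        assert e_mean == pytest.approx(0.5, abs=1e-4)

    def test_efficiency_decreases_with_chain_length(self, neutral_params):
        """Athermal homopolymers: longer chains transfer less."""
        means = []
        for n in (20, 40, 60):
            top = neutral_homopolymer(n)
            traj = run_langevin(top, neutral_params, n_steps=400_000,
                                seed=10 + n, stride=500)
            e_mean, _ = fret_from_trajectory(traj.equilibrated(), (0, n - 1),
                                             6.0)
            means.append(e_mean)
        assert means[0] > means[1] > means[2]

    def test_missing_dye_beads_error(self):
        with pytest.raises(ValueError):
            fret_from_trajectory(np.zeros((1, 2, 3)), None, 6.0)
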