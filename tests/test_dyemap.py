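"""Dye attachment tests: clash logic, enumeration oracle, convergence."""

import numpy as np
import pytest
from scipy import integrate

from idrscope import dyemap, synthdata
from idrscope.dyemap import (
    AttachmentSite,
    RotamerLibrary,
    attach_dyes,
    ensemble_efficiencies,
    frame_mean_efficiency,
    make_synthetic_library,
)


def _extended_chain(n=60, spacing=0.38):
    """Straight bead chain along x; sites at both ends pointing apart."""
    xyz = np.zeros((n, 3))
    xyz[:, 0] = np.arange(n) * spacing
    site1 = AttachmentSite(cb_index=1, sg_index=0,
                           residue_atoms=np.array([0, 1]))
    site2 = AttachmentSite(cb_index=n - 2, sg_index=n - 1,
                           residue_atoms=np.array([n - 2, n - 1]))
    return xyz, site1, site2


class TestAttachment:
    def test_fully_extended_chain_all_trials_succeed(self):
        xyz, s1, s2 = _extended_chain()
        lib = make_synthetic_library("dye", 5, seed=1, spread=0.1)
        res = attach_dyes(xyz, s1, s2, lib, lib, seed=3)
        assert res.accepted
        assert res.n_success_site1 == 50
        assert res.n_success_site2 == 50

    def test_buried_site_rejects_frame(self):
        """Dense decoy cluster around one site clashes every rotamer."""
        xyz, s1, s2 = _extended_chain(20)
        rng = np.random.default_rng(4)
        cage = xyz[0] + rng.normal(scale=0.3, size=(300, 3))
        frame = np.vstack([xyz, cage])
        lib = make_synthetic_library("dye", 5, seed=1)
        res = attach_dyes(frame, s1, s2, lib, lib, seed=3)
        assert not res.accepted
        assert res.n_success_site1 == 0

    def test_distance_multiset_equals_exhaustive_enumeration(self):
        """Toy 3-rotamer library on two frames: accepted distances equal the
        brute-force enumeration over all rotamer pairs."""
        lib = make_synthetic_library("dye", 3, seed=2, spread=0.2)
        for frame_seed in (0, 1):
            xyz, s1, s2 = _extended_chain(40)
            xyz = xyz + np.random.default_rng(frame_seed).normal(
                scale=0.01, size=xyz.shape)
            res = attach_dyes(xyz, s1, s2, lib, lib, seed=5,
                              n_trials=200, min_success=1)
            # brute force: every rotamer pair, same clash rules
            from idrscope.dyemap import _attachment_rotation, _clashes, _place

            expected = []
            for site, other in ((s1, s2),):
                rot1 = _attachment_rotation(xyz[s1.cb_index], xyz[s1.sg_index])
                rot2 = _attachment_rotation(xyz[s2.cb_index], xyz[s2.sg_index])
                env1 = np.delete(xyz, s1.residue_atoms, axis=0)
                env2 = np.delete(xyz, s2.residue_atoms, axis=0)
                ok1 = [r for r in lib.rotamers
                       if not _clashes(_place(r, rot1, xyz[s1.sg_index]),
                                       env1, 0.5)]
                ok2 = [r for r in lib.rotamers
                       if not _clashes(_place(r, rot2, xyz[s2.sg_index]),
                                       env2, 0.5)]
                for r1 in ok1:
                    p1 = _place(r1, rot1, xyz[s1.sg_index])
                    for r2 in ok2:
                        p2 = _place(r2, rot2, xyz[s2.sg_index])
                        if _clashes(p1, p2, 0.5):
                            continue
                        expected.append(np.linalg.norm(
                            p1[r1.center_index] - p2[r2.center_index]))
            assert sorted(np.round(res.distances, 10)) == \
                sorted(np.round(expected, 10))

    def test_missing_attachment_atom_raises(self):
        xyz, s1, s2 = _extended_chain(10)
        s1.cb_index = 99
        lib = make_synthetic_library("dye", 2, seed=1)
        with pytest.raises(ValueError, match="missing"):
            attach_dyes(xyz, s1, s2, lib, lib, seed=1)

    def test_deterministic_under_seed(self):
        xyz, s1, s2 = _extended_chain()
        lib = make_synthetic_library("dye", 8, seed=6, spread=0.3)
        r1 = attach_dyes(xyz, s1, s2, lib, lib, seed=11)
        r2 = attach_dyes(xyz, s1, s2, lib, lib, seed=11)
        np.testing.assert_array_equal(r1.distances, r2.distances)

    def test_acceptance_rate_non_increasing_in_clash_radius(self):
        rng = np.random.default_rng(12)
        frames, _ = synthdata.gen_gaussian_chain(30, 40, seed=12)
        lib = make_synthetic_library("dye", 6, seed=7, spread=0.3)
        s1 = AttachmentSite(1, 0, np.array([0, 1]))
        s2 = AttachmentSite(38, 39, np.array([38, 39]))
        rates = []
        for radius in (0.2, 0.4, 0.6):
            acc = sum(
                attach_dyes(f, s1, s2, lib, lib, seed=20,
                            clash_radius=radius, min_success=5).accepted
                for f in frames)
            rates.append(acc)
        assert rates[0] >= rates[1] >= rates[2]


class TestFrameEfficiency:
    def test_all_distances_at_r0(self):
        assert frame_mean_efficiency(np.full(7, 6.0), 6.0) == pytest.approx(0.5)

    def test_two_distance_arithmetic(self):
        e = frame_mean_efficiency(np.array([3.0, 12.0]), 6.0)
        assert e == pytest.approx(0.5 * (1 / (1 + 0.5 ** 6)
                                         + 1 / (1 + 2.0 ** 6)))

    def test_bounds(self):
        rng = np.random.default_rng(3)
        e = frame_mean_efficiency(rng.uniform(0.5, 20.0, size=100), 6.0)
        assert 0.0 < e < 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            frame_mean_efficiency(np.array([]))


def test_sites_from_multi_model_pdb(tmp_path):
    """Attachment sites extracted from a programmatically written 3-model
    PDB of two Cys residues."""
    lines = []
    for model in range(1, 4):
        lines.append(f"MODEL     {model}")
        serial = 1
        for r in range(2):
            x0 = 10.0 * r + model * 0.3
            for name, off in (("N", 0.0), ("CA", 1.0), ("CB", 2.0),
                              ("SG", 3.5)):
                el = "S" if name == "SG" else "C"
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} CYS A{r + 1:4d}    "
                    f"{x0 + off:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00"
                    f"           {el}")
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    pdb = tmp_path / "toy.pdb"
    pdb.write_text("\n".join(lines) + "\n")

    frames, s1, s2 = dyemap.sites_from_pdb(pdb, 0, 1)
    assert frames.shape == (3, 8, 3)
    assert (s1.cb_index, s1.sg_index) == (2, 3)
    assert (s2.cb_index, s2.sg_index) == (6, 7)
    # mdtraj reports nm; CB->SG separation is 1.5 A = 0.15 nm
    d = np.linalg.norm(frames[0, s1.sg_index] - frames[0, s1.cb_index])
    assert d == pytest.approx(0.15, abs=1e-6)


def test_gaussian_chain_ensemble_converges_to_analytical_average():
    """Point-like dyes on a Gaussian chain: dyemap ensemble <E> approaches
    the closed-form average over the Gaussian end-to-end density."""
    n_beads, b = 50, 0.38
    frames, truth = synthdata.gen_gaussian_chain(4000, n_beads, seed=31,
                                                 bond_nm=b)
    lib = make_synthetic_library("dye", 4, seed=8, n_atoms=2,
                                 reach_nm=0.05, spread=0.005)
    s1 = AttachmentSite(1, 0, np.array([0, 1]))
    s2 = AttachmentSite(n_beads - 2, n_beads - 1,
                        np.array([n_beads - 2, n_beads - 1]))
    idx, effs = ensemble_efficiencies(frames, s1, s2, lib, lib, seed=100,
                                      R0_nm=6.0, min_success=2,
                                      clash_radius=0.05)
    assert len(effs) > 3500

    R2 = truth["R2_exact"]
    # Gaussian end-to-end density: P(r) = 4 pi r^2 (3/(2 pi R2))^{3/2}
    #                              exp(-3 r^2 / (2 R2))
    def p(r):
        return (4 * np.pi * r ** 2 * (3 / (2 * np.pi * R2)) ** 1.5
                * np.exp(-3 * r ** 2 / (2 * R2)))

    e_exact, _ = integrate.quad(lambda r: p(r) / (1 + (r / 6.0) ** 6),
                                0, np.inf)
    assert float(np.mean(effs)) == pytest.approx(e_exact, abs=0.01)
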