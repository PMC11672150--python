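"""Ensemble analytics against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from idrscope import ensana, synthdata
from idrscope.ensana import (
    contact_map,
    contact_network,
    guinier_rg,
    internal_scaling,
    lin_concordance,
    regression_suite,
    saxs_profile,
    scaled_distance_map,
    shape_metrics,
)


def _rod_frames(n_frames=20, n_beads=30, b=0.38):
    frames, _ = synthdata.gen_rod(n_frames, n_beads, seed=2, bond_nm=b)
    return frames


class TestInternalScaling:
    def test_rod_has_unit_exponent(self):
        fit = internal_scaling(_rod_frames())
        assert fit.nu == pytest.approx(1.0, abs=1e-6)
        assert fit.A0 == pytest.approx(0.38, abs=1e-6)

    def test_gaussian_chain_half_exponent(self, gauss_frames):
        frames, _ = gauss_frames
        fit = internal_scaling(frames)
        assert fit.nu == pytest.approx(0.50, abs=0.02)

    def test_duplicated_frames_weighting_consistency(self):
        frames, _ = synthdata.gen_gaussian_chain(200, 20, seed=3)
        doubled = np.concatenate([frames, frames[:100]])
        w = np.concatenate([np.ones(200), np.ones(100)])
        w2 = np.concatenate([2 * np.ones(100), np.ones(100), np.zeros(100)])
        a = internal_scaling(doubled, w / w.sum())
        # same multiset expressed through weights on the first copy
        b = internal_scaling(doubled, w2 / w2.sum())
        np.testing.assert_allclose(a.distances, b.distances, rtol=1e-12)

    def test_window_too_small_rejected(self):
        frames, _ = synthdata.gen_gaussian_chain(10, 8, seed=1)
        with pytest.raises(ValueError, match="fewer than 3"):
            internal_scaling(frames, fit_window=(3, 4))


class TestScaledDistanceMap:
    def test_self_normalization_near_unity(self, gauss_frames):
        frames, _ = gauss_frames
        fit = internal_scaling(frames)
        m = scaled_distance_map(frames, fit=fit, min_spacing=10)
        vals = m[np.isfinite(m)]
        assert np.nanmax(np.abs(vals - 1.0)) < 0.05
        assert np.nanmean(np.abs(vals - 1.0)) < 0.02

    def test_symmetry_and_masking(self, gauss_frames):
        frames, _ = gauss_frames
        fit = internal_scaling(frames)
        m = scaled_distance_map(frames, fit=fit, min_spacing=10)
        np.testing.assert_allclose(m, m.T, atol=1e-12, equal_nan=True)
        i, j = np.indices(m.shape)
        assert np.all(np.isnan(m[np.abs(i - j) < 10]))

    def test_planted_compact_segment_detected(self):
        """A harmonically collapsed interior segment shows scaled distances
        below one exactly inside its block."""
        rng = np.random.default_rng(8)
        frames, _ = synthdata.gen_gaussian_chain(2000, 40, seed=8)
        # collapse residues 15..25 toward their centroid
        seg = slice(15, 26)
        frames = frames.copy()
        centroid = frames[:, seg].mean(axis=1, keepdims=True)
        frames[:, seg] = centroid + 0.25 * (frames[:, seg] - centroid)
        fit = internal_scaling(frames)
        m = scaled_distance_map(frames, fit=fit, min_spacing=5)
        inside = m[16, 24]
        outside = m[2, 32]
        assert inside < 0.8 < outside

    def test_requires_fit(self, gauss_frames):
        with pytest.raises(ValueError, match="fit"):
            scaled_distance_map(gauss_frames[0], fit=None)


class TestContacts:
    def test_bonded_neighbors_always_in_contact(self):
        frames = _rod_frames()
        cmap = contact_map(frames, threshold=0.4)
        np.testing.assert_allclose(np.diag(cmap, k=1), 1.0, atol=1e-12)

    def test_rod_has_no_long_range_contacts(self):
        frames = _rod_frames()
        cmap = contact_map(frames, threshold=1.0)
        i, j = np.indices(cmap.shape)
        assert np.all(cmap[np.abs(i - j) > 3] == 0.0)

    def test_matches_brute_force_scan(self):
        frames, _ = synthdata.gen_gaussian_chain(100, 15, seed=4)
        w = np.random.default_rng(0).dirichlet(np.ones(100))
        cmap = contact_map(frames, weights=w, threshold=0.8)
        n = frames.shape[1]
        ref = np.zeros((n, n))
        for f in range(100):                       # O(N^2 * frames) oracle
            for a in range(n):
                for b in range(n):
                    if np.linalg.norm(frames[f, a] - frames[f, b]) < 0.8:
                        ref[a, b] += w[f]
        np.testing.assert_allclose(cmap, ref / w.sum(), atol=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown contact mode"):
            contact_map(_rod_frames(), mode="voronoi")


class TestContactNetwork:
    def test_uniform_map_gives_complete_far_graph(self):
        n = 12
        cmap = np.full((n, n), 0.5)
        g = contact_network(cmap, edge_fraction=0.35, min_separation=3)
        expected_edges = sum(1 for a in range(n) for b in range(a + 3, n))
        assert g.number_of_edges() == expected_edges

    def test_single_dominant_pair(self):
        n = 10
        cmap = np.zeros((n, n))
        cmap[1, 8] = cmap[8, 1] = 0.6
        g = contact_network(cmap)
        assert list(g.edges()) == [(1, 8)]

    def test_edge_count_monotone_in_fraction(self):
        rng = np.random.default_rng(5)
        cmap = rng.uniform(size=(20, 20))
        cmap = (cmap + cmap.T) / 2
        counts = [contact_network(cmap, f).number_of_edges()
                  for f in (0.1, 0.35, 0.6, 0.9)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_residue_class_metadata(self):
        cmap = np.full((4, 4), 0.2)
        g = contact_network(cmap, sequence="GRDP", min_separation=3)
        assert g.nodes[0]["residue_class"] == "glycine"
        assert g.nodes[1]["residue_class"] == "basic"


class TestShapeMetrics:
    def test_rod_asphericity_one(self):
        m = shape_metrics(_rod_frames())
        assert m["asphericity"] == pytest.approx(1.0, abs=1e-9)

    def test_cube_corners_isotropic(self):
        corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1)
                            for k in (0, 1)], dtype=float)
        m = shape_metrics(corners[None, :, :])
        assert m["asphericity"] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_chain_size_ratio(self, gauss_frames):
        frames, _ = gauss_frames
        m = shape_metrics(frames)
        assert (m["Ree"] / m["Rg"]) ** 2 == pytest.approx(6.0, abs=0.2)


class TestSAXS:
    def test_two_scatterer_closed_form(self):
        d = 2.5
        frames = np.array([[[0.0, 0, 0], [d, 0, 0]]])
        q = np.linspace(0.0, 5.0, 40)
        prof = saxs_profile(frames, q_grid=q)
        qd = q * d
        with np.errstate(invalid="ignore"):
            expected = (2 + 2 * np.where(qd > 0, np.sin(qd) / np.where(qd > 0, qd, 1), 1.0)) / 4
        np.testing.assert_allclose(prof["I_over_I0"], expected, atol=1e-10)

    def test_normalized_at_zero(self, gauss_frames):
        prof = saxs_profile(gauss_frames[0][:200], q_grid=np.array([0.0, 0.1]))
        assert prof["I_over_I0"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_guinier_rg_matches_gyration_tensor(self):
        """Compact globular ensemble: Guinier-slope Rg agrees with the
        gyration-tensor Rg within 3%."""
        rng = np.random.default_rng(6)
        frames = rng.normal(scale=0.5, size=(300, 40, 3))
        m = shape_metrics(frames)
        q = np.linspace(0.02, 2.0, 120)
        prof = saxs_profile(frames, q_grid=q)
        assert guinier_rg(prof, qmax_rg=0.9) == pytest.approx(m["Rg"], rel=0.03)

    def test_monotone_decrease_at_small_q(self, gauss_frames):
        prof = saxs_profile(gauss_frames[0][:200],
                            q_grid=np.linspace(0.0, 0.8, 20))
        assert np.all(np.diff(prof["I_over_I0"]) < 0)

    def test_empty_q_grid_rejected(self, gauss_frames):
        with pytest.raises(ValueError, match="q_grid"):
            saxs_profile(gauss_frames[0][:10], q_grid=np.array([]))


class TestRegression:
    def test_exact_linear_function(self):
        rng = np.random.default_rng(7)
        x = pd.DataFrame({"a": rng.uniform(size=16)})
        y = 3.0 * x["a"] - 1.0
        res = regression_suite(x, y, max_order=1)
        assert res.loc[0, "rho2"] == pytest.approx(1.0, abs=1e-12)

    def test_concordance_penalizes_offset(self):
        x = np.linspace(0, 1, 16)
        assert lin_concordance(x, x) == pytest.approx(1.0)
        assert lin_concordance(x, x + 0.1) < 1.0

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(16, 3)), columns=list("abc"))
        y = rng.normal(size=16)
        res = regression_suite(X, y, max_order=3)
        row = res[res.features == "a+b+c"].iloc[0]
        A = np.column_stack([np.ones(16), X.to_numpy()])
        beta = np.linalg.pinv(A) @ y
        fitted = A @ beta
        rho2 = 1 - np.sum((y - fitted) ** 2) / np.sum((y - y.mean()) ** 2)
        assert row["rho2"] == pytest.approx(rho2, abs=1e-10)

    def test_leave_one_out_distribution_shape(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"a": rng.uniform(size=16)})
        y = X["a"] + rng.normal(scale=0.1, size=16)
        res = regression_suite(X, y, max_order=1)
        assert len(res.loc[0, "loo_rho2"]) == 16
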