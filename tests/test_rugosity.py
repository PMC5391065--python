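"""Cross-sections and virtual-chain rugosity against analytic oracles."""

import numpy as np
import pytest

from oracles import (extendible_R_oracle, fixed_R_oracle,
                     semicircle_polyline, sinusoid_polyline)
from conftest import make_contour
from reefc import (ChainError, ContourError, chain_grid, cross_section,
                   divide_equidistant, rugosity_extendible, rugosity_fixed,
                   triplet_average)
from reefc.surfaces import as_model, hemisphere, plane, sinusoid


class TestCrossSection:
    def test_flat_mesh_straight_contour(self):
        mesh, _ = plane(side=2.0, mesh_step=0.1, z0=0.1)
        c = cross_section(mesh, (0.0, 1.0), (2.0, 1.0))
        assert np.allclose(c.points[:, 2], 0.1, atol=1e-12)
        assert np.allclose(c.points[:, 1], 1.0, atol=1e-12)
        assert c.chord_extent() == pytest.approx(2.0, abs=1e-9)
        # stations strictly ordered along the cut for a single-valued plane
        assert (np.diff(c.points[:, 0]) > 0).all()

    def test_hemisphere_section_is_semicircle(self):
        r = 0.5
        mesh, _ = hemisphere(side=2.0, mesh_step=0.005, radius=r)
        c = cross_section(mesh, (0.0, 1.0), (2.0, 1.0))
        on_bump = np.abs(c.points[:, 0] - 1.0) < r - 0.02
        d = np.hypot(c.points[on_bump, 0] - 1.0, c.points[on_bump, 2])
        # grid-interpolated cap: sagitta error ~ step^2 / (2 r)
        assert np.abs(d - r).max() < 5e-4

    def test_plane_missing_mesh(self):
        mesh, _ = plane(side=2.0, mesh_step=0.1)
        with pytest.raises(ContourError):
            cross_section(mesh, (0.0, 5.0), (2.0, 5.0))

    def test_overhang_keeps_highest_branch(self):
        # two stacked horizontal sheets: the envelope must ride the upper
        # one where they overlap
        lower, _ = plane(side=2.0, mesh_step=0.25, z0=0.0)
        upper, _ = plane(side=1.0, mesh_step=0.25, z0=0.3)
        shifted = upper.vertices + np.array([0.5, 0.5, 0.0])
        from reefc import TriMesh
        merged = TriMesh(
            np.vstack([lower.vertices, shifted]),
            np.vstack([lower.faces, upper.faces + lower.n_vertices]))
        c = cross_section(merged, (0.0, 1.0), (2.0, 1.0))
        x, z = c.points[:, 0], c.points[:, 2]
        assert np.allclose(z[(x > 0.51) & (x < 1.49)], 0.3, atol=1e-9)
        assert np.allclose(z[(x < 0.49) | (x > 1.51)], 0.0, atol=1e-9)


class TestDivideEquidistant:
    def test_straight_metre(self):
        pts = np.column_stack([np.linspace(0, 1, 11), np.zeros(11),
                               np.zeros(11)])
        nodes, n_full = divide_equidistant(make_contour(pts), 0.02)
        assert n_full == 50
        assert len(nodes) == 51  # endpoint coincides with the last node
        np.testing.assert_allclose(np.linalg.norm(np.diff(nodes, axis=0),
                                                  axis=1), 0.02, atol=1e-12)

    def test_semicircle_matches_bisection_marcher(self):
        pts = semicircle_polyline(0.5, 100_000)
        nodes, n_full = divide_equidistant(make_contour(pts), 0.02)
        from oracles import chord_march_oracle
        o_nodes, o_full = chord_march_oracle(pts, 0.02)
        assert n_full == o_full
        np.testing.assert_allclose(nodes[:o_full + 1], o_nodes, atol=1e-9)

    def test_link_exceeds_extent(self):
        pts = np.array([[0, 0, 0], [1, 0, 0.0]])
        with pytest.raises(ChainError):
            divide_equidistant(make_contour(pts), 2.5)


class TestExtendible:
    def test_flat_contour_R_is_one(self):
        pts = np.column_stack([np.linspace(0, 2, 21), np.zeros(21),
                               np.full(21, 0.2)])
        chain = rugosity_extendible(make_contour(pts), 0.02)
        assert chain.R == pytest.approx(1.0, abs=1e-9)

    def test_semicircle_matches_oracle(self):
        pts = semicircle_polyline(0.5, 100_000)
        chain = rugosity_extendible(make_contour(pts), 0.02)
        assert chain.R == pytest.approx(extendible_R_oracle(pts, 0.02),
                                        abs=1e-6)
        assert chain.undraped_length == pytest.approx(1.0, abs=1e-9)

    def test_sinusoid_matches_oracle(self):
        pts = sinusoid_polyline(2.0, 0.1, 0.4, 100_000)
        chain = rugosity_extendible(make_contour(pts), 0.02)
        assert chain.R == pytest.approx(extendible_R_oracle(pts, 0.02),
                                        abs=1e-6)
        assert chain.R > 1.3  # strongly corrugated profile

    def test_degenerate_contour(self):
        pts = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 0.0]])
        with pytest.raises(ChainError):
            rugosity_extendible(make_contour(pts), 0.02)

    def test_relief_monotonicity(self):
        # scaling Z-relief up never decreases extendible R
        Rs = []
        for amp in (0.02, 0.05, 0.1, 0.2):
            pts = sinusoid_polyline(2.0, amp, 0.4, 20_000)
            Rs.append(rugosity_extendible(make_contour(pts), 0.02).R)
        assert all(b >= a - 1e-12 for a, b in zip(Rs, Rs[1:]))

    def test_link_length_convergence(self):
        # draped length converges to the arc length from below; finer links
        # land closer to the analytic semicircle limit R = pi/2
        pts = semicircle_polyline(0.5, 100_000)
        errs = [abs(rugosity_extendible(make_contour(pts), L).R - np.pi / 2)
                for L in (0.08, 0.02, 0.005)]
        assert errs[2] < errs[1] < errs[0]


class TestFixed:
    def test_straight_contour(self):
        pts = np.column_stack([np.linspace(0, 2, 21), np.zeros(21),
                               np.zeros(21)])
        chain = rugosity_fixed(make_contour(pts), 0.02, 1.0)
        assert np.linalg.norm(chain.nodes[-1] - chain.nodes[0]) == \
            pytest.approx(1.0, abs=1e-9)
        assert chain.R == pytest.approx(1.0, abs=1e-9)

    def test_semicircle_closed_form(self):
        # 1 m of chain covers arc angle 2 rad in the small-link limit:
        # undraped = 2 r sin(1), R = 1 / (2 * 0.5 * sin 1)
        pts = semicircle_polyline(0.5, 100_000)
        chain = rugosity_fixed(make_contour(pts), 0.02, 1.0)
        assert chain.R == pytest.approx(fixed_R_oracle(pts, 0.02, 1.0),
                                        abs=1e-9)
        assert chain.R == pytest.approx(1.0 / np.sin(1.0), abs=1e-3)

    def test_chain_longer_than_contour(self):
        pts = np.column_stack([np.linspace(0, 0.5, 6), np.zeros(6),
                               np.zeros(6)])
        with pytest.raises(ChainError, match="runs off"):
            rugosity_fixed(make_contour(pts), 0.02, 1.0)

    def test_non_multiple_chain_warns_and_rounds_down(self):
        pts = np.column_stack([np.linspace(0, 2, 21), np.zeros(21),
                               np.zeros(21)])
        with pytest.warns(UserWarning, match="rounding down"):
            chain = rugosity_fixed(make_contour(pts), 0.02, 1.01)
        assert chain.draped_length == pytest.approx(1.0)

    def test_fixed_not_above_extendible_on_same_span(self):
        # homogeneous relief: the extendible chain over the span the fixed
        # chain covered drapes at least as much per unit chord
        pts = sinusoid_polyline(2.0, 0.1, 0.4, 50_000)
        fixed = rugosity_fixed(make_contour(pts), 0.02, 1.0)
        x_end = fixed.nodes[-1][0]
        sub = pts[pts[:, 0] <= x_end + 1e-12]
        sub = np.vstack([sub, fixed.nodes[-1]])
        ext = rugosity_extendible(make_contour(sub), 0.02)
        assert fixed.R <= ext.R + 1e-6


class TestChainGrid:
    def test_flat_quadrat_six_chains(self, flat_model):
        chains, mean_R = chain_grid(flat_model, n_per_direction=3)
        assert len(chains) == 6
        assert mean_R == pytest.approx(1.0, abs=1e-9)
        assert all(c.R == pytest.approx(1.0, abs=1e-9) for c in chains)

    def test_single_bump_raises_one_chain(self):
        # bump at (0.75, 0.5), r = 0.1: crosses only the y = 0.5 transect
        mesh, _ = hemisphere(side=2.0, mesh_step=0.01, radius=0.1,
                             center=(0.75, 0.5))
        chains, mean_R = chain_grid(as_model(mesh), n_per_direction=3)
        Rs = np.array([c.R for c in chains])
        assert (Rs > 1 + 1e-6).sum() == 1
        assert np.sum(np.isclose(Rs, 1.0, atol=1e-9)) == 5

    def test_zero_chains_rejected(self, flat_model):
        with pytest.raises(ChainError):
            chain_grid(flat_model, n_per_direction=0)


class TestTripletAverage:
    def test_flat(self, flat_model):
        _, mean_R = triplet_average(flat_model, (0.0, 1.0), (2.0, 1.0))
        assert mean_R == pytest.approx(1.0, abs=1e-9)

    def test_translational_symmetry(self):
        # surface varies only along the transect: offsets see the same
        # profile, so the triplet mean equals the single-chain R
        mesh, _ = sinusoid(side=2.0, mesh_step=0.01, amplitude=0.05,
                           wavelength=0.5)
        model = as_model(mesh)
        chains, mean_R = triplet_average(model, (0.0, 1.0), (2.0, 1.0))
        assert mean_R == pytest.approx(chains[1].R, abs=1e-9)

    def test_central_ridge_partially_dilutes(self):
        # bump narrower than the 4 cm offset: only the central chain sees it
        mesh, _ = hemisphere(side=2.0, mesh_step=0.005, radius=0.03,
                             center=(1.0, 1.0))
        model = as_model(mesh)
        chains, mean_R = triplet_average(model, (0.0, 1.0), (2.0, 1.0))
        central = chains[1].R
        assert central > 1 + 1e-6
        assert 1.0 < mean_R < central

    def test_offset_missing_mesh(self, flat_model):
        with pytest.raises(ContourError):
            triplet_average(flat_model, (0.0, 0.01), (2.0, 0.01),
                            spacing=0.04)
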