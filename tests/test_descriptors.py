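"""Shell assignment and hydropathy/shape descriptors."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spaceball.cavity import _single_run
from spaceball.descriptors import (
    ShellResidueSet,
    assign_shell,
    compute_descriptors,
    hydropathy_H,
    hydropathy_vector,
    radius_of_gyration,
    shape_parameter,
)
from spaceball.fixtures import fibonacci_sphere, make_hydropathy_shell
from spaceball.lattice import CAVITY_CENTER, ProbeParams
from spaceball.surface import extract_surface

from conftest import point_cloud_structure


def shell_from_points(points, names):
    """Build a ShellResidueSet directly from coordinates and residue names."""
    structure = point_cloud_structure(points, residue_names=names)
    atoms = structure.atoms
    m = np.array([a.mass for a in atoms])
    x = np.array([a.coords for a in atoms])
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    return ShellResidueSet(residues=list(structure.residues), com=com)


def _surface(structure, params):
    grid, labels, largest, *_ = _single_run(structure, params)
    mask = (labels == largest) & (grid.state == CAVITY_CENTER)
    return extract_surface(None, grid=grid, center_mask=mask, params=params)


class TestShellAssignment:
    def test_sealed_shell_captures_all_wall_residues(self, default_params):
        structure, _ = make_hydropathy_shell(radius=8.0, n_atoms=200, mode="uniform")
        metrics = _surface(structure, default_params)
        shell = assign_shell(metrics, structure)
        assert shell.n_cp == 200

    def test_only_inner_wall_layer_joins_shell(self, default_params):
        inner = 8.0 * fibonacci_sphere(240)
        outer = 11.6 * fibonacci_sphere(480)
        structure = point_cloud_structure(
            np.vstack([inner, outer]), ["ILE"] * 240 + ["ARG"] * 480
        )
        metrics = _surface(structure, default_params)
        shell = assign_shell(metrics, structure)
        assert {r.name for r in shell.residues} == {"ILE"}

    def test_empty_surface_empty_shell(self, default_params):
        structure = point_cloud_structure([[0.0, 0.0, 0.0]])
        metrics = _surface(structure, default_params)
        shell = assign_shell(metrics, structure)
        assert shell.n_cp == 0
        desc = compute_descriptors(metrics, structure)
        assert desc.h is None and desc.r_g is None and desc.w is None


class TestHydropathy:
    def test_uniform_ile_shell_sums_exactly(self):
        shell = shell_from_points(8 * fibonacci_sphere(10), ["ILE"] * 10)
        h, excluded = hydropathy_H(shell)
        assert h == pytest.approx(45.0) and excluded == 0

    def test_sum_additive_over_partition(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-5, 5, (30, 3))
        names = list(rng.choice(["ILE", "ARG", "GLY", "SER"], size=30))
        whole, _ = hydropathy_H(shell_from_points(pts, names))
        part1, _ = hydropathy_H(shell_from_points(pts[:13], names[:13]))
        part2, _ = hydropathy_H(shell_from_points(pts[13:], names[13:]))
        assert whole == pytest.approx(part1 + part2)

    def test_nonstandard_residues_excluded_with_count(self):
        shell = shell_from_points(8 * fibonacci_sphere(4), ["ILE", "ILE", "MSE", "MSE"])
        h, excluded = hydropathy_H(shell)
        assert h == pytest.approx(9.0) and excluded == 2

    def test_centrosymmetric_shell_cancels_vector(self):
        pts = 8 * fibonacci_sphere(64)
        pts = np.vstack([pts, -pts])  # exactly centrosymmetric
        shell = shell_from_points(pts, ["ILE"] * len(pts))
        _, h_norm = hydropathy_vector(shell)
        assert h_norm == pytest.approx(0.0, abs=1e-9)

    def test_bipartite_shell_matches_direct_summation(self):
        pts = 8 * fibonacci_sphere(100)
        names = ["ILE" if p[2] >= 0 else "ARG" for p in pts]
        shell = shell_from_points(pts, names)
        h_vec, h_norm = hydropathy_vector(shell)
        # independent direct sum
        q = np.array([4.5 if n == "ILE" else -4.5 for n in names])
        com = pts.mean(axis=0)  # equal masses
        expected = (q[:, None] * (pts - com)).sum(axis=0)
        assert np.allclose(h_vec, expected, atol=1e-9)
        assert h_vec[2] > 0  # points toward the hydrophobic hemisphere

    def test_flipping_scale_sign_flips_vector(self):
        pts = 8 * fibonacci_sphere(50)
        names = ["ILE" if p[2] >= 0 else "ARG" for p in pts]
        flipped = ["ARG" if n == "ILE" else "ILE" for n in names]
        v1, _ = hydropathy_vector(shell_from_points(pts, names))
        v2, _ = hydropathy_vector(shell_from_points(pts, flipped))
        assert np.allclose(v1, -v2, atol=1e-9)

    def test_vector_translation_invariant(self):
        pts = 8 * fibonacci_sphere(40)
        names = ["ILE" if p[2] >= 0 else "ARG" for p in pts]
        v1, _ = hydropathy_vector(shell_from_points(pts, names))
        v2, _ = hydropathy_vector(shell_from_points(pts + 100.0, names))
        assert np.allclose(v1, v2, atol=1e-6)


class TestGyrationAndShape:
    def test_constant_radius_shell_gyration_equals_radius(self):
        shell = shell_from_points(7.5 * fibonacci_sphere(128), ["GLY"] * 128)
        assert radius_of_gyration(shell) == pytest.approx(7.5, abs=0.01)

    def test_duplicating_positions_leaves_gyration_unchanged(self):
        pts = 6.0 * fibonacci_sphere(60)
        r1 = radius_of_gyration(shell_from_points(pts, ["GLY"] * 60))
        r2 = radius_of_gyration(shell_from_points(np.vstack([pts, pts]), ["GLY"] * 120))
        assert r2 == pytest.approx(r1, abs=1e-9)

    def test_spherical_shell_w_near_zero(self):
        shell = shell_from_points(8 * fibonacci_sphere(200), ["GLY"] * 200)
        radii, w, r_bar, delta_r = shape_parameter(shell)
        assert abs(w) < 0.05
        assert radii[0] <= radii[1] <= radii[2]

    def test_prolate_positive_oblate_negative(self):
        rng = np.random.default_rng(0)
        cigar = rng.normal(size=(150, 3)) * np.array([10.0, 1.0, 1.0])
        disc = rng.normal(size=(150, 3)) * np.array([10.0, 10.0, 1.0])
        _, w_cigar, *_ = shape_parameter(shell_from_points(cigar, ["GLY"] * 150))
        _, w_disc, *_ = shape_parameter(shell_from_points(disc, ["GLY"] * 150))
        assert w_cigar > 0.3
        assert w_disc < -0.05

    def test_collinear_shell_rejected(self):
        pts = np.column_stack([np.linspace(-5, 5, 10), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="degenerate"):
            shape_parameter(shell_from_points(pts, ["GLY"] * 10))

    @given(scale=st.floats(0.5, 20.0))
    def test_scale_invariance_of_w_and_linearity_of_radii(self, scale):
        pts = np.array(
            [[4.0, 0, 0], [-4, 0, 0], [0, 2.0, 0], [0, -2, 0], [0, 0, 1.0],
             [0, 0, -1.0], [2.0, 2.0, 0.5], [-2.0, -2.0, -0.5]]
        )
        base_r, base_w, *_ = shape_parameter(shell_from_points(pts, ["GLY"] * 8))
        scaled_r, scaled_w, *_ = shape_parameter(
            shell_from_points(pts * scale, ["GLY"] * 8)
        )
        assert scaled_w == pytest.approx(base_w, abs=1e-9)
        assert np.allclose(np.array(scaled_r), scale * np.array(base_r), rtol=1e-9)
        assert abs(base_w) < 1.0

    def test_w_zero_when_middle_radius_is_midpoint(self):
        # R_2 = (R_1+R_3)/2 forces ΔR = 0 exactly
        shell = shell_from_points(8 * fibonacci_sphere(300), ["GLY"] * 300)
        radii, w, r_bar, delta_r = shape_parameter(shell)
        assert w == pytest.approx(delta_r / r_bar)
        assert r_bar == pytest.approx(0.5 * (radii[0] + radii[2]))
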