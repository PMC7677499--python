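"""Point classification, chamber labeling, volumes, entrances, rotations."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from spaceball.cavity import (
    CavityResult,
    _single_run,
    classify_points,
    find_entrances,
    label_chambers,
    measure_volumes,
    run_spaceball,
)
from spaceball.fixtures import (
    make_bored_sphere,
    make_dumbbell,
    make_hollow_sphere,
    make_tetramer_ring,
)
from spaceball.lattice import (
    CAVITY_CENTER,
    CAVITY_COVERED,
    UNSEEN,
    ProbeParams,
    build_box,
    rain,
)

from conftest import single_atom_structure


def _classified_grid(structure, params):
    grid = build_box(structure, params)
    rain(grid, structure, params)
    classify_points(grid, structure, params)
    return grid


class TestClassification:
    def test_no_unseen_points_remain(self, small_sphere, default_params):
        grid = _classified_grid(small_sphere[0], default_params)
        assert not np.any(grid.state == UNSEEN)

    def test_centers_keep_probe_clearance(self, small_sphere, default_params):
        """Every cavity center admits the probe: distance ≥ r_w + r_atom."""
        structure = small_sphere[0]
        grid = _classified_grid(structure, default_params)
        centers = grid.world_coords(np.argwhere(grid.state == CAVITY_CENTER))
        d, _ = cKDTree(structure.coords()).query(centers)
        assert d.min() >= 1.42 + 1.7 - 1e-9

    def test_deep_interior_is_cavity(self, small_sphere, default_params):
        structure, expected = small_sphere
        grid = _classified_grid(structure, default_params)
        idx = np.argwhere(grid.state == CAVITY_CENTER)
        r = np.linalg.norm(grid.world_coords(idx), axis=1)
        # center ball radius R_s − r_atom − r_w, up to grid quantization
        assert r.max() <= 10.0 - 1.7 - 1.42 + grid.a * np.sqrt(3)
        center_idx = tuple(np.rint((np.zeros(3) - grid.origin) / grid.a).astype(int))
        assert grid.state[center_idx] == CAVITY_CENTER

    def test_single_atom_has_no_cavity(self, default_params):
        grid = _classified_grid(single_atom_structure(), default_params)
        assert not np.any(grid.state == CAVITY_CENTER)
        assert not np.any(grid.state == CAVITY_COVERED)


class TestChambers:
    def test_two_sealed_voids_two_chambers(self, default_params):
        structure, expected = make_dumbbell(r1=12.0, r2=8.0)
        grid = _classified_grid(structure, default_params)
        labels, sizes = label_chambers(grid, default_params)
        assert len(sizes) == expected["n_chambers"] == 2
        v_t, v_c, largest = measure_volumes(grid, labels, sizes, default_params)
        assert v_c == pytest.approx(expected["v_c_nm3"], rel=expected["v_c_tol_rel"])
        # largest chamber is the wider void
        assert sizes[largest] == max(sizes.values())

    def test_merged_voids_single_chamber(self, default_params):
        structure, expected = make_dumbbell(r1=12.0, r2=8.0, separation=17.0)
        assert expected["merged"] and expected["passage_clear_radius"] > 1.42
        grid = _classified_grid(structure, default_params)
        _, sizes = label_chambers(grid, default_params)
        assert len(sizes) == 1

    def test_halo_included_in_chamber_volume(self, small_sphere, default_params):
        structure, expected = small_sphere
        grid = _classified_grid(structure, default_params)
        labels, sizes = label_chambers(grid, default_params)
        n_centers = int(np.count_nonzero(grid.state == CAVITY_CENTER))
        n_halo = int(np.count_nonzero(grid.state == CAVITY_COVERED))
        assert sum(sizes.values()) == n_centers + n_halo

    def test_no_cavity_no_chambers(self, default_params):
        grid = _classified_grid(single_atom_structure(), default_params)
        labels, sizes = label_chambers(grid, default_params)
        assert sizes == {}
        v_t, v_c, largest = measure_volumes(grid, labels, sizes, default_params)
        assert v_c == 0.0 and largest == 0 and v_t > 0


class TestVolumes:
    def test_sealed_sphere_matches_analytic(self, sphere_run):
        structure, expected, result = sphere_run
        assert result.v_c_mean == pytest.approx(
            expected["v_c_nm3"], rel=expected["v_c_tol_rel"]
        )

    def test_vt_flag_adds_cavity_points(self, small_sphere):
        structure = small_sphere[0]
        excl = ProbeParams(n_rotations=1, seed=0)
        incl = ProbeParams(n_rotations=1, seed=0, vt_includes_cavity=True)
        r_excl = run_spaceball(structure, excl)
        r_incl = run_spaceball(structure, incl)
        assert r_incl.v_t_mean == pytest.approx(
            r_excl.v_t_mean + r_excl.v_c_mean, rel=1e-9
        )

    def test_probe_accessible_interior_shrinks_with_probe_radius(self, small_sphere):
        counts = []
        for r_w in (1.2, 1.42, 1.6, 1.8):
            params = ProbeParams(r_w=r_w, n_rotations=1, seed=0)
            grid, labels, largest, *_ = _single_run(small_sphere[0], params)
            counts.append(int(((labels == largest) & (grid.state == CAVITY_CENTER)).sum()))
        assert counts == sorted(counts, reverse=True)


class TestEntrances:
    def test_sealed_shell_has_no_entrance(self, sphere_run):
        assert len(sphere_run[2].entrances) == 0

    def test_axis_bore_opens_entrances(self, default_params):
        structure, expected = make_bored_sphere(radius=15.0, bore_diameter=4.0)
        assert expected["bore_admits_probe"]
        grid, labels, largest, v_t, v_c, sizes, entrances = _single_run(
            structure, default_params
        )
        assert len(entrances) > 0
        # entrance points belong to the largest chamber
        mask = labels == largest
        assert all(mask[tuple(p)] for p in entrances)

    def test_pre_rain_grid_yields_no_entrances(self, small_sphere, default_params):
        grid = build_box(small_sphere[0], default_params)
        out = find_entrances(grid, np.ones(grid.dims, dtype=bool))
        assert len(out) == 0


class TestRotationProtocol:
    def test_same_seed_reproduces_bitwise(self, small_sphere):
        params = ProbeParams(n_rotations=3, seed=42)
        r1 = run_spaceball(small_sphere[0], params)
        r2 = run_spaceball(small_sphere[0], params)
        assert [r.v_c for r in r1.rotations] == [r.v_c for r in r2.rotations]
        assert np.array_equal(r1.grid.state, r2.grid.state)
        assert r1.reference_rotation == r2.reference_rotation

    def test_reference_rotation_is_lower_median(self, small_sphere):
        params = ProbeParams(n_rotations=4, seed=3)
        result = run_spaceball(small_sphere[0], params)
        v_cs = [r.v_c for r in result.rotations]
        order = sorted(range(4), key=lambda i: (v_cs[i], i))
        assert result.reference_rotation == order[1]

    def test_rotation_spread_is_small_for_sealed_sphere(self, small_sphere):
        """Coefficient of variation of V_C over rotations stays below 2%."""
        params = ProbeParams(n_rotations=5, seed=11)
        result = run_spaceball(small_sphere[0], params)
        assert result.v_c_std / result.v_c_mean < 0.02

    def test_summary_is_mean_and_sample_std(self, small_sphere):
        params = ProbeParams(n_rotations=3, seed=5)
        result = run_spaceball(small_sphere[0], params)
        v_cs = [r.v_c for r in result.rotations]
        assert result.v_c_mean == pytest.approx(np.mean(v_cs))
        assert result.v_c_std == pytest.approx(np.std(v_cs, ddof=1))


class TestQuaternaryAssembly:
    def test_ring_encloses_void_only_jointly(self, tmp_path):
        from spaceball.structure import read_structure, write_structure

        structure, expected = make_tetramer_ring(n_chains=4, radius=12.0)
        params = ProbeParams(n_rotations=1, seed=8)
        assembly = run_spaceball(structure, params)
        path = tmp_path / "ring.pdb"
        write_structure(structure, path)
        chain_vcs = []
        for chain in "ABCD":
            sub = read_structure(path, chains=chain)
            chain_vcs.append(run_spaceball(sub, params).v_c_mean)
        assert assembly.v_c_mean > 1.0
        assert assembly.v_c_mean > 10 * max(max(chain_vcs), 1e-9)

    def test_gapped_ring_leaks(self):
        """Wide inter-chain gaps let the rain flood the central void.

        A slit only marginally wider than the probe still leaves shadow
        volume; 90° gaps drain the void almost completely.
        """
        structure, expected = make_tetramer_ring(n_chains=3, radius=12.0, gap_deg=90.0)
        assert expected["leaky"]
        params = ProbeParams(n_rotations=1, seed=8)
        result = run_spaceball(structure, params)
        sealed, _ = make_hollow_sphere(radius=12.0)
        sealed_vc = run_spaceball(sealed, params).v_c_mean
        assert result.v_c_mean < 0.05 * sealed_vc
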