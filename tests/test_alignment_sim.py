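import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import rdcalign as ra
from rdcalign.alignment_sim import _placed_positions
from rdcalign.fixtures import consecutive_pairs


# ---------------------------------------------------------------------------
# orientation sampling
# ---------------------------------------------------------------------------


def test_sample_orientations_count_and_properness():
    rots = ra.sample_orientations(100, 18)
    assert rots.shape == (1800, 3, 3)
    dets = np.linalg.det(rots)
    np.testing.assert_allclose(dets, 1.0, atol=1e-12)
    orth = np.einsum("rij,rkj->rik", rots, rots)
    np.testing.assert_allclose(orth, np.broadcast_to(np.eye(3), orth.shape), atol=1e-12)


def test_sample_orientations_single_is_identity():
    rots = ra.sample_orientations(1, 1)
    assert rots.shape == (1, 3, 3)
    np.testing.assert_allclose(rots[0], np.eye(3), atol=1e-15)


def test_sample_orientations_isotropy():
    # for a uniform rotation cover, <(3 uu^T - I)/2> -> 0 for any fixed u
    rots = ra.sample_orientations(1000, 4)
    u = np.array([0.3, -0.5, 0.81])
    u /= np.linalg.norm(u)
    ru = np.einsum("rij,j->ri", rots, u)
    order = 1.5 * np.einsum("ri,rj->rij", ru, ru) - 0.5 * np.eye(3)
    assert np.abs(order.mean(axis=0)).max() < 5e-3  # O(1/n) discretization


# ---------------------------------------------------------------------------
# steric exclusion
# ---------------------------------------------------------------------------


def test_steric_far_away_is_free(small_rod_medium):
    mol = ra.make_solute("rod", 4, seed=1)
    assert not ra.steric_excluded(mol, small_rod_medium, np.array([50.0, 0, 0]), np.eye(3))


def test_steric_coincident_center_is_excluded(small_rod_medium):
    mol = ra.make_solute("sphere", 1, seed=0)
    center = small_rod_medium.sphere_centers[0]
    assert ra.steric_excluded(mol, small_rod_medium, center, np.eye(3))


def test_steric_matches_brute_force(small_rod_medium):
    mol = ra.make_solute("bent", 6, seed=3)
    rng = np.random.default_rng(0)
    for _ in range(50):
        t = rng.uniform(-12, 12, 3)
        rot = Rotation.random(random_state=rng).as_matrix()
        pos = _placed_positions(mol, t, rot)
        expected = False
        for p, rv in zip(pos, mol.vdw_radii):  # all-pairs distance check
            for c, rs in small_rod_medium.spheres:
                if np.linalg.norm(p - c) < rv + rs:
                    expected = True
        assert ra.steric_excluded(mol, small_rod_medium, t, rot) == expected


# ---------------------------------------------------------------------------
# electrostatics
# ---------------------------------------------------------------------------


def _tiny_grid():
    rng = np.random.default_rng(5)
    return ra.PotentialGrid(origin=[-2, -2, -2], spacing=[1, 1, 1], values=rng.normal(size=(5, 5, 5)))


def test_energy_zero_for_uncharged():
    mol = ra.make_solute("rod", 4, "neutral", seed=1)
    assert ra.electrostatic_energy(mol, _tiny_grid(), np.zeros(3), np.eye(3)) == 0.0


def test_energy_single_charge_at_node_is_node_value():
    grid = _tiny_grid()
    atom = ra.Atom("Q", "H", [0.0, 0.0, 0.0], 1.2, charge=1.0)
    mol = ra.Molecule("probe", (atom,))
    node = grid.origin + grid.spacing * np.array([1, 2, 3])
    e = ra.electrostatic_energy(mol, grid, node, np.eye(3))
    assert e == pytest.approx(grid.values[1, 2, 3], rel=1e-12)


def test_energy_off_node_matches_trilinear_formula():
    grid = _tiny_grid()
    atom = ra.Atom("Q", "H", [0.0, 0.0, 0.0], 1.2, charge=0.7)
    mol = ra.Molecule("probe", (atom,))
    frac = np.array([0.3, 0.6, 0.8])
    point = grid.origin + grid.spacing * (np.array([1, 1, 2]) + frac)
    e = ra.electrostatic_energy(mol, grid, point, np.eye(3))
    # independent trilinear interpolation over the 8 corner nodes
    expected = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[0] if dx else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dz else 1 - frac[2])
                )
                expected += w * grid.values[1 + dx, 1 + dy, 2 + dz]
    assert e == pytest.approx(0.7 * expected, rel=1e-12)


def test_boltzmann_weight_cap_and_monotone():
    assert ra.boltzmann_weight(0.0, 2.0) == 1.0
    assert ra.boltzmann_weight(10.0, 2.0) == pytest.approx(np.exp(-2.0))
    es = np.linspace(-5, 5, 41)
    ws = ra.boltzmann_weight(es, 2.0)
    assert np.all(np.diff(ws) <= 1e-15)


# ---------------------------------------------------------------------------
# the full sweep
# ---------------------------------------------------------------------------


def test_single_atom_solute_is_isotropic(small_rod_medium, small_config):
    mol = ra.make_solute("sphere", 1, seed=0)
    tensor, dist = ra.simulate_alignment(mol, small_rod_medium, small_config)
    assert np.abs(tensor.matrix).max() < 1e-3
    assert np.all(dist.weights >= 0)


def test_steric_only_equals_full_on_null_potential(small_rod_medium, small_config):
    mol = ra.make_solute("bent", 8, "dipolar", seed=5)  # charged, but null potential
    full, _ = ra.simulate_alignment(mol, small_rod_medium, small_config)
    steric = ra.simulate_steric_only(mol, small_rod_medium, small_config)
    np.testing.assert_array_equal(full.matrix, steric.matrix)  # bitwise


def test_electrostatics_changes_tensor_only_with_charged_medium(
    small_rod_medium, charged_rod_medium, small_config
):
    mol = ra.make_solute("bent", 8, "dipolar", seed=5)
    flipped = mol.with_charges(-mol.charges)
    s_plus, _ = ra.simulate_alignment(mol, charged_rod_medium, small_config)
    s_minus, _ = ra.simulate_alignment(flipped, charged_rod_medium, small_config)
    assert np.abs(s_plus.matrix - s_minus.matrix).max() > 1e-6
    n_plus, _ = ra.simulate_alignment(mol, small_rod_medium, small_config)
    n_minus, _ = ra.simulate_alignment(flipped, small_rod_medium, small_config)
    np.testing.assert_array_equal(n_plus.matrix, n_minus.matrix)


def test_lc_order_scales_tensor_linearly(charged_rod_medium, small_config):
    from dataclasses import replace

    mol = ra.make_solute("rod", 6, "neutral", seed=5)
    s_high, _ = ra.simulate_alignment(mol, charged_rod_medium, small_config)  # lcS 0.8
    s_low, _ = ra.simulate_alignment(
        mol, charged_rod_medium, replace(small_config, lc_order=0.4)
    )
    np.testing.assert_allclose(s_low.matrix, 0.5 * s_high.matrix, rtol=1e-13, atol=0)


def test_rotating_input_structure_leaves_rdcs_unchanged(charged_rod_medium, small_config):
    # predicted couplings must not depend on how the input structure is oriented
    mol = ra.make_solute("bent", 8, "dipolar", seed=5)
    pairs = consecutive_pairs(mol)
    s0, _ = ra.simulate_alignment(mol, charged_rod_medium, small_config)
    d0 = ra.predict_rdcs(s0, mol, pairs).values
    q = Rotation.from_euler("zyx", [0.4, 1.2, -0.8]).as_matrix()
    rotated = mol.with_positions(mol.positions @ q.T)
    s1, _ = ra.simulate_alignment(rotated, charged_rod_medium, small_config)
    d1 = ra.predict_rdcs(s1, rotated, pairs).values
    np.testing.assert_allclose(d1, d0, atol=1e-6 * max(1.0, np.abs(d0).max()))


def test_rod_beside_wall_orders_along_wall_director():
    wall = ra.make_medium(
        ra.SyntheticMediumSpec(kind="planar_wall", length=20, radius=2.5, sphere_spacing=2.5,
                               grid_spacing=2.0, grid_padding=4)
    )
    rod = ra.make_solute("rod", 6, "neutral", seed=5)
    cfg = ra.SimulationConfig(grid_spacing=(2.0, 2.0, 2.0), grid_counts=(13, 13, 13),
                              z_range=(3, 9), n_sphere=40, n_spin=6)
    coarse, _ = ra.simulate_alignment(rod, wall, cfg)
    # a rod next to a wall lies in the wall plane: positive order along the
    # in-plane director (z)
    assert coarse.matrix[2, 2] > 0
    dense, _ = ra.simulate_alignment(
        rod, wall,
        ra.SimulationConfig(grid_spacing=(2.0, 2.0, 2.0), grid_counts=(13, 13, 13),
                            z_range=(3, 9), n_sphere=300, n_spin=6),
    )
    assert np.sign(dense.matrix[2, 2]) == np.sign(coarse.matrix[2, 2])


def test_grid_refinement_consistency():
    # the base grid must already resolve the ~4 Å contact features (the binary
    # steric boundary converges first-order in spacing); reach_padding is held
    # fixed so both sweeps integrate the same physical shell
    medium = ra.make_medium(
        ra.SyntheticMediumSpec(kind="helical_rod", length=24, radius=4, sphere_spacing=4,
                               grid_spacing=1.0, grid_padding=6, surface_charge_density=0.02)
    )
    mol = ra.make_solute("rod", 4, "dipolar", seed=2)
    coarse_cfg = ra.SimulationConfig(grid_spacing=(1.0, 1.0, 1.0), grid_counts=(21, 21, 29),
                                     z_range=(8, 20), n_sphere=40, n_spin=6, reach_padding=6.0)
    fine_cfg = ra.SimulationConfig(grid_spacing=(0.5, 0.5, 0.5), grid_counts=(41, 41, 57),
                                   z_range=(16, 40), n_sphere=40, n_spin=6, reach_padding=6.0)
    s_coarse, _ = ra.simulate_alignment(mol, medium, coarse_cfg)
    s_fine, _ = ra.simulate_alignment(mol, medium, fine_cfg)
    scale = np.abs(s_fine.matrix).max()
    assert np.abs(s_fine.matrix - s_coarse.matrix).max() < 0.1 * scale


def test_unreachable_solute_is_error(small_rod_medium):
    mol = ra.make_solute("rod", 4, seed=1)
    cfg = ra.SimulationConfig(
        grid_spacing=(1.0, 1.0, 1.0), grid_counts=(5, 5, 5), z_range=(0, 4),
        grid_origin=(200.0, 200.0, 200.0), n_sphere=10, n_spin=2,
    )
    with pytest.raises(ValueError, match="cannot approach"):
        ra.simulate_alignment(mol, small_rod_medium, cfg)


def test_predict_rdcs_wraps_back_calculation(bent_molecule, bent_pairs):
    from conftest import random_saupe

    t = random_saupe(9)
    rdcs = ra.predict_rdcs(t, bent_molecule, bent_pairs)
    for rec in rdcs.records:
        assert rec.d_exp == pytest.approx(
            ra.rdc_from_tensor(t, bent_molecule, (rec.atom_a, rec.atom_b)), rel=1e-12
        )
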