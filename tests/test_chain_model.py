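import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from driftfold.chain_model import (
    DEFAULT_TEMPLATES,
    FrozenPivotError,
    VIRTUAL_BOND_NM,
    build_extended_chain,
    coarse_grain_regions,
    curl_chain,
    expand_to_residues,
    insert_templates,
    mobile_block,
    radius_of_gyration,
    rotate_about_pivot,
)
from driftfold.residue_props import annotate_sequence
from driftfold.ss_rules import SecondaryStructureAnnotation, predict_secondary

from conftest import random_chain


def _pairwise(coords):
    return np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)


# ----------------------------------------------------- extended chain

def test_extended_chain_construction():
    seq = annotate_sequence("DKA")
    chain = build_extended_chain(seq)
    assert chain.n_sites == 3 and len(chain.pivots) == 2
    np.testing.assert_allclose(
        np.linalg.norm(np.diff(chain.positions, axis=0), axis=1),
        VIRTUAL_BOND_NM,
    )
    rank = np.linalg.matrix_rank(chain.positions - chain.positions[0])
    assert rank == 1  # collinear
    np.testing.assert_allclose(chain.charges, seq.q)
    assert not any(p.frozen for p in chain.pivots)
    assert all(p.win_count == 0 for p in chain.pivots)


# --------------------------------------------------------- templates

def test_insert_templates_identity_without_regions():
    seq = annotate_sequence("AAAAA")
    chain = build_extended_chain(seq)
    ann = SecondaryStructureAnnotation("CCCCC", ())
    out = insert_templates(chain, ann)
    np.testing.assert_allclose(out.positions, chain.positions)
    assert not any(p.frozen for p in out.pivots)


def test_insert_templates_freezes_interior_pivots_and_groups():
    seq = annotate_sequence("A" * 10)
    chain = build_extended_chain(seq)
    ann = SecondaryStructureAnnotation("CCHHHHHHCC", ((2, 7, "H"),))
    out = insert_templates(chain, ann)
    assert set(out.rigid_group[2:8]) == {0}
    assert set(out.rigid_group[:2]) == set(out.rigid_group[8:]) == {-1}
    frozen = [p.i for p in out.pivots if p.frozen]
    assert frozen == [2, 3, 4, 5, 6]  # the 5 interior pivots of a 6-site region
    # charge/hydrophobicity totals conserved
    assert out.total_charge() == pytest.approx(chain.total_charge())
    assert out.hydrophobicity.sum() == pytest.approx(chain.hydrophobicity.sum())


def test_template_geometry_matches_ideal_parameters():
    helix = DEFAULT_TEMPLATES["H"].local_coords(6)
    # consecutive rise along the axis is constant
    np.testing.assert_allclose(np.diff(helix[:, 0]), 0.15, atol=1e-12)
    strand = DEFAULT_TEMPLATES["E"].local_coords(4)
    np.testing.assert_allclose(
        np.linalg.norm(np.diff(strand, axis=0), axis=1), 0.35
    )


def test_intra_region_distances_survive_folding():
    seq = annotate_sequence("A" * 10)
    ann = SecondaryStructureAnnotation("CCHHHHHHCC", ((2, 7, "H"),))
    chain = insert_templates(build_extended_chain(seq), ann)
    before = _pairwise(chain.positions[2:8])
    moved = rotate_about_pivot(chain, 0, 0.7)
    moved = rotate_about_pivot(moved, 8, -0.4)
    after = _pairwise(moved.positions[2:8])
    np.testing.assert_allclose(after, before, rtol=1e-9)


def test_overlapping_regions_rejected():
    with pytest.raises(ValueError):
        SecondaryStructureAnnotation("HHHHH", ((0, 2, "H"), (2, 4, "E")))


# ----------------------------------------------------- coarse-graining

def test_coarse_grain_sums_tags_and_keeps_totals():
    seq = annotate_sequence("DKAAAKD")
    ann = SecondaryStructureAnnotation("CHHHHC" + "C", ((1, 4, "H"),))
    chain = insert_templates(build_extended_chain(seq), ann)
    coarse = coarse_grain_regions(chain)
    assert coarse.n_sites == 4  # 1 + region + 2
    region_site = 1
    assert coarse.charges[region_site] == pytest.approx(sum(seq.q[1:5]))
    assert coarse.hydrophobicity[region_site] == pytest.approx(sum(seq.h[1:5]))
    assert coarse.total_charge() == pytest.approx(chain.total_charge())
    assert coarse.spans[region_site] == (1, 4)


def test_coarse_grain_identity_without_regions():
    seq = annotate_sequence("AAAA")
    chain = build_extended_chain(seq)
    coarse = coarse_grain_regions(chain)
    assert coarse.n_sites == 4
    np.testing.assert_allclose(coarse.positions, chain.positions)


# ------------------------------------------------------------ rotation

def test_rotation_identities():
    rng = np.random.default_rng(3)
    chain = random_chain(rng, 8)
    for theta in (0.0, 2.0 * np.pi):
        out = rotate_about_pivot(chain, 3, theta)
        np.testing.assert_allclose(out.positions, chain.positions, atol=1e-9)


def test_rotation_quarter_turn_matches_rodrigues():
    seq = annotate_sequence("AAAA")
    chain = build_extended_chain(seq)
    # offset the last site perpendicular to the pivot-1 bond axis (x);
    # for pivot 1 the mobile block is the C-side {2, 3} (tie-break)
    chain.positions[3] = chain.positions[2] + np.array([0.0, 0.38, 0.0])
    out = rotate_about_pivot(chain, 1, np.pi / 2.0)
    # the perpendicular offset rotates y -> z about +x (right-hand rule)
    expected = chain.positions[2] + np.array([0.0, 0.0, 0.38])
    np.testing.assert_allclose(out.positions[3], expected, atol=1e-12)
    np.testing.assert_allclose(out.positions[:3], chain.positions[:3])


def test_rotation_preserves_block_distances_property():
    rng = np.random.default_rng(17)
    for _ in range(25):
        chain = random_chain(rng, rng.integers(4, 12))
        pivot = int(rng.integers(0, chain.n_sites - 1))
        theta = float(rng.uniform(-np.pi, np.pi))
        block, _ = mobile_block(chain, pivot)
        keep = np.setdiff1d(np.arange(chain.n_sites), block)
        out = rotate_about_pivot(chain, pivot, theta)
        for idx in (block, keep):
            np.testing.assert_allclose(
                _pairwise(out.positions[idx]),
                _pairwise(chain.positions[idx]),
                rtol=1e-9, atol=1e-12,
            )
        np.testing.assert_allclose(out.charges, chain.charges)


def test_frozen_pivot_rejects_rotation():
    chain = build_extended_chain(annotate_sequence("AAAA"))
    chain.pivots[1].frozen = True
    with pytest.raises(FrozenPivotError):
        rotate_about_pivot(chain, 1, 0.1)


def test_mobile_block_smaller_side_ties_to_c_terminal():
    chain = build_extended_chain(annotate_sequence("AAAA"))
    block, direction = mobile_block(chain, 0)
    assert list(block) == [0] and direction == -1
    block, direction = mobile_block(chain, 1)  # 2 vs 2 tie -> C side
    assert list(block) == [2, 3] and direction == +1


# ----------------------------------------------------------- expansion

def test_expand_identity_without_coarse_graining():
    chain = build_extended_chain(annotate_sequence("DKAAA"))
    np.testing.assert_allclose(expand_to_residues(chain), chain.positions)


def test_expand_covers_every_residue_after_coarse_graining():
    seq = annotate_sequence("AAVLAIAAA")
    ann = predict_secondary(seq)
    chain = coarse_grain_regions(insert_templates(build_extended_chain(seq), ann))
    coords = expand_to_residues(chain)
    assert coords.shape == (9, 3)


def test_expansion_commutes_with_rigid_rotation():
    seq = annotate_sequence("AAAAAVLAIAAAA")
    ann = SecondaryStructureAnnotation(
        "CCCCHHHHHCCCC", ((4, 8, "H"),)
    )
    chain = coarse_grain_regions(insert_templates(build_extended_chain(seq), ann))
    rot = Rotation.from_rotvec([0.3, -0.2, 0.5])
    # route 1: rotate the whole chain rigidly, then expand
    rotated = chain.copy()
    rotated.positions = rot.apply(rotated.positions)
    for body in rotated.bodies.values():
        body.rotation = rot.as_matrix() @ body.rotation
    route1 = expand_to_residues(rotated)
    # route 2: expand, then rotate the residue coordinates
    route2 = rot.apply(expand_to_residues(chain))
    np.testing.assert_allclose(route1, route2, atol=1e-12)


# ---------------------------------------------------------------- curl

def test_curl_breaks_collinearity_preserving_bonds():
    chain = build_extended_chain(annotate_sequence("A" * 12))
    curled = curl_chain(chain, 0.15)
    bonds = np.linalg.norm(np.diff(curled.positions, axis=0), axis=1)
    np.testing.assert_allclose(bonds, VIRTUAL_BOND_NM, rtol=1e-12)
    rank = np.linalg.matrix_rank(
        curled.positions - curled.positions[0], tol=1e-6
    )
    assert rank == 3
    assert radius_of_gyration(curled.positions) < radius_of_gyration(chain.positions)
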