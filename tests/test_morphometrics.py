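"""Scalar morphometrics, profiles and the primary-branch decomposition."""

import math

import numpy as np
import pytest

from lcnmorph.core import AXON, DENDRITE, SOMA, MorphNode, MorphologyError, Reconstruction
from lcnmorph.morphometrics import (
    axon_origin,
    bounding_extents,
    branch_overlap,
    count_branch_points,
    decompose_primary_branches,
    path_distance_histogram,
    sholl,
    soma_area,
    stem_count,
    total_length,
    total_volume,
    z_shrinkage_correct,
)
from lcnmorph.synthetic import SyntheticSpec, generate_lcn


def _node(nid, parent, x, y, z, d, label):
    return MorphNode(node_id=nid, parent_id=parent, x=x, y=y, z=z, diameter=d, label=label)


def chain(points, label=AXON, d=1.0, soma_d=8.0):
    """Point soma at the first coordinate, then a chain of `label` nodes."""
    x0, y0, z0 = points[0]
    nodes = [_node(1, None, x0, y0, z0, soma_d, SOMA)]
    for i, (x, y, z) in enumerate(points, start=2):
        dd = d if np.isscalar(d) else d[i - 2]
        nodes.append(_node(i, i - 1, x, y, z, dd, label))
    return Reconstruction(neuron_id="chain", nodes=nodes)


class TestExtents:
    def test_two_axon_nodes_default_axis_map(self):
        recon = chain([(0, 0, 0), (100, 50, 25)])
        ext = bounding_extents(recon, AXON)
        assert (ext.rc, ext.dv, ext.ml) == (100, 50, 25)

    def test_single_node_is_degenerate_zero(self):
        recon = chain([(5, 5, 5)])
        assert bounding_extents(recon, AXON) == (0, 0, 0)

    def test_empty_class_raises(self):
        recon = chain([(0, 0, 0)])
        with pytest.raises(MorphologyError):
            bounding_extents(recon, DENDRITE)

    def test_synthetic_extents_match_ground_truth(self, default_lcn):
        recon, truth = default_lcn
        assert np.allclose(bounding_extents(recon, AXON), truth.axon_extents)
        assert np.allclose(bounding_extents(recon, DENDRITE), truth.dendrite_extents)


class TestLengthVolumeCounts:
    def test_path_length_sums_segments(self):
        recon = chain([(0, 0, 0), (10, 0, 0), (30, 0, 0)])
        assert total_length(recon, AXON) == pytest.approx(30.0)
        assert count_branch_points(recon, AXON) == 0

    def test_binary_tree_branch_points(self):
        # root bifurcates, both children bifurcate: 3 branch points, 6 unit edges
        nodes = [_node(1, None, 0, 0, 0, 8, SOMA), _node(2, 1, 0, 0, 0, 1, AXON)]
        nid = 3
        for parent, (dx, dy) in [(2, (1, 0)), (2, (0, 1))]:
            p = nodes[parent - 1]
            nodes.append(_node(nid, parent, p.x + dx, p.y + dy, 0, 1, AXON))
            nid += 1
        for parent in (3, 3, 4, 4):
            p = nodes[parent - 1]
            nodes.append(_node(nid, parent, p.x, p.y, nid, 1, AXON))
            nid += 1
        recon = Reconstruction(neuron_id="btree", nodes=nodes)
        assert count_branch_points(recon, AXON) == 3

    def test_trifurcation_counts_once(self):
        nodes = [_node(1, None, 0, 0, 0, 8, SOMA), _node(2, 1, 0, 0, 0, 1, AXON)]
        for k in range(3):
            nodes.append(_node(3 + k, 2, 10, 10 * k, 0, 1, AXON))
        recon = Reconstruction(neuron_id="tri", nodes=nodes)
        assert count_branch_points(recon, AXON) == 1

    def test_stem_count_four_dendrites_from_soma(self):
        nodes = [_node(1, None, 0, 0, 0, 8, SOMA)]
        for k in range(4):
            nodes.append(_node(2 + k, 1, 10, 10 * k, 0, 2, DENDRITE))
        recon = Reconstruction(neuron_id="stems", nodes=nodes)
        assert stem_count(recon) == 4

    def test_cylinder_volume_closed_form(self):
        recon = chain([(0, 0, 0), (10, 0, 0)], d=1.0)
        # takeoff segment has zero length; the 10-μm segment is a cylinder
        assert total_volume(recon, AXON) == pytest.approx(math.pi * 10 / 4, rel=1e-9)

    def test_frustum_volume_closed_form(self):
        recon = chain([(0, 0, 0), (3, 0, 0)], d=[1.0, 2.0])
        # frustum between d=1 and d=2 over l=3: π·3/12·(1+2+4) = 7π/4
        assert total_volume(recon, AXON) == pytest.approx(7 * math.pi / 4, rel=1e-9)

    def test_zero_length_segment_contributes_nothing(self):
        recon = chain([(0, 0, 0), (0, 0, 0)], d=1.0)
        assert total_volume(recon, AXON) == 0.0

    def test_rigid_transform_invariance(self, default_lcn):
        recon, _ = default_lcn
        # rotate about dv axis and translate
        theta = 0.7
        rot = np.array(
            [
                [math.cos(theta), 0, -math.sin(theta)],
                [0, 1, 0],
                [math.sin(theta), 0, math.cos(theta)],
            ]
        )
        moved = recon.transformed(lambda pts: pts @ rot.T + np.array([100.0, -50.0, 30.0]))
        assert total_length(moved, AXON) == pytest.approx(total_length(recon, AXON), rel=1e-9)
        assert total_volume(moved, AXON) == pytest.approx(total_volume(recon, AXON), rel=1e-9)


class TestSomaArea:
    def test_unit_square(self):
        assert soma_area([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]) == pytest.approx(1.0)

    def test_triangle(self):
        assert soma_area([(0, 0, 0), (2, 0, 0), (0, 2, 0)]) == pytest.approx(2.0)

    def test_orientation_invariance(self):
        pts = [(0, 0, 0), (2, 0, 0), (2, 3, 0), (0, 3, 0)]
        assert soma_area(pts) == pytest.approx(soma_area(pts[::-1]))

    def test_collinear_or_short_contours_raise(self):
        with pytest.raises(MorphologyError):
            soma_area([(0, 0, 0), (1, 0, 0)])
        with pytest.raises(MorphologyError):
            soma_area([(0, 0, 0), (1, 0, 0), (2, 0, 0)])

    def test_tilted_plane_matches_in_plane_area(self):
        # unit square rotated out of the xy plane keeps its area
        sq = np.array([(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)], dtype=float)
        theta = 0.5
        rot = np.array(
            [[1, 0, 0], [0, math.cos(theta), -math.sin(theta)], [0, math.sin(theta), math.cos(theta)]]
        )
        assert soma_area(sq @ rot.T) == pytest.approx(1.0, rel=1e-9)


class TestAxonOrigin:
    def test_somatic_origin(self):
        recon = chain([(5, 0, 0)])
        assert axon_origin(recon) == ("somatic", 0.0)

    def test_dendritic_origin_sums_path_segments(self):
        nodes = [_node(1, None, 0, 0, 0, 8, SOMA)]
        for k in range(3):  # three 5-μm dendrite segments
            nodes.append(_node(2 + k, 1 + k, 5 * (k + 1), 0, 0, 2, DENDRITE))
        nodes.append(_node(5, 4, 15, 1, 0, 1, AXON))
        recon = Reconstruction(neuron_id="d-origin", nodes=nodes)
        origin, dist = axon_origin(recon)
        assert origin == "dendritic"
        assert dist == pytest.approx(15.0)

    def test_multiple_takeoffs_raise(self):
        nodes = [
            _node(1, None, 0, 0, 0, 8, SOMA),
            _node(2, 1, 5, 0, 0, 1, AXON),
            _node(3, 1, -5, 0, 0, 1, AXON),
        ]
        recon = Reconstruction(neuron_id="two-axons", nodes=nodes)
        with pytest.raises(MorphologyError, match="take-off"):
            axon_origin(recon)


class TestProfiles:
    def test_sholl_bins_branch_points_by_radius(self):
        # dendritic branch points at r = 30, 70, 70 with 50-μm shells
        nodes = [_node(1, None, 0, 0, 0, 8, SOMA)]
        nid = 2
        for r in (30.0, 70.0, -70.0):
            nodes.append(_node(nid, 1, r, 0, 0, 2, DENDRITE))
            fork = nid
            nid += 1
            for dy in (10.0, -10.0):
                nodes.append(_node(nid, fork, r, dy, 0, 1, DENDRITE))
                nid += 1
        recon = Reconstruction(neuron_id="sholl", nodes=nodes)
        profile = sholl(recon, "dendritic_branch_points", center=(0, 0, 0), shell_width=50.0)
        assert list(profile.counts) == [1, 2]

    def test_varicosity_at_takeoff_lands_in_first_bin(self, default_lcn):
        recon, _ = default_lcn
        hist = path_distance_histogram(recon, bin_width=100.0)
        takeoff = recon.axon_takeoff()
        from lcnmorph.core import Varicosity

        with_v = recon.with_nodes(
            recon.nodes,
            varicosities=[
                Varicosity(x=takeoff.x, y=takeoff.y, z=takeoff.z, diameter=1.0,
                           host_node_id=takeoff.node_id)
            ],
        )
        h0 = path_distance_histogram(with_v, bin_width=100.0)
        assert h0.counts[0] == 1 and h0.total == 1
        assert hist.total == len(recon.varicosities)

    def test_profile_totals_conserve_counts(self, default_lcn):
        recon, truth = default_lcn
        assert sholl(recon, "varicosities", shell_width=100.0).total == truth.n_varicosities
        assert path_distance_histogram(recon).total == truth.n_varicosities
        n_dend_bp = sum(
            1
            for n in recon.nodes
            if n.label == DENDRITE
            and sum(1 for c in recon.children(n.node_id) if c.label == DENDRITE) >= 2
        )
        assert sholl(recon, "dendritic_branch_points", shell_width=50.0).total == n_dend_bp

    def test_nonpositive_width_raises(self, default_lcn):
        recon, _ = default_lcn
        with pytest.raises(MorphologyError):
            sholl(recon, "varicosities", shell_width=0.0)
        with pytest.raises(MorphologyError):
            path_distance_histogram(recon, bin_width=-1.0)


class TestZShrinkage:
    def test_scales_section_normal_axis(self):
        recon = chain([(0, 0, 0), (10, 10, 100)])
        fixed = z_shrinkage_correct(recon, measured_thickness=100.0, nominal_thickness=80.0)
        tip = fixed.node(3)
        assert (tip.x, tip.y, tip.z) == (10.0, 10.0, 80.0)

    def test_equal_thicknesses_are_identity(self):
        recon = chain([(0, 0, 0), (10, 10, 100)])
        same = z_shrinkage_correct(recon, 80.0, 80.0)
        assert np.allclose(same.coords_of(), recon.coords_of())

    def test_length_changes_match_anisotropic_hand_computation(self):
        recon = chain([(0, 0, 0), (0, 0, 30), (0, 40, 30)])
        fixed = z_shrinkage_correct(recon, 100.0, 80.0)
        # first segment lies along the normal (30 -> 24), second is unchanged
        assert total_length(fixed, AXON) == pytest.approx(24.0 + 40.0)

    def test_nonpositive_thickness_raises(self):
        recon = chain([(0, 0, 0), (1, 1, 1)])
        with pytest.raises(MorphologyError):
            z_shrinkage_correct(recon, 0.0, 80.0)


class TestPrimaryBranches:
    def test_side_subtrees_in_path_order(self):
        # main axon along +x (d=1), five single-node side branches (d=0.4)
        nodes = [_node(1, None, 0, 0, 0, 8, SOMA), _node(2, 1, 0, 0, 0, 1, AXON)]
        nid = 3
        main_ids = [2]
        for k in range(6):
            nodes.append(_node(nid, main_ids[-1], 10.0 * (k + 1), 0, 0, 1, AXON))
            main_ids.append(nid)
            nid += 1
        side_roots = []
        for k in range(5):
            nodes.append(_node(nid, main_ids[k + 1], 10.0 * (k + 1), 20, 0, 0.4, AXON))
            side_roots.append(nid)
            nid += 1
        recon = Reconstruction(neuron_id="primary", nodes=nodes)
        dec = decompose_primary_branches(recon)
        assert dec.main_axon_ids == main_ids
        assert [b.root_id for b in dec.branches] == side_roots
        assert [b.order for b in dec.branches] == [1, 2, 3, 4, 5]

    def test_requested_branch_count_is_recovered(self):
        recon, truth = generate_lcn(SyntheticSpec(seed=11, n_primary_branches=5))
        dec = decompose_primary_branches(recon)
        assert len(dec.branches) == truth.n_primary_branches == 5

    def test_partition_of_axon_nodes(self, default_lcn):
        recon, _ = default_lcn
        dec = decompose_primary_branches(recon)
        groups = [set(dec.main_axon_ids)] + [set(b.node_ids) for b in dec.branches]
        union = set().union(*groups)
        assert union == {n.node_id for n in recon.nodes_of(AXON)}
        assert sum(len(g) for g in groups) == len(union)  # pairwise disjoint

    def test_overlap_identical_and_disjoint(self):
        nodes = [_node(1, None, 0, 0, 0, 8, SOMA), _node(2, 1, 0, 0, 0, 1, AXON),
                 _node(3, 2, 50, 0, 0, 1, AXON)]
        nid = 4
        # two identical side branches from the same node, one far-away branch
        for y0 in (20.0, 20.0, 900.0):
            nodes.append(_node(nid, 2, 0, y0, 0, 0.4, AXON))
            nid += 1
        recon = Reconstruction(neuron_id="overlap", nodes=nodes)
        dec = decompose_primary_branches(recon)
        overlap = branch_overlap(recon, dec, voxel_edge=100.0)
        assert overlap.shape == (3, 3)
        assert overlap[0, 1] == pytest.approx(1.0)  # duplicated branch
        assert overlap[0, 2] == 0.0  # disjoint territories
        assert np.allclose(overlap, overlap.T)
        assert ((overlap >= 0) & (overlap <= 1)).all()

    def test_overlap_matrix_on_synthetic_cell(self, default_lcn):
        recon, _ = default_lcn
        dec = decompose_primary_branches(recon)
        overlap = branch_overlap(recon, dec)
        assert np.allclose(np.diag(overlap), 1.0)
        assert np.allclose(overlap, overlap.T)
        assert overlap.min() >= 0.0 and overlap.max() <= 1.0
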