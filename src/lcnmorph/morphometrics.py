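"""Scalar and profile morphometrics of reconstructed arbors.

Covers the classic per-neuron measurements reported for lamina I
local-circuit neurons — bounding extents along the anatomical axes, total
cable length and volume, branch-point and stem-dendrite counts, soma contour
area, axon origin (somatic vs dendritic, with the path distance along the
dendrite) — plus the spatial profiles: 3-D Sholl counts in concentric shells
and path-distance histograms of axon varicosities, the primary-branch
decomposition of the axon and the voxel overlap between primary branches.

Conventions: a segment belongs to its child node's label; a branch point is a
node with at least two children of its own label (a trifurcation counts
once); segment volume uses the conical frustum between the endpoint
diameters, V = π·l/12·(d₁² + d₁d₂ + d₂²); extents are measured on node
coordinates only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .core import AXON, DENDRITE, SOMA, MorphNode, MorphologyError, Reconstruction

SOMATIC = "somatic"
DENDRITIC = "dendritic"


class Extents(NamedTuple):
    rc: float
    ml: float
    dv: float


# ---------------------------------------------------------------------------
# scalar morphometrics
# ---------------------------------------------------------------------------


def bounding_extents(recon: Reconstruction, which: str) -> Extents:
    """Largest extent of a tree class along each anatomical axis (μm)."""
    pts = recon.coords_of(which)
    if pts.size == 0:
        raise MorphologyError(f"no nodes of class {which!r}")
    span = pts.max(axis=0) - pts.min(axis=0)
    return Extents(
        rc=float(span[recon.axis_index("rc")]),
        ml=float(span[recon.axis_index("ml")]),
        dv=float(span[recon.axis_index("dv")]),
    )


def total_length(recon: Reconstruction, which: str) -> float:
    """Sum of Euclidean segment lengths of a tree class (μm)."""
    return float(sum(p.distance_to(c) for p, c in recon.iter_segments(which)))


def count_branch_points(recon: Reconstruction, which: str) -> int:
    """Nodes of the class with ≥2 children of the same class."""
    count = 0
    for node in recon.nodes:
        if node.label != which:
            continue
        same = sum(1 for c in recon.children(node.node_id) if c.label == which)
        if same >= 2:
            count += 1
    return count


def stem_count(recon: Reconstruction) -> int:
    """Dendrite branches rooted directly on soma nodes."""
    return sum(
        1
        for n in recon.nodes
        if n.label == DENDRITE
        and n.parent_id is not None
        and recon.node(n.parent_id).label == SOMA
    )


def _frustum_volume(length: float, d1: float, d2: float) -> float:
    return math.pi * length / 12.0 * (d1 * d1 + d1 * d2 + d2 * d2)


def total_volume(recon: Reconstruction, which: str) -> float:
    """Sum of conical-frustum segment volumes of a tree class (μm³)."""
    total = 0.0
    for p, c in recon.iter_segments(which):
        if p.diameter <= 0 or c.diameter <= 0:
            raise MorphologyError(
                f"non-positive diameter on segment {p.node_id}->{c.node_id}"
            )
        total += _frustum_volume(p.distance_to(c), p.diameter, c.diameter)
    return float(total)


def soma_area(contour: np.ndarray) -> float:
    """Absolute shoelace area (μm²) of the soma outline.

    The contour may live in any plane; it is projected onto its best-fit
    plane (principal components) before the shoelace evaluation, which
    reduces to the plain 2-D shoelace for a planar polygon.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise MorphologyError("soma contour needs at least 3 points")
    centered = pts - pts.mean(axis=0)
    # project to the two dominant in-plane directions
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if pts.shape[1] == 2:
        plane = centered
    else:
        plane = centered @ vt[:2].T
    if np.allclose(s[1] if len(s) > 1 else 0.0, 0.0):
        raise MorphologyError("soma contour points are collinear")
    return float(Polygon(plane).area)


def axon_origin(recon: Reconstruction) -> tuple[str, float]:
    """Whether the axon arises from the soma or a dendrite, and at what distance.

    The take-off node is the unique axon-labelled node with a non-axon parent.
    A somatic origin has distance 0; a dendritic origin's distance is the path
    length along the dendrite from the nearest soma-labelled ancestor to the
    dendrite node the axon branches from.
    """
    takeoff = recon.axon_takeoff()
    parent = recon.parent(takeoff)
    if parent is None or parent.label == SOMA:
        return SOMATIC, 0.0
    distance = 0.0
    node = parent
    while node.label != SOMA:
        up = recon.parent(node)
        if up is None:
            raise MorphologyError(
                f"axon take-off node {takeoff.node_id} has no soma ancestor"
            )
        distance += node.distance_to(up)
        node = up
    return DENDRITIC, float(distance)


def z_shrinkage_correct(
    recon: Reconstruction,
    measured_thickness: float,
    nominal_thickness: float,
    *,
    normal_axis: str = "ml",
) -> Reconstruction:
    """Rescale the section-normal axis by nominal/measured thickness.

    Histological sections shrink along their normal during embedding; scaling
    by nominal/measured restores the nominal thickness.  The normal axis
    defaults to mediolateral (sagittal sectioning).
    """
    if measured_thickness <= 0 or nominal_thickness <= 0:
        raise MorphologyError("section thicknesses must be positive")
    factor = nominal_thickness / measured_thickness
    col = recon.axis_index(normal_axis)

    def scale(points: np.ndarray) -> np.ndarray:
        out = np.array(points, dtype=float)
        if out.size:
            out[:, col] *= factor
        return out

    return recon.transformed(scale)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


@dataclass
class ShollProfile:
    """Feature counts in concentric 3-D spherical shells [k·w, (k+1)·w)."""

    center: np.ndarray
    shell_width: float
    counts: np.ndarray
    counted_feature: str

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        edges = np.arange(len(self.counts)) * self.shell_width
        return pd.DataFrame({"shell_lower_um": edges, "count": self.counts})


@dataclass
class PathDistanceHistogram:
    """Varicosity counts binned by path distance along the axon (μm)."""

    bin_width: float
    counts: np.ndarray
    reference: str

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        edges = np.arange(len(self.counts)) * self.bin_width
        return pd.DataFrame({"bin_lower_um": edges, "count": self.counts})


def _bin_counts(values: np.ndarray, width: float) -> np.ndarray:
    if width <= 0:
        raise MorphologyError("bin/shell width must be positive")
    if values.size == 0:
        return np.zeros(0, dtype=int)
    idx = np.floor(values / width).astype(int)
    return np.bincount(idx)


def sholl(
    recon: Reconstruction,
    feature: str = "dendritic_branch_points",
    center: Optional[Sequence[float]] = None,
    shell_width: float = 50.0,
) -> ShollProfile:
    """3-D Sholl profile of dendritic branch points or axon varicosities.

    The center defaults to the soma centroid; shells are half-open
    [k·w, (k+1)·w) in Euclidean distance.
    """
    c = np.asarray(center if center is not None else recon.soma_centroid(), dtype=float)
    if feature == "dendritic_branch_points":
        pts = np.array(
            [
                [n.x, n.y, n.z]
                for n in recon.nodes
                if n.label == DENDRITE
                and sum(1 for ch in recon.children(n.node_id) if ch.label == DENDRITE) >= 2
            ]
        ).reshape(-1, 3)
    elif feature == "varicosities":
        pts = np.array([[v.x, v.y, v.z] for v in recon.varicosities]).reshape(-1, 3)
    else:
        raise MorphologyError(f"unknown Sholl feature {feature!r}")
    radii = np.linalg.norm(pts - c, axis=1) if pts.size else np.zeros(0)
    return ShollProfile(
        center=c,
        shell_width=float(shell_width),
        counts=_bin_counts(radii, shell_width),
        counted_feature=feature,
    )


def varicosity_path_distances(
    recon: Reconstruction, reference: str = "axon_origin"
) -> np.ndarray:
    """Path distance (μm) along the axon to every varicosity.

    Measured from the axon take-off node through the tree to the host node,
    plus the marker's residual Euclidean offset from its host.  With
    ``reference='soma'`` the path from the nearest soma ancestor to the
    take-off node is added.
    """
    takeoff = recon.axon_takeoff()
    dist: dict[int, float] = {takeoff.node_id: 0.0}
    for nid in recon.subtree_ids(takeoff.node_id):
        node = recon.node(nid)
        for child in recon.children(nid):
            if child.label == AXON:
                dist[child.node_id] = dist[nid] + node.distance_to(child)
    offset = 0.0
    if reference == "soma":
        node = takeoff
        while node.label != SOMA:
            up = recon.parent(node)
            if up is None:
                break
            offset += node.distance_to(up)
            node = up
    elif reference != "axon_origin":
        raise MorphologyError(f"unknown path-distance reference {reference!r}")
    out = []
    for v in recon.varicosities:
        if v.host_node_id not in dist:
            raise MorphologyError(
                f"varicosity host node {v.host_node_id} is not on the connected axon"
            )
        host = recon.node(v.host_node_id)
        out.append(dist[v.host_node_id] + math.dist(
            (v.x, v.y, v.z), (host.x, host.y, host.z)
        ) + offset)
    return np.asarray(out, dtype=float)


def path_distance_histogram(
    recon: Reconstruction, bin_width: float = 100.0, reference: str = "axon_origin"
) -> PathDistanceHistogram:
    distances = varicosity_path_distances(recon, reference=reference)
    return PathDistanceHistogram(
        bin_width=float(bin_width),
        counts=_bin_counts(distances, bin_width),
        reference=reference,
    )


# ---------------------------------------------------------------------------
# primary-branch decomposition
# ---------------------------------------------------------------------------


@dataclass
class PrimaryBranch:
    order: int  # 1-based take-off sequence along the main axon
    root_id: int
    node_ids: list[int]


@dataclass
class PrimaryBranchDecomposition:
    main_axon_ids: list[int]
    branches: list[PrimaryBranch] = field(default_factory=list)


def _subtree_length(recon: Reconstruction, root_id: int) -> float:
    total = 0.0
    for nid in recon.subtree_ids(root_id):
        node = recon.node(nid)
        if nid != root_id:
            total += node.distance_to(recon.parent(node))
    return total


def decompose_primary_branches(recon: Reconstruction) -> PrimaryBranchDecomposition:
    """Split the axon into the main axon and its primary branches.

    The main axon follows, from the take-off node, always the child of
    largest diameter (ties: longest subtree).  Every subtree hanging off the
    main axon is one primary branch; branches are numbered in take-off order
    along the main axon.
    """
    takeoff = recon.axon_takeoff()
    main: list[int] = []
    node = takeoff
    while True:
        main.append(node.node_id)
        axon_children = [c for c in recon.children(node.node_id) if c.label == AXON]
        if not axon_children:
            break
        best = max(
            axon_children,
            key=lambda c: (c.diameter, _subtree_length(recon, c.node_id), -c.node_id),
        )
        node = best
    main_set = set(main)
    decomposition = PrimaryBranchDecomposition(main_axon_ids=main)
    order = 0
    for nid in main:
        for child in sorted(recon.children(nid), key=lambda c: c.node_id):
            if child.label != AXON or child.node_id in main_set:
                continue
            ids = recon.subtree_ids(child.node_id)
            if not ids:
                continue
            order += 1
            decomposition.branches.append(
                PrimaryBranch(order=order, root_id=child.node_id, node_ids=ids)
            )
    return decomposition


def _occupied_voxels(
    recon: Reconstruction, node_ids: Sequence[int], origin: np.ndarray, edge: float
) -> set[tuple[int, int, int]]:
    """Voxel indices touched by the branch, sampling each segment densely."""
    ids = set(node_ids)
    pts = [recon.node(nid).xyz for nid in node_ids]
    for nid in node_ids:
        node = recon.node(nid)
        parent = recon.parent(node)
        if parent is None or parent.node_id not in ids:
            continue
        seg = node.xyz - parent.xyz
        length = float(np.linalg.norm(seg))
        n_steps = max(1, int(math.ceil(length / (edge / 4.0))))
        for t in np.linspace(0.0, 1.0, n_steps + 1):
            pts.append(parent.xyz + t * seg)
    idx = np.floor((np.asarray(pts) - origin) / edge).astype(int)
    return {tuple(row) for row in idx}


def branch_overlap(
    recon: Reconstruction,
    decomposition: PrimaryBranchDecomposition,
    voxel_edge: float = 100.0,
) -> np.ndarray:
    """Pairwise territorial overlap of primary branches on a shared voxel grid.

    overlap(i, j) = |voxels(i) ∩ voxels(j)| / min(|voxels(i)|, |voxels(j)|);
    symmetric, in [0, 1], 1 for identical voxel sets, 0 for disjoint ones.
    """
    if voxel_edge <= 0:
        raise MorphologyError("voxel edge must be positive")
    pts = recon.coords_of(AXON)
    origin = pts.min(axis=0)
    occupied = [
        _occupied_voxels(recon, b.node_ids, origin, voxel_edge)
        for b in decomposition.branches
    ]
    k = len(occupied)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            smaller = min(len(occupied[i]), len(occupied[j]))
            if smaller == 0:
                out[i, j] = out[j, i] = 0.0
            else:
                inter = len(occupied[i] & occupied[j])
                out[i, j] = out[j, i] = inter / smaller
    return out


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------


@dataclass
class MorphometrySummary:
    neuron_id: str
    soma_area: Optional[float]
    stem_dendrites: int
    dendrite_extents: Optional[Extents]
    axon_extents: Extents
    total_axon_length: float
    total_axon_volume: float
    axon_branch_points: int
    axon_origin: str
    origin_distance: float
    n_varicosities: int

    def to_row(self) -> dict:
        row = {
            "neuron_id": self.neuron_id,
            "soma_area_um2": self.soma_area,
            "stem_dendrites": self.stem_dendrites,
            "total_axon_length_um": self.total_axon_length,
            "total_axon_volume_um3": self.total_axon_volume,
            "axon_branch_points": self.axon_branch_points,
            "axon_origin": self.axon_origin,
            "origin_distance_um": self.origin_distance,
            "n_varicosities": self.n_varicosities,
        }
        for prefix, ext in (("dendrite", self.dendrite_extents), ("axon", self.axon_extents)):
            for axis in ("rc", "ml", "dv"):
                row[f"{prefix}_{axis}_extent_um"] = (
                    getattr(ext, axis) if ext is not None else None
                )
        return row


def summarize(recon: Reconstruction) -> MorphometrySummary:
    """Compute the per-neuron scalar morphometry table row."""
    origin, distance = axon_origin(recon)
    has_dend = bool(recon.nodes_of(DENDRITE))
    area = None
    if recon.soma_contour is not None and len(recon.soma_contour) >= 3:
        area = soma_area(recon.soma_contour)
    return MorphometrySummary(
        neuron_id=recon.neuron_id,
        soma_area=area,
        stem_dendrites=stem_count(recon),
        dendrite_extents=bounding_extents(recon, DENDRITE) if has_dend else None,
        axon_extents=bounding_extents(recon, AXON),
        total_axon_length=total_length(recon, AXON),
        total_axon_volume=total_volume(recon, AXON),
        axon_branch_points=count_branch_points(recon, AXON),
        axon_origin=origin,
        origin_distance=distance,
        n_varicosities=len(recon.varicosities),
    )
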