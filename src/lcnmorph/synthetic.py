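"""Synthetic local-circuit-neuron arbors with exact ground truth.

Real lamina I LCN reconstructions are built from serial-section tracings; no
such data ship with this package, so every pipeline stage is exercised on
generated arbors that emulate the published summary statistics: a ~22 μm
soma, 2–8 stem dendrites (mean ≈ 4.4), an axon arising from a primary
dendrite in ~64% of cells at ~16 μm from the soma, a thick (0.76 μm,
above-threshold) main axon that loops and then gives off 3–7 thinner primary
branches in an alternating rostral/caudal manner, sub-threshold
(0.2–0.35 μm) varicose terminal twigs carrying thousands of 0.5–1.5 μm
varicosities concentrated near the cell body, a rostrocaudal axonal span of
roughly 2.3 mm, and an optional long, constant-diameter solitary branch
devoid of varicosities that continues the main axon distally.

Every geometric quantity the pipeline measures is recorded in a
:class:`GroundTruth` at construction time, so parameter recovery can be
checked exactly.  Generation is fully deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import (
    AXON,
    DENDRITE,
    SOMA,
    DEFAULT_AXIS_MAP,
    MorphNode,
    MorphologyError,
    Reconstruction,
    Varicosity,
)
from .morphometrics import DENDRITIC, SOMATIC, Extents


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic LCN generator (lengths in μm).

    ``None`` for a drawable field means "draw from the default distribution";
    a value pins it.  Extent targets are hit by a final per-axis rescale with
    ±``extent_jitter`` relative jitter.
    """

    seed: int = 0
    soma_diameter: float = 22.4
    n_stem_dendrites: Optional[int] = None  # draw: round N(4.4, 1.2) clipped [2, 8]
    axon_origin_dendritic_prob: float = 0.64
    origin_distance: Optional[float] = None  # draw: N(16, 8) clipped [3, 60]
    n_primary_branches: Optional[int] = None  # draw: uniform int [3, 7]
    axon_extents: tuple[float, float, float] = (2312.0, 636.0, 295.0)  # rc, ml, dv
    dendrite_extents: tuple[float, float, float] = (320.0, 323.0, 159.0)
    main_axon_diameter: float = 0.76
    primary_trunk_diameter: float = 0.5
    terminal_diameter_range: tuple[float, float] = (0.2, 0.35)
    varicosity_diameter_range: tuple[float, float] = (0.5, 1.5)
    varicosity_spacing: float = 8.0  # node spacing along varicose terminal twigs
    n_varicosities_target: Optional[int] = None
    solitary_branch: Optional[bool] = None  # draw: Bernoulli(solitary_branch_prob)
    solitary_branch_prob: float = 0.33
    solitary_branch_length: float = 1500.0
    extent_jitter: float = 0.02

    def validate(self) -> None:
        for name in ("terminal_diameter_range", "varicosity_diameter_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise MorphologyError(f"{name} must be positive and ordered, got {(lo, hi)}")
        for name in ("axon_origin_dendritic_prob", "solitary_branch_prob"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise MorphologyError(f"{name} must be a probability")
        if self.soma_diameter <= 0 or self.varicosity_spacing <= 0:
            raise MorphologyError("soma diameter and varicosity spacing must be positive")
        if min(self.axon_extents) <= self.soma_diameter:
            raise MorphologyError("axon extent targets smaller than the soma are infeasible")
        if self.n_stem_dendrites is not None and not (2 <= self.n_stem_dendrites <= 8):
            raise MorphologyError("n_stem_dendrites must be in [2, 8]")


@dataclass
class GroundTruth:
    """Exact pipeline quantities recorded while building the arbor."""

    total_axon_length: float
    total_axon_volume: float
    axon_branch_points: int
    n_varicosities: int
    varicosity_xyz: np.ndarray
    n_stem_dendrites: int
    n_primary_branches: int
    axon_origin: str
    origin_distance: float
    axon_extents: Extents
    dendrite_extents: Extents
    main_axon_ids: list[int] = field(default_factory=list)
    branch_node_ids: list[list[int]] = field(default_factory=list)
    has_solitary_branch: bool = False

    def to_dict(self) -> dict:
        return {
            "total_axon_length_um": self.total_axon_length,
            "total_axon_volume_um3": self.total_axon_volume,
            "axon_branch_points": self.axon_branch_points,
            "n_varicosities": self.n_varicosities,
            "n_stem_dendrites": self.n_stem_dendrites,
            "n_primary_branches": self.n_primary_branches,
            "axon_origin": self.axon_origin,
            "origin_distance_um": self.origin_distance,
            "axon_extents_um": list(self.axon_extents),
            "dendrite_extents_um": list(self.dendrite_extents),
            "has_solitary_branch": self.has_solitary_branch,
        }


class _Builder:
    def __init__(self) -> None:
        self.nodes: list[MorphNode] = []
        self.next_id = 1

    def add(self, parent_id, xyz, diameter, label) -> int:
        nid = self.next_id
        self.nodes.append(
            MorphNode(
                node_id=nid,
                parent_id=parent_id,
                x=float(xyz[0]),
                y=float(xyz[1]),
                z=float(xyz[2]),
                diameter=float(diameter),
                label=label,
            )
        )
        self.next_id += 1
        return nid


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# geometry knobs of the default preset (not part of the public spec surface):
# dendrite stems have a graded-step trunk with one bifurcation into two
# 2-segment daughters; primary-branch trunks step 50 μm; terminal twigs are a
# 3-node stem bifurcating into two 4-node daughters at the varicosity
# spacing, with one varicosity per twig node.  Every trunk node carries one
# diffuse twig; the two leading branches additionally carry dense bouquets of
# _BOUQUET_TWIGS twigs at staggered path offsets, reproducing the compact
# local accumulations of varicosities seen in the published density maps.
_TRUNK_STEP = 50.0
_TWIG_STEM_NODES = 3
_TWIG_DAUGHTER_NODES = 4
_BOUQUET_TWIGS = 14


def _grow_twig(b: _Builder, rng, root_id: int, root_xyz, spacing: float, d_rng) -> list[np.ndarray]:
    """One varicose terminal twig: stem then a bifurcation into two daughters.

    Twigs meander (per-step random-walk directions), like the undulating thin
    varicose branches seen in filled material; this also keeps each twig's
    varicosity cloud compact (RMS reach ≈ spacing·√n)."""
    diameter = rng.uniform(*d_rng)
    positions: list[np.ndarray] = []
    xyz = np.array(root_xyz, dtype=float)
    last = root_id
    for _ in range(_TWIG_STEM_NODES):
        xyz = xyz + _unit(rng.normal(size=3)) * spacing
        last = b.add(last, xyz, diameter, AXON)
        positions.append(xyz.copy())
    fork_id, fork_xyz = last, xyz.copy()
    for _ in range(2):
        xyz = fork_xyz.copy()
        last = fork_id
        for _ in range(_TWIG_DAUGHTER_NODES):
            xyz = xyz + _unit(rng.normal(size=3)) * spacing
            last = b.add(last, xyz, diameter, AXON)
            positions.append(xyz.copy())
    return positions


def generate_lcn(spec: SyntheticSpec) -> tuple[Reconstruction, GroundTruth]:
    """Generate one synthetic LCN and its exact ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    b = _Builder()

    # --- soma: ring of 12 contour points in the sagittal (rc-dv) plane -----
    r_soma = spec.soma_diameter / 2.0
    angles = np.linspace(0.0, 2.0 * math.pi, 12, endpoint=False)
    soma_ids = []
    prev = None
    for a in angles:
        prev = b.add(prev, (r_soma * math.cos(a), r_soma * math.sin(a), 0.0), spec.soma_diameter, SOMA)
        soma_ids.append(prev)
    soma_xyz = {sid: b.nodes[sid - 1].xyz for sid in soma_ids}

    # --- dendrites ---------------------------------------------------------
    n_stem = spec.n_stem_dendrites
    if n_stem is None:
        n_stem = int(np.clip(round(rng.normal(4.4, 1.2)), 2, 8))
    stem_paths: list[list[int]] = []  # trunk + first-daughter path per stem
    first_dendrite_idx = len(b.nodes)
    for i in range(n_stem):
        phi = 2.0 * math.pi * i / n_stem + rng.normal(scale=0.25)
        elev = rng.normal(scale=math.radians(15.0))
        direction = np.array(
            [math.cos(phi) * math.cos(elev), math.sin(elev), math.sin(phi) * math.cos(elev)]
        )
        # attach to the ring node whose angular position is closest
        ring = min(soma_ids, key=lambda sid: np.linalg.norm(_unit(soma_xyz[sid]) - _unit(direction)))
        xyz = soma_xyz[ring].copy()
        path = [ring]
        last = ring
        trunk_ids = []
        # graded steps: a short first segment keeps dendritic axon origins
        # close to the soma, as in the recorded 3-60 μm range
        for k, step in enumerate((15.0, 30.0, 45.0, 50.0, 40.0)):
            xyz = xyz + direction * step + rng.normal(scale=3.0, size=3)
            d = 2.0 - 0.25 * k
            last = b.add(last, xyz, d, DENDRITE)
            trunk_ids.append(last)
            path.append(last)
        # one bifurcation at the 2nd trunk node
        fork = trunk_ids[1]
        fork_xyz = b.nodes[fork - 1].xyz
        for s in (-1.0, 1.0):
            ddir = _unit(direction + s * 0.5 * rng.normal(scale=1.0, size=3))
            xyz2 = fork_xyz.copy()
            last2 = fork
            for _ in range(2):
                xyz2 = xyz2 + ddir * 30.0 + rng.normal(scale=3.0, size=3)
                last2 = b.add(last2, xyz2, 0.8, DENDRITE)
        stem_paths.append(path)

    # rescale dendrites to the target extents (about the soma centre)
    dend_targets = {
        "rc": spec.dendrite_extents[0],
        "ml": spec.dendrite_extents[1],
        "dv": spec.dendrite_extents[2],
    }
    axis_cols = {"rc": 0, "dv": 1, "ml": 2}  # default sagittal axis map
    dend_nodes = [n for n in b.nodes if n.label == DENDRITE]
    pts = np.array([[n.x, n.y, n.z] for n in dend_nodes])
    span = pts.max(axis=0) - pts.min(axis=0)
    factors = np.ones(3)
    for axis, col in axis_cols.items():
        target = dend_targets[axis] * (1.0 + rng.uniform(-spec.extent_jitter, spec.extent_jitter))
        factors[col] = target / span[col]
    for n in dend_nodes:
        b.nodes[n.node_id - 1] = MorphNode(
            node_id=n.node_id,
            parent_id=n.parent_id,
            x=n.x * factors[0],
            y=n.y * factors[1],
            z=n.z * factors[2],
            diameter=n.diameter,
            label=n.label,
        )

    node_xyz = lambda nid: b.nodes[nid - 1].xyz  # noqa: E731

    # --- axon origin -------------------------------------------------------
    dendritic = rng.random() < spec.axon_origin_dendritic_prob
    if dendritic:
        target_dist = spec.origin_distance
        if target_dist is None:
            target_dist = float(np.clip(rng.normal(16.0, 8.0), 3.0, 60.0))
        path = stem_paths[int(rng.integers(0, n_stem))]
        # walk the (scaled) stem, pick the dendrite node nearest the target distance
        cum = 0.0
        best_nid, best_err = path[1], math.inf
        prev_xyz = node_xyz(path[0])
        for nid in path[1:]:
            xyz = node_xyz(nid)
            cum += float(np.linalg.norm(xyz - prev_xyz))
            prev_xyz = xyz
            if abs(cum - target_dist) < best_err:
                best_nid, best_err = nid, abs(cum - target_dist)
        attach_id = best_nid
        origin = DENDRITIC
    else:
        attach_id = soma_ids[0]
        origin = SOMATIC

    attach_xyz = node_xyz(attach_id)
    takeoff_xyz = attach_xyz + _unit(rng.normal(size=3)) * 1.5
    takeoff_id = b.add(attach_id, takeoff_xyz, spec.main_axon_diameter, AXON)

    # --- main axon: ventrodorsal loop then a winding rostral run -----------
    main_ids = [takeoff_id]
    last = takeoff_id
    xyz = takeoff_xyz.copy()
    loop_r = 35.0
    for k in range(1, 9):
        theta = math.pi * k / 8.0
        xyz = takeoff_xyz + np.array(
            [6.0 * k, loop_r * math.sin(theta), loop_r * (1.0 - math.cos(theta))]
        )
        last = b.add(last, xyz, spec.main_axon_diameter, AXON)
        main_ids.append(last)
    run_ids = []
    for k in range(1, 11):
        xyz = xyz + np.array(
            [40.0, 15.0 * math.sin(0.9 * k) - xyz[1] * 0.1, 15.0 * math.cos(0.9 * k) - xyz[2] * 0.1]
        )
        last = b.add(last, xyz, spec.main_axon_diameter, AXON)
        main_ids.append(last)
        run_ids.append(last)

    # --- primary branches, alternating rostral/caudal ----------------------
    n_pb = spec.n_primary_branches
    if n_pb is None:
        n_pb = int(rng.integers(3, 8))
    # the last run node stays branch-free so the main axon has a bare tip
    takeoff_nodes = [run_ids[int(i)] for i in np.linspace(0, len(run_ids) - 2, n_pb)]
    rc_half = spec.axon_extents[0] / 2.0
    branch_node_ids: list[list[int]] = []
    varicosity_xyz: list[np.ndarray] = []
    varicosity_host: list[int] = []
    d_lo, d_hi = spec.terminal_diameter_range

    solitary = spec.solitary_branch
    if solitary is None:
        solitary = bool(rng.random() < spec.solitary_branch_prob)

    # the first rostral and first caudal branches carry the rostrocaudal span;
    # the rest stay local
    lengths = [
        rc_half * 0.92 if bi < 2 else float(rng.uniform(350.0, 900.0))
        for bi in range(n_pb)
    ]

    for bi, root in enumerate(takeoff_nodes):
        sign = 1.0 if bi % 2 == 0 else -1.0
        length = lengths[bi]
        # branches on the same side fan out mediolaterally so their varicose
        # target fields occupy distinct territories (overlap stays partial)
        ml_center = (-24.0, -8.0, 8.0, 24.0)[(bi // 2) % 4]
        theta_ml = math.radians(ml_center + rng.uniform(-6.0, 6.0))
        theta_dv = rng.uniform(-math.radians(10.0), math.radians(10.0))
        heading = np.array(
            [
                sign * math.cos(theta_ml) * math.cos(theta_dv),
                math.sin(theta_dv),
                math.sin(theta_ml) * math.cos(theta_dv),
            ]
        )
        n_steps = max(2, int(round(length / _TRUNK_STEP)))
        first_branch_node = b.next_id
        xyz = node_xyz(root).copy()
        last = root
        trunk_ids = []
        for k in range(n_steps):
            xyz = xyz + heading * _TRUNK_STEP + rng.normal(scale=6.0, size=3)
            # the myelinated-appearance persists only over the proximal part;
            # beyond ~300 μm the trunk thins below the myelination threshold
            d = spec.primary_trunk_diameter if (k + 1) * _TRUNK_STEP <= 300.0 else 0.3
            last = b.add(last, xyz, d, AXON)
            trunk_ids.append(last)
        # diffuse varicose cover: one meandering twig per trunk node, plus
        # dense terminal bouquets on the two leading branches, staggered along
        # the path — the "local accumulations" of varicosities that dominate
        # the density maps near (but not centered on) the soma
        bouquet_nodes = set()
        if bi < 2:
            bouquet_nodes = {3, 8, 13, 18}  # path offsets 200/450/700/950 μm
        for k, tid in enumerate(trunk_ids[:-1]):
            n_twigs = 1 + (_BOUQUET_TWIGS if k in bouquet_nodes else 0)
            for _ in range(n_twigs):
                positions = _grow_twig(
                    b, rng, tid, node_xyz(tid), spec.varicosity_spacing, (d_lo, d_hi)
                )
                # one varicosity per twig node, placed exactly at the node
                start = b.next_id - len(positions)
                for off, pos in enumerate(positions):
                    varicosity_xyz.append(pos)
                    varicosity_host.append(start + off)
        branch_node_ids.append(list(range(first_branch_node, b.next_id)))

    # --- optional solitary branch: distal continuation of the main axon ----
    if solitary:
        xyz = node_xyz(main_ids[-1]).copy()
        heading = np.array([math.cos(math.radians(8.0)), math.sin(math.radians(8.0)), 0.0])
        last = main_ids[-1]
        for _ in range(int(round(spec.solitary_branch_length / 100.0))):
            xyz = xyz + heading * 100.0 + rng.normal(scale=3.0, size=3)
            last = b.add(last, xyz, spec.main_axon_diameter, AXON)
            main_ids.append(last)

    # --- rescale the axon (and markers) to the target extents --------------
    axon_nodes = [n for n in b.nodes if n.label == AXON]
    pts = np.array([[n.x, n.y, n.z] for n in axon_nodes])
    span = pts.max(axis=0) - pts.min(axis=0)
    axon_targets = {
        "rc": spec.axon_extents[0],
        "ml": spec.axon_extents[1],
        "dv": spec.axon_extents[2],
    }
    factors = np.ones(3)
    for axis, col in axis_cols.items():
        target = axon_targets[axis] * (1.0 + rng.uniform(-spec.extent_jitter, spec.extent_jitter))
        factors[col] = target / span[col]
    center = takeoff_xyz
    for n in axon_nodes:
        p = center + (n.xyz - center) * factors
        b.nodes[n.node_id - 1] = MorphNode(
            node_id=n.node_id,
            parent_id=n.parent_id,
            x=p[0],
            y=p[1],
            z=p[2],
            diameter=n.diameter,
            label=n.label,
        )
    varicosity_xyz = [center + (p - center) * factors for p in varicosity_xyz]

    # --- optional down-sampling to an exact varicosity count ----------------
    keep = np.arange(len(varicosity_xyz))
    if spec.n_varicosities_target is not None and spec.n_varicosities_target < len(keep):
        keep = np.sort(rng.choice(keep, size=spec.n_varicosities_target, replace=False))
    varicosities = [
        Varicosity(
            x=float(varicosity_xyz[i][0]),
            y=float(varicosity_xyz[i][1]),
            z=float(varicosity_xyz[i][2]),
            diameter=float(rng.uniform(*spec.varicosity_diameter_range)),
            host_node_id=varicosity_host[i],
        )
        for i in keep
    ]

    contour = np.array([[n.x, n.y, n.z] for n in b.nodes if n.label == SOMA])
    recon = Reconstruction(
        neuron_id=f"synthetic-lcn-{spec.seed}",
        nodes=b.nodes,
        soma_contour=contour,
        varicosities=varicosities,
        axis_map=dict(DEFAULT_AXIS_MAP),
    )

    truth = _measure_ground_truth(
        recon,
        origin=origin,
        attach_id=attach_id,
        takeoff_id=takeoff_id,
        n_stem=n_stem,
        n_pb=n_pb,
        main_ids=main_ids,
        branch_node_ids=branch_node_ids,
        solitary=solitary,
    )
    return recon, truth


def _measure_ground_truth(
    recon: Reconstruction,
    *,
    origin: str,
    attach_id: int,
    takeoff_id: int,
    n_stem: int,
    n_pb: int,
    main_ids: list[int],
    branch_node_ids: list[list[int]],
    solitary: bool,
) -> GroundTruth:
    """Record the constructed quantities, mirroring the measurement conventions."""
    length = 0.0
    volume = 0.0
    children_axon: dict[int, int] = {}
    for n in recon.nodes:
        if n.parent_id is None or n.label != AXON:
            continue
        p = recon.node(n.parent_id)
        seg = n.distance_to(p)
        length += seg
        volume += math.pi * seg / 12.0 * (
            p.diameter**2 + p.diameter * n.diameter + n.diameter**2
        )
        if p.label == AXON:
            children_axon[p.node_id] = children_axon.get(p.node_id, 0) + 1
    branch_points = sum(1 for c in children_axon.values() if c >= 2)

    # origin distance: up-walk from the dendrite attachment point to the soma
    dist = 0.0
    if origin == DENDRITIC:
        node = recon.node(attach_id)
        while node.label != SOMA:
            up = recon.node(node.parent_id)
            dist += node.distance_to(up)
            node = up

    def extents(label: str) -> Extents:
        pts = recon.coords_of(label)
        span = pts.max(axis=0) - pts.min(axis=0)
        return Extents(rc=float(span[0]), ml=float(span[2]), dv=float(span[1]))

    return GroundTruth(
        total_axon_length=float(length),
        total_axon_volume=float(volume),
        axon_branch_points=branch_points,
        n_varicosities=len(recon.varicosities),
        varicosity_xyz=np.array([[v.x, v.y, v.z] for v in recon.varicosities]).reshape(-1, 3),
        n_stem_dendrites=n_stem,
        n_primary_branches=n_pb,
        axon_origin=origin,
        origin_distance=float(dist),
        axon_extents=extents(AXON),
        dendrite_extents=extents(DENDRITE),
        main_axon_ids=list(main_ids),
        branch_node_ids=[list(ids) for ids in branch_node_ids],
        has_solitary_branch=solitary,
    )


def generate_straight_axon(
    length: float, diameter: float, n_nodes: int, *, neuron_id: str = "straight-axon"
) -> Reconstruction:
    """A collinear, uniform-diameter axon from a point soma (analytic fixture).

    The first axon node coincides with the soma, so the path distance from
    the take-off point to the tip equals ``length`` exactly.
    """
    if length <= 0 or diameter <= 0 or n_nodes < 2:
        raise MorphologyError("need positive length/diameter and at least 2 nodes")
    b = _Builder()
    soma = b.add(None, (0.0, 0.0, 0.0), 10.0, SOMA)
    step = length / (n_nodes - 1)
    last = soma
    for k in range(n_nodes):
        last = b.add(last, (k * step, 0.0, 0.0), diameter, AXON)
    return Reconstruction(neuron_id=neuron_id, nodes=b.nodes)
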