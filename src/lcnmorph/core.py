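"""Core data model for reconstructed neurons.

A reconstruction is a forest of rooted trees over traced points
(:class:`MorphNode`), each point carrying a position in μm, a local process
diameter and a structure label (soma / axon / dendrite), plus a planar soma
contour and a set of point-like axonal varicosity markers.  Node order is
topological: every non-root node's parent precedes it, which lets all
traversals run as single forward/backward passes over the node list.

Anatomical axes (rostrocaudal, dorsoventral, mediolateral) are decoupled from
the file's x/y/z via ``axis_map``; the default corresponds to sagittal
sectioning (x = rostrocaudal, y = dorsoventral, z = mediolateral).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np

SOMA = "soma"
AXON = "axon"
DENDRITE = "dendrite"

LABELS = (SOMA, AXON, DENDRITE)

#: anatomical axis -> coordinate letter, sagittal sectioning convention
DEFAULT_AXIS_MAP = {"rc": "x", "dv": "y", "ml": "z"}

_COORD_INDEX = {"x": 0, "y": 1, "z": 2}


class MorphologyError(ValueError):
    """Raised when a reconstruction violates a structural invariant."""


@dataclass(frozen=True)
class MorphNode:
    """One traced point of a neuron."""

    node_id: int
    parent_id: Optional[int]
    x: float
    y: float
    z: float
    diameter: float
    label: str

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def distance_to(self, other: "MorphNode") -> float:
        return math.dist((self.x, self.y, self.z), (other.x, other.y, other.z))


@dataclass(frozen=True)
class Varicosity:
    """A point-like axonal swelling (en passant varicosity or terminal bouton)."""

    x: float
    y: float
    z: float
    diameter: float
    host_node_id: int

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Reconstruction:
    """A neuron: soma contour, dendrite/axon trees and varicosity markers."""

    neuron_id: str
    nodes: list[MorphNode]
    soma_contour: Optional[np.ndarray] = None
    varicosities: list[Varicosity] = field(default_factory=list)
    axis_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_AXIS_MAP))

    def __post_init__(self) -> None:
        self._by_id: dict[int, MorphNode] = {}
        self._children: dict[int, list[int]] = {}
        for node in self.nodes:
            if node.node_id in self._by_id:
                raise MorphologyError(f"duplicate node id {node.node_id}")
            if node.diameter <= 0:
                raise MorphologyError(
                    f"node {node.node_id}: non-positive diameter {node.diameter}"
                )
            if node.label not in LABELS:
                raise MorphologyError(f"node {node.node_id}: unknown label {node.label!r}")
            if node.parent_id is not None and node.parent_id not in self._by_id:
                raise MorphologyError(
                    f"node {node.node_id}: parent {node.parent_id} does not precede it"
                )
            self._by_id[node.node_id] = node
            self._children.setdefault(node.node_id, [])
            if node.parent_id is not None:
                self._children[node.parent_id].append(node.node_id)
        if set(self.axis_map.keys()) != {"rc", "dv", "ml"} or set(
            self.axis_map.values()
        ) != {"x", "y", "z"}:
            raise MorphologyError(f"axis_map is not a bijection: {self.axis_map}")

    # -- basic accessors -------------------------------------------------

    def node(self, node_id: int) -> MorphNode:
        return self._by_id[node_id]

    def has_node(self, node_id: int) -> bool:
        return node_id in self._by_id

    def children(self, node_id: int) -> list[MorphNode]:
        return [self._by_id[i] for i in self._children.get(node_id, [])]

    def parent(self, node: MorphNode) -> Optional[MorphNode]:
        return None if node.parent_id is None else self._by_id[node.parent_id]

    def nodes_of(self, label: str) -> list[MorphNode]:
        return [n for n in self.nodes if n.label == label]

    def coords_of(self, label: Optional[str] = None) -> np.ndarray:
        sel = self.nodes if label is None else self.nodes_of(label)
        if not sel:
            return np.empty((0, 3))
        return np.array([[n.x, n.y, n.z] for n in sel])

    def axis_index(self, anatomical: str) -> int:
        """Column index (0/1/2) of an anatomical axis ('rc', 'dv' or 'ml')."""
        return _COORD_INDEX[self.axis_map[anatomical]]

    # -- segments --------------------------------------------------------

    def iter_segments(self, label: Optional[str] = None) -> Iterator[tuple[MorphNode, MorphNode]]:
        """Yield (parent, child) pairs; a segment belongs to its child's label."""
        for node in self.nodes:
            if node.parent_id is None:
                continue
            if label is not None and node.label != label:
                continue
            yield self._by_id[node.parent_id], node

    # -- landmarks -------------------------------------------------------

    def soma_centroid(self) -> np.ndarray:
        soma_nodes = self.nodes_of(SOMA)
        if soma_nodes:
            return np.array([[n.x, n.y, n.z] for n in soma_nodes]).mean(axis=0)
        if self.soma_contour is not None and len(self.soma_contour):
            return np.asarray(self.soma_contour, dtype=float).mean(axis=0)
        raise MorphologyError("reconstruction has no soma nodes or contour")

    def axon_takeoff(self) -> MorphNode:
        """The unique axon node whose parent is absent or non-axon."""
        candidates = [
            n
            for n in self.nodes
            if n.label == AXON
            and (n.parent_id is None or self._by_id[n.parent_id].label != AXON)
        ]
        if len(candidates) != 1:
            ids = [n.node_id for n in candidates]
            raise MorphologyError(
                f"expected exactly one axon take-off node, found {len(candidates)}: {ids}"
            )
        return candidates[0]

    # -- path metrics ----------------------------------------------------

    def path_distance_up_to(self, node_id: int, ancestor_id: int) -> float:
        """Sum of segment lengths along the unique path from node up to ancestor."""
        total = 0.0
        node = self._by_id[node_id]
        while node.node_id != ancestor_id:
            parent = self.parent(node)
            if parent is None:
                raise MorphologyError(
                    f"node {ancestor_id} is not an ancestor of node {node_id}"
                )
            total += node.distance_to(parent)
            node = parent
        return total

    def subtree_ids(self, root_id: int) -> list[int]:
        """All node ids in the subtree rooted at ``root_id`` (inclusive), preorder."""
        out: list[int] = []
        stack = [root_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(reversed(self._children.get(nid, [])))
        return out

    # -- transforms ------------------------------------------------------

    def with_nodes(
        self,
        nodes: Iterable[MorphNode],
        varicosities: Optional[list[Varicosity]] = None,
        soma_contour: Optional[np.ndarray] = None,
    ) -> "Reconstruction":
        return Reconstruction(
            neuron_id=self.neuron_id,
            nodes=list(nodes),
            soma_contour=self.soma_contour if soma_contour is None else soma_contour,
            varicosities=list(self.varicosities) if varicosities is None else varicosities,
            axis_map=dict(self.axis_map),
        )

    def transformed(self, fn) -> "Reconstruction":
        """Apply a point transform ``fn: (m,3) array -> (m,3) array`` to all geometry."""
        pts = self.coords_of()
        new_pts = np.asarray(fn(pts), dtype=float)
        nodes = [
            replace(n, x=p[0], y=p[1], z=p[2]) for n, p in zip(self.nodes, new_pts)
        ]
        contour = None
        if self.soma_contour is not None:
            contour = np.asarray(fn(np.asarray(self.soma_contour, dtype=float)))
        varis = []
        if self.varicosities:
            vpts = np.array([[v.x, v.y, v.z] for v in self.varicosities])
            vnew = np.asarray(fn(vpts), dtype=float)
            varis = [
                replace(v, x=p[0], y=p[1], z=p[2])
                for v, p in zip(self.varicosities, vnew)
            ]
        return Reconstruction(
            neuron_id=self.neuron_id,
            nodes=nodes,
            soma_contour=contour,
            varicosities=varis,
            axis_map=dict(self.axis_map),
        )

    # -- validation ------------------------------------------------------

    def validate(
        self,
        varicosity_diameter_range: tuple[float, float] = (0.1, 5.0),
        attachment_tolerance: float = 2.0,
    ) -> None:
        """Check type invariants beyond those enforced at construction."""
        soma_roots = {
            self._root_of(n.node_id) for n in self.nodes if n.label == SOMA
        }
        if self.nodes_of(SOMA) and len(soma_roots) != 1:
            raise MorphologyError(
                f"soma nodes are spread over {len(soma_roots)} trees"
            )
        lo, hi = varicosity_diameter_range
        for i, v in enumerate(self.varicosities):
            if not (lo <= v.diameter <= hi):
                raise MorphologyError(
                    f"varicosity {i}: diameter {v.diameter} outside [{lo}, {hi}]"
                )
            host = self._by_id.get(v.host_node_id)
            if host is None:
                raise MorphologyError(f"varicosity {i}: host node {v.host_node_id} missing")
            if host.label != AXON:
                raise MorphologyError(
                    f"varicosity {i}: host node {v.host_node_id} is {host.label}, not axon"
                )
            if math.dist((v.x, v.y, v.z), (host.x, host.y, host.z)) > attachment_tolerance:
                raise MorphologyError(
                    f"varicosity {i} farther than {attachment_tolerance} μm from host node"
                )

    def _root_of(self, node_id: int) -> int:
        node = self._by_id[node_id]
        while node.parent_id is not None:
            node = self._by_id[node.parent_id]
        return node.node_id
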