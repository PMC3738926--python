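"""Reading and writing neuron morphologies and varicosity markers.

Formats
-------
SWC
    Standard 7-column plain text (``id type x y z radius parent``), 1-based
    ids, type codes 1 = soma, 2 = axon, 3/4 = dendrite.  Coordinates and radii
    are in μm and are written with 6 decimals, so a round-trip preserves them
    far below the 10⁻³ μm contract.
Marker CSV
    Varicosities live in a sidecar table with header
    ``x,y,z,diameter[,host_node_id]`` because SWC has no marker concept.
    Markers without an explicit host are attached to the nearest axon node
    within a tolerance (default 2 μm); ties go to the lowest node id.
ASC subset
    A restricted Neurolucida-ASC dialect (grammar in the README): top-level
    parenthesized blocks labelled ``CellBody``, ``Axon``, ``Dendrite`` or
    ``Marker``, containing ``(x y z d)`` samples; a nested parenthesized group
    with ``|`` separators splits a tree into child branches.
Exports
    Per-node scalars as extended SWC (8th column) or legacy-VTK polylines with
    point data; voxel grids as legacy-VTK STRUCTURED_POINTS or CSV.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

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

PathLike = Union[str, Path]

_SWC_TYPE_TO_LABEL = {1: SOMA, 2: AXON, 3: DENDRITE, 4: DENDRITE}
_LABEL_TO_SWC_TYPE = {SOMA: 1, AXON: 2, DENDRITE: 3}


class SwcParseError(MorphologyError):
    """Malformed SWC content; carries the offending line number."""


class AscParseError(MorphologyError):
    """Malformed ASC content; names the offending construct."""


class MarkerAttachmentError(MorphologyError):
    """A marker lies farther than the tolerance from every axon node."""


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------


def read_swc(
    path: PathLike,
    marker_path: Optional[PathLike] = None,
    *,
    attachment_tolerance: float = 2.0,
    axis_map: Optional[dict[str, str]] = None,
    neuron_id: Optional[str] = None,
) -> Reconstruction:
    """Read a 7-column SWC file, optionally with a sidecar varicosity table."""
    path = Path(path)
    nodes: list[MorphNode] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise SwcParseError(f"{path.name}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            node_id = int(parts[0])
            type_code = int(parts[1])
            x, y, z, radius = (float(p) for p in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SwcParseError(f"{path.name}:{lineno}: {exc}") from None
        label = _SWC_TYPE_TO_LABEL.get(type_code)
        if label is None:
            raise SwcParseError(f"{path.name}:{lineno}: unsupported type code {type_code}")
        if radius <= 0:
            raise SwcParseError(f"{path.name}:{lineno}: non-positive radius {radius}")
        nodes.append(
            MorphNode(
                node_id=node_id,
                parent_id=None if parent == -1 else parent,
                x=x,
                y=y,
                z=z,
                diameter=2.0 * radius,
                label=label,
            )
        )
    recon = Reconstruction(
        neuron_id=neuron_id or path.stem,
        nodes=nodes,
        soma_contour=_contour_from_soma_nodes(nodes),
        axis_map=dict(axis_map or DEFAULT_AXIS_MAP),
    )
    if marker_path is not None:
        markers = read_markers(marker_path)
        recon.varicosities.extend(
            attach_markers(recon, markers, tolerance=attachment_tolerance)
        )
    return recon


def _contour_from_soma_nodes(nodes: Sequence[MorphNode]) -> Optional[np.ndarray]:
    soma = [n for n in nodes if n.label == SOMA]
    if len(soma) < 3:
        return None
    return np.array([[n.x, n.y, n.z] for n in soma])


def write_swc(recon: Reconstruction, path: PathLike, marker_path: Optional[PathLike] = None) -> Path:
    """Write a reconstruction as 7-column SWC (μm, radii); optionally markers as CSV."""
    path = Path(path)
    lines = ["# id type x y z radius parent", f"# neuron {recon.neuron_id}"]
    for n in recon.nodes:
        parent = -1 if n.parent_id is None else n.parent_id
        lines.append(
            f"{n.node_id} {_LABEL_TO_SWC_TYPE[n.label]} "
            f"{n.x:.6f} {n.y:.6f} {n.z:.6f} {n.diameter / 2.0:.6f} {parent}"
        )
    path.write_text("\n".join(lines) + "\n")
    if marker_path is not None:
        write_markers(recon.varicosities, marker_path)
    return path


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------


def read_markers(path: PathLike) -> pd.DataFrame:
    """Read a marker CSV with header ``x,y,z,diameter[,host_node_id]``."""
    df = pd.read_csv(path, comment="#")
    required = {"x", "y", "z", "diameter"}
    missing = required - set(df.columns)
    if missing:
        raise MorphologyError(f"marker file {path}: missing columns {sorted(missing)}")
    if "host_node_id" not in df.columns:
        df["host_node_id"] = np.nan
    return df


def write_markers(varicosities: Sequence[Varicosity], path: PathLike) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {"x": v.x, "y": v.y, "z": v.z, "diameter": v.diameter, "host_node_id": v.host_node_id}
            for v in varicosities
        ],
        columns=["x", "y", "z", "diameter", "host_node_id"],
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def attach_markers(
    recon: Reconstruction,
    markers: pd.DataFrame,
    *,
    tolerance: float = 2.0,
) -> list[Varicosity]:
    """Resolve marker rows to varicosities hosted on axon nodes.

    Rows with an explicit ``host_node_id`` use it; the rest attach to the
    nearest axon node.  A marker farther than ``tolerance`` from its host (or
    from every axon node) raises :class:`MarkerAttachmentError` listing it.
    """
    axon_nodes = recon.nodes_of(AXON)
    if markers.empty:
        return []
    if not axon_nodes:
        raise MarkerAttachmentError("reconstruction has no axon nodes to host markers")
    axon_ids = np.array([n.node_id for n in axon_nodes])
    axon_xyz = np.array([[n.x, n.y, n.z] for n in axon_nodes])
    tree = cKDTree(axon_xyz)
    out: list[Varicosity] = []
    failures: list[str] = []
    for idx, row in markers.iterrows():
        p = (float(row["x"]), float(row["y"]), float(row["z"]))
        host = row.get("host_node_id")
        if host is not None and not (isinstance(host, float) and math.isnan(host)):
            host_id = int(host)
            if not recon.has_node(host_id):
                failures.append(f"marker {idx} at {p}: host node {host_id} not found")
                continue
            hn = recon.node(host_id)
            dist = math.dist(p, (hn.x, hn.y, hn.z))
        else:
            dist, j = tree.query(p)
            # ties broken deterministically toward the lowest node id
            near = tree.query_ball_point(p, dist + 1e-9)
            host_id = int(axon_ids[near].min()) if near else int(axon_ids[j])
        if dist > tolerance:
            failures.append(
                f"marker {idx} at {p}: nearest axon node {host_id} is {dist:.3f} μm away "
                f"(tolerance {tolerance} μm)"
            )
            continue
        out.append(
            Varicosity(
                x=p[0], y=p[1], z=p[2], diameter=float(row["diameter"]), host_node_id=host_id
            )
        )
    if failures:
        raise MarkerAttachmentError("; ".join(failures))
    return out


# ---------------------------------------------------------------------------
# ASC subset
# ---------------------------------------------------------------------------

_TREE_LABELS = {"cellbody": SOMA, "axon": AXON, "dendrite": DENDRITE}
_MARKER_LABELS = {"marker", "varicosity"}


def _tokenize_asc(text: str) -> list[str]:
    tokens: list[str] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c in "();|":
            if c == ";":  # comment to end of line
                while i < n and text[i] != "\n":
                    i += 1
                continue
            tokens.append(c)
            i += 1
        elif c == '"':
            j = text.index('"', i + 1)
            tokens.append(text[i + 1 : j])
            i = j + 1
        elif c.isspace():
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "();|":
                j += 1
            tokens.append(text[i:j])
            i = j
    return tokens


def _parse_group(tokens: list[str], pos: int):
    """Parse one parenthesized group starting at tokens[pos] == '('.

    Returns (samples, children, markers?) content as a nested structure:
    a group is a list of alternatives (split on '|'), each alternative a list
    of items; an item is either a 4-float sample tuple or a nested group.
    """
    if tokens[pos] != "(":
        raise AscParseError(f"expected '(' at token {pos}, got {tokens[pos]!r}")
    pos += 1
    alternatives: list[list] = [[]]
    while True:
        if pos >= len(tokens):
            raise AscParseError("unbalanced parentheses: unexpected end of file")
        tok = tokens[pos]
        if tok == ")":
            return alternatives, pos + 1
        if tok == "|":
            alternatives.append([])
            pos += 1
        elif tok == "(":
            sub, pos = _parse_group(tokens, pos)
            alternatives[-1].append(sub)
        else:
            alternatives[-1].append(tok)
            pos += 1


def _is_sample(item) -> bool:
    if not isinstance(item, list) or len(item) != 1 or len(item[0]) != 4:
        return False
    try:
        [float(v) for v in item[0]]
        return True
    except (TypeError, ValueError):
        return False


def _sample(item) -> tuple[float, float, float, float]:
    x, y, z, d = (float(v) for v in item[0])
    return x, y, z, d


def read_neurolucida_asc(
    path: PathLike,
    *,
    attachment_tolerance: float = 2.0,
    axis_map: Optional[dict[str, str]] = None,
    neuron_id: Optional[str] = None,
) -> Reconstruction:
    """Read the documented ASC subset into a :class:`Reconstruction`."""
    path = Path(path)
    tokens = _tokenize_asc(path.read_text())
    blocks = []
    pos = 0
    while pos < len(tokens):
        if tokens[pos] != "(":
            raise AscParseError(f"unexpected top-level token {tokens[pos]!r}")
        group, pos = _parse_group(tokens, pos)
        blocks.append(group)

    nodes: list[MorphNode] = []
    marker_rows: list[dict] = []
    next_id = 1
    soma_root: Optional[int] = None

    def add_node(parent_id, x, y, z, d, label) -> int:
        nonlocal next_id
        nodes.append(
            MorphNode(node_id=next_id, parent_id=parent_id, x=x, y=y, z=z, diameter=d, label=label)
        )
        next_id += 1
        return next_id - 1

    def build_branch(items, parent_id, label) -> None:
        last = parent_id
        for item in items:
            if _is_sample(item):
                x, y, z, d = _sample(item)
                last = add_node(last, x, y, z, d, label)
            elif isinstance(item, list):
                for alternative in item:
                    build_branch(alternative, last, label)
            else:
                raise AscParseError(f"unexpected token {item!r} inside a {label} tree")

    for group in blocks:
        if len(group) != 1:
            raise AscParseError("top-level block must not contain '|'")
        items = group[0]
        if not items or isinstance(items[0], list):
            raise AscParseError("top-level block lacks a label")
        label_tok = str(items[0]).lower()
        body = items[1:]
        if label_tok in _TREE_LABELS:
            label = _TREE_LABELS[label_tok]
            if label == SOMA:
                # contour points become a chained ring of soma nodes
                last = None
                for item in body:
                    if not _is_sample(item):
                        raise AscParseError("CellBody block may contain only samples")
                    x, y, z, d = _sample(item)
                    last = add_node(last, x, y, z, d, SOMA)
                    if soma_root is None:
                        soma_root = last
            else:
                build_branch(body, soma_root, label)
        elif label_tok in _MARKER_LABELS:
            for item in body:
                if not _is_sample(item):
                    raise AscParseError("marker block may contain only samples")
                x, y, z, d = _sample(item)
                marker_rows.append({"x": x, "y": y, "z": z, "diameter": d, "host_node_id": np.nan})
        else:
            raise AscParseError(f"unknown block label {items[0]!r}")

    recon = Reconstruction(
        neuron_id=neuron_id or path.stem,
        nodes=nodes,
        soma_contour=_contour_from_soma_nodes(nodes),
        axis_map=dict(axis_map or DEFAULT_AXIS_MAP),
    )
    if marker_rows:
        recon.varicosities.extend(
            attach_markers(recon, pd.DataFrame(marker_rows), tolerance=attachment_tolerance)
        )
    return recon


# ---------------------------------------------------------------------------
# Annotated / voxel exports
# ---------------------------------------------------------------------------


def write_annotated(
    recon: Reconstruction, per_node_scalar: Mapping[int, float], path: PathLike
) -> Path:
    """Write an extended SWC with one scalar per node in an 8th column."""
    path = Path(path)
    missing = [n.node_id for n in recon.nodes if n.node_id not in per_node_scalar]
    if missing:
        raise MorphologyError(f"scalar missing for nodes {missing[:10]}")
    lines = ["# id type x y z radius parent scalar"]
    for n in recon.nodes:
        parent = -1 if n.parent_id is None else n.parent_id
        lines.append(
            f"{n.node_id} {_LABEL_TO_SWC_TYPE[n.label]} "
            f"{n.x:.6f} {n.y:.6f} {n.z:.6f} {n.diameter / 2.0:.6f} {parent} "
            f"{float(per_node_scalar[n.node_id]):.6f}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_vtk_polylines(
    recon: Reconstruction, per_node_scalar: Mapping[int, float], path: PathLike
) -> Path:
    """Write the morphology as legacy-VTK polylines with a point-data scalar."""
    path = Path(path)
    missing = [n.node_id for n in recon.nodes if n.node_id not in per_node_scalar]
    if missing:
        raise MorphologyError(f"scalar missing for nodes {missing[:10]}")
    index = {n.node_id: i for i, n in enumerate(recon.nodes)}
    lines = [
        "# vtk DataFile Version 3.0",
        f"lcnmorph morphology {recon.neuron_id}",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(recon.nodes)} float",
    ]
    lines += [f"{n.x:.6f} {n.y:.6f} {n.z:.6f}" for n in recon.nodes]
    edges = [(index[n.parent_id], index[n.node_id]) for n in recon.nodes if n.parent_id is not None]
    lines.append(f"LINES {len(edges)} {3 * len(edges)}")
    lines += [f"2 {a} {b}" for a, b in edges]
    lines += [
        f"POINT_DATA {len(recon.nodes)}",
        "SCALARS annotation float 1",
        "LOOKUP_TABLE default",
    ]
    lines += [f"{float(per_node_scalar[n.node_id]):.6f}" for n in recon.nodes]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_voxels(grid, path: PathLike) -> Path:
    """Export a voxel grid: ``.vtk`` → STRUCTURED_POINTS, else CSV.

    The VTK export carries two cell-data arrays, ``count`` and ``intensity``;
    the intensity doubles as the opacity channel for 3-D viewing.  The CSV has
    columns ``ix,iy,iz,count,intensity`` for occupied voxels plus a header
    comment with origin, edge and dims.
    """
    path = Path(path)
    counts = np.asarray(grid.counts)
    intensity = np.asarray(grid.intensity)
    nx, ny, nz = grid.dims
    if path.suffix.lower() == ".vtk":
        lines = [
            "# vtk DataFile Version 3.0",
            "lcnmorph varicosity voxel grid",
            "ASCII",
            "DATASET STRUCTURED_POINTS",
            f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
            f"ORIGIN {grid.origin[0]:.6f} {grid.origin[1]:.6f} {grid.origin[2]:.6f}",
            f"SPACING {grid.edge:.6f} {grid.edge:.6f} {grid.edge:.6f}",
            f"CELL_DATA {nx * ny * nz}",
            "SCALARS count int 1",
            "LOOKUP_TABLE default",
        ]
        order = [
            str(int(counts[ix, iy, iz]))
            for iz in range(nz)
            for iy in range(ny)
            for ix in range(nx)
        ]
        lines += order
        lines += ["SCALARS intensity float 1", "LOOKUP_TABLE default"]
        lines += [
            f"{intensity[ix, iy, iz]:.6f}"
            for iz in range(nz)
            for iy in range(ny)
            for ix in range(nx)
        ]
        path.write_text("\n".join(lines) + "\n")
    else:
        ix, iy, iz = np.nonzero(counts)
        df = pd.DataFrame(
            {
                "ix": ix,
                "iy": iy,
                "iz": iz,
                "count": counts[ix, iy, iz].astype(int),
                "intensity": intensity[ix, iy, iz],
            }
        )
        header = (
            f"# origin {grid.origin[0]:.6f} {grid.origin[1]:.6f} {grid.origin[2]:.6f} "
            f"edge {grid.edge:.6f} dims {nx} {ny} {nz}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.6f")
    return path
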