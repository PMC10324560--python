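"""Compartment-tree morphologies of cone bipolar cells.

A cell is a rooted tree of cylindrical compartments.  Each compartment is a
node carrying the 3-D position of its distal end, its diameter and a section
label (soma, dendrite, axon or axon terminal); the cylinder runs from the
parent node to the node itself, so a node's "length" is the length of its
parent edge.  The soma (the root) is treated as a sphere.

Coordinates are in micrometres in a right-handed frame with the stimulating
electrode plane at z = 0 and +z pointing from the electrode into the retina:
for an epiretinal electrode the axon terminals of a bipolar cell are the
compartments with the smallest z.

SWC I/O uses the standard 7-column format.  Type codes 1 (soma), 2 (axon)
and 3 (dendrite) keep their usual meanings; the custom code 5 marks axon
terminals, which this model treats as a distinct section because the calcium
channels live there.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "SectionLabel",
    "Compartment",
    "CellMorphology",
    "MorphometryRecord",
    "MorphologyError",
    "read_swc",
    "write_swc",
    "validate",
    "count_bifurcations",
    "count_terminals",
    "axon_path_length",
    "axon_initial_length",
    "segmentize",
    "reposition",
    "measure",
    "compartment_centers",
]


class MorphologyError(ValueError):
    """Raised for malformed SWC input or invalid compartment trees."""


class SectionLabel(IntEnum):
    """Section labels; integer values double as SWC type codes."""

    SOMA = 1
    AXON = 2
    DENDRITE = 3
    AXON_TERMINAL = 5


AXONAL_LABELS = frozenset({SectionLabel.AXON, SectionLabel.AXON_TERMINAL})

_SWC_CODES = {int(v): v for v in SectionLabel}


@dataclass(frozen=True)
class Compartment:
    """A single compartment (one SWC row)."""

    id: int
    parent_id: int  # -1 for the root
    label: SectionLabel
    x: float
    y: float
    z: float
    diameter: float


@dataclass
class CellMorphology:
    """A labeled compartment tree.

    Arrays are aligned and topologically ordered (each parent precedes its
    children).  ``parent`` holds array indices (-1 for the root) while
    ``ids`` preserves the external SWC identifiers.
    """

    ids: np.ndarray  # (n,) int
    parent: np.ndarray  # (n,) int, index into arrays, -1 for root
    labels: np.ndarray  # (n,) int (SectionLabel values)
    xyz: np.ndarray  # (n, 3) float, μm
    diameter: np.ndarray  # (n,) float, μm
    cell_class: str = "ON"  # "ON" | "OFF"
    condition: str = "healthy"  # "healthy" | "degenerate"
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.diameter = np.asarray(self.diameter, dtype=np.float64)

    @property
    def n(self) -> int:
        return len(self.ids)

    def lengths(self) -> np.ndarray:
        """Length of each compartment's parent edge (root: 0)."""
        L = np.zeros(self.n)
        has_parent = self.parent >= 0
        d = self.xyz[has_parent] - self.xyz[self.parent[has_parent]]
        L[has_parent] = np.linalg.norm(d, axis=1)
        return L

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def root(self) -> int:
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        return int(roots[0])

    def is_leaf(self) -> np.ndarray:
        leaf = np.ones(self.n, dtype=bool)
        leaf[self.parent[self.parent >= 0]] = False
        return leaf

    def areas(self) -> np.ndarray:
        """Membrane area per compartment in μm² (soma: sphere, rest: cylinder)."""
        L = self.lengths()
        a = np.pi * self.diameter * L
        soma = self.labels == SectionLabel.SOMA
        a[soma] = np.pi * self.diameter[soma] ** 2
        return a

    def compartments(self) -> Iterable[Compartment]:
        for i in range(self.n):
            pid = int(self.ids[self.parent[i]]) if self.parent[i] >= 0 else -1
            yield Compartment(
                int(self.ids[i]), pid, SectionLabel(int(self.labels[i])),
                *map(float, self.xyz[i]), float(self.diameter[i]),
            )

    def translated(self, offset: Sequence[float]) -> "CellMorphology":
        return replace(self, xyz=self.xyz + np.asarray(offset, dtype=float))

    def copy(self) -> "CellMorphology":
        return replace(
            self, ids=self.ids.copy(), parent=self.parent.copy(),
            labels=self.labels.copy(), xyz=self.xyz.copy(),
            diameter=self.diameter.copy(),
        )


def validate(cell: CellMorphology, require_all_sections: bool = False) -> None:
    """Check the shared tree invariants; raise MorphologyError on violation.

    Checks: a single root, topological ordering (parents precede children),
    connected acyclic graph, positive diameters, and that no axon-terminal
    compartment has a child of another section (terminals form the distal
    ends of the axonal subtree).  With ``require_all_sections`` the cell must
    contain at least one compartment of each of the four labels.
    """
    n = cell.n
    if n == 0:
        raise MorphologyError("empty morphology")
    if not (len(cell.parent) == len(cell.labels) == len(cell.diameter) == n
            and cell.xyz.shape == (n, 3)):
        raise MorphologyError("array shapes inconsistent")
    if np.any(cell.diameter <= 0):
        raise MorphologyError("non-positive diameter")
    if len(np.unique(cell.ids)) != n:
        raise MorphologyError("duplicate compartment ids")
    cell.root()  # exactly one root
    idx = np.arange(n)
    if np.any(cell.parent >= idx):
        raise MorphologyError("parent does not precede child (topological order violated)")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((int(p), i) for i, p in enumerate(cell.parent) if p >= 0)
    if not nx.is_tree(g):
        raise MorphologyError("compartment graph is not a connected acyclic tree")
    for lab in cell.labels:
        if int(lab) not in _SWC_CODES:
            raise MorphologyError(f"unknown section label {lab}")
    term = cell.labels == SectionLabel.AXON_TERMINAL
    bad = term[cell.parent[cell.parent >= 0]] & (
        cell.labels[cell.parent >= 0] != SectionLabel.AXON_TERMINAL
    )
    # a terminal may only parent further terminal pieces
    if np.any(bad):
        raise MorphologyError("axon_terminal compartment has a non-terminal child")
    if require_all_sections:
        present = set(int(v) for v in np.unique(cell.labels))
        missing = {v.name for v in SectionLabel if int(v) not in present}
        if missing:
            raise MorphologyError(f"missing sections: {sorted(missing)}")


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path: str | Path | io.TextIOBase, cell_class: str = "ON",
             condition: str = "healthy", cell_id: str | None = None) -> CellMorphology:
    """Read a 7-column SWC file (id, type, x, y, z, radius, parent).

    Radii are stored as diameters (d = 2 r).  Parents must appear before
    their children; unknown type codes, duplicate ids, forward parent
    references and orphan nodes raise :class:`MorphologyError` naming the
    offending line.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
        name = Path(path).stem
    else:
        text = path.read()
        name = "swc"
    ids: list[int] = []
    parent: list[int] = []
    labels: list[int] = []
    xyz: list[tuple[float, float, float]] = []
    diam: list[float] = []
    index_of: dict[int, int] = {}
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise MorphologyError(f"line {ln}: expected 7 columns, got {len(parts)}")
        try:
            nid = int(parts[0]); code = int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            pid = int(parts[6])
        except ValueError as exc:
            raise MorphologyError(f"line {ln}: {exc}") from None
        if code not in _SWC_CODES:
            raise MorphologyError(f"line {ln}: unknown SWC type code {code}")
        if nid in index_of:
            raise MorphologyError(f"line {ln}: duplicate id {nid}")
        if pid == nid:
            raise MorphologyError(f"line {ln}: node {nid} is its own parent")
        if pid < 0:
            pidx = -1
        elif pid in index_of:
            pidx = index_of[pid]
        else:
            raise MorphologyError(
                f"line {ln}: parent {pid} of node {nid} not defined yet "
                "(forward reference or orphan)")
        index_of[nid] = len(ids)
        ids.append(nid); parent.append(pidx); labels.append(code)
        xyz.append((x, y, z)); diam.append(2.0 * r)
    if not ids:
        raise MorphologyError("no data lines in SWC input")
    cell = CellMorphology(
        np.array(ids), np.array(parent), np.array(labels), np.array(xyz),
        np.array(diam), cell_class=cell_class, condition=condition,
        cell_id=cell_id or name,
    )
    validate(cell)
    return cell


def write_swc(cell: CellMorphology, path: str | Path | io.TextIOBase) -> None:
    """Write a morphology as 7-column SWC (radius = diameter / 2)."""
    lines = [f"# {cell.cell_id} class={cell.cell_class} condition={cell.condition}"]
    for c in cell.compartments():
        lines.append(
            f"{c.id} {int(c.label)} {c.x:.6f} {c.y:.6f} {c.z:.6f} "
            f"{c.diameter / 2.0:.6f} {c.parent_id}")
    text = "\n".join(lines) + "\n"
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------

def _labeled_children(cell: CellMorphology, labels: frozenset) -> list[list[int]]:
    mask = np.isin(cell.labels, [int(l) for l in labels])
    ch: list[list[int]] = [[] for _ in range(cell.n)]
    for i, p in enumerate(cell.parent):
        if p >= 0 and mask[i] and mask[p]:
            ch[p].append(i)
    return ch


def count_bifurcations(cell: CellMorphology,
                       labels: Iterable[SectionLabel] = AXONAL_LABELS) -> int:
    """Number of branch points (nodes with >= 2 children) in the labeled subtree.

    A trifurcation counts once.  Defaults to the axonal subtree (axon and
    axon-terminal compartments), the quantity compared between healthy and
    degenerate cohorts.
    """
    labels = frozenset(labels)
    mask = np.isin(cell.labels, [int(l) for l in labels])
    if not mask.any():
        warnings.warn("no compartments with the requested labels", stacklevel=2)
        return 0
    ch = _labeled_children(cell, labels)
    return int(sum(1 for i in range(cell.n) if mask[i] and len(ch[i]) >= 2))


def count_terminals(cell: CellMorphology) -> int:
    """Number of leaf compartments labeled axon_terminal (synaptic endpoints)."""
    leaf = cell.is_leaf()
    return int(np.sum(leaf & (cell.labels == SectionLabel.AXON_TERMINAL)))


def _axon_origin(cell: CellMorphology) -> int:
    """Index of the first axon-labeled node whose parent is not axonal."""
    axonal = np.isin(cell.labels, [int(l) for l in AXONAL_LABELS])
    if not axonal.any():
        raise MorphologyError("cell has no axonal compartments")
    for i in np.flatnonzero(axonal):
        p = cell.parent[i]
        if p < 0 or not axonal[p]:
            return int(i)
    raise MorphologyError("axonal subtree has no origin")  # pragma: no cover


def _cumulative_lengths(cell: CellMorphology) -> np.ndarray:
    L = cell.lengths()
    cum = np.zeros(cell.n)
    for i in range(cell.n):
        p = cell.parent[i]
        cum[i] = L[i] + (cum[p] if p >= 0 else 0.0)
    return cum


def axon_path_length(cell: CellMorphology,
                     definition: str = "mean_root_to_tip") -> float:
    """Axonal path length in μm.

    ``mean_root_to_tip`` (default): mean over axon terminals of the geodesic
    distance from the axon origin (its attachment to the soma) to the
    terminal tip, including the origin compartment's own edge.
    ``total_cable``: total cable length of the axonal subtree.
    """
    if definition not in ("mean_root_to_tip", "total_cable"):
        raise ValueError(f"unknown path-length definition {definition!r}")
    origin = _axon_origin(cell)
    axonal = np.isin(cell.labels, [int(l) for l in AXONAL_LABELS])
    L = cell.lengths()
    if definition == "total_cable":
        return float(np.sum(L[axonal]))
    leaf = cell.is_leaf()
    tips = np.flatnonzero(leaf & (cell.labels == SectionLabel.AXON_TERMINAL))
    if len(tips) == 0:
        # fall back to axonal leaves for partially labeled cells
        tips = np.flatnonzero(leaf & axonal)
    if len(tips) == 0:
        raise MorphologyError("axonal subtree has no terminals")
    cum = _cumulative_lengths(cell)
    base = cum[origin] - L[origin]  # path length up to the origin's parent
    return float(np.mean(cum[tips] - base))


def axon_initial_length(cell: CellMorphology) -> float:
    """Length of the unbranched initial axon (origin to first branch point), μm.

    The first node with two or more axonal children terminates the initial
    segment and its own edge is included; an unbranched axon is measured to
    its sole tip.
    """
    origin = _axon_origin(cell)
    ch = _labeled_children(cell, AXONAL_LABELS)
    L = cell.lengths()
    total = 0.0
    node = origin
    while True:
        total += L[node]
        kids = ch[node]
        if len(kids) != 1:
            return float(total)
        node = kids[0]


def measure(cell: CellMorphology,
            path_definition: str = "mean_root_to_tip") -> "MorphometryRecord":
    """All §-level morphometrics of a cell in one record."""
    axonal = np.isin(cell.labels, [int(l) for l in AXONAL_LABELS])
    d = cell.diameter[axonal]
    return MorphometryRecord(
        n_bifurcations=count_bifurcations(cell),
        n_terminals=count_terminals(cell),
        path_length=axon_path_length(cell, path_definition),
        axon_initial_length=axon_initial_length(cell),
        diameter_min=float(d.min()),
        diameter_max=float(d.max()),
        diameter_mean=float(d.mean()),
    )


@dataclass(frozen=True)
class MorphometryRecord:
    """Morphometric summary of one cell (all lengths/diameters in μm)."""

    n_bifurcations: int
    n_terminals: int
    path_length: float
    axon_initial_length: float
    diameter_min: float
    diameter_max: float
    diameter_mean: float


# ---------------------------------------------------------------------------
# Spatial refinement and repositioning
# ---------------------------------------------------------------------------

def segmentize(cell: CellMorphology, max_segment_length: float) -> CellMorphology:
    """Split compartments so every edge is at most ``max_segment_length`` μm.

    Positions of the inserted nodes interpolate linearly along the parent
    edge; each piece keeps the original node's diameter and label, so total
    cable length and per-label membrane area are conserved exactly.
    """
    if max_segment_length <= 0:
        raise ValueError("max_segment_length must be positive")
    L = cell.lengths()
    if np.all(L <= max_segment_length + 1e-12):
        return cell.copy()
    ids: list[int] = []
    parent: list[int] = []
    labels: list[int] = []
    xyz: list[np.ndarray] = []
    diam: list[float] = []
    new_index: dict[int, int] = {}

    def add(pidx: int, lab: int, pos: np.ndarray, d: float) -> int:
        ids.append(len(ids) + 1)
        parent.append(pidx)
        labels.append(lab)
        xyz.append(pos)
        diam.append(d)
        return len(ids) - 1

    for i in range(cell.n):
        p = cell.parent[i]
        if p < 0:
            new_index[i] = add(-1, int(cell.labels[i]), cell.xyz[i], float(cell.diameter[i]))
            continue
        k = max(1, int(np.ceil(L[i] / max_segment_length - 1e-12)))
        prev = new_index[int(p)]
        p_pos = cell.xyz[int(p)]
        for j in range(1, k + 1):
            pos = p_pos + (cell.xyz[i] - p_pos) * (j / k)
            prev = add(prev, int(cell.labels[i]), pos, float(cell.diameter[i]))
        new_index[i] = prev
    out = CellMorphology(
        np.array(ids), np.array(parent), np.array(labels), np.array(xyz),
        np.array(diam), cell_class=cell.cell_class, condition=cell.condition,
        cell_id=cell.cell_id,
    )
    validate(out)
    return out


def reposition(cell: CellMorphology, target_distance: float,
               electrode_center: Sequence[float] = (0.0, 0.0, 0.0)) -> CellMorphology:
    """Rigidly translate along z so the nearest axon terminal sits
    ``target_distance`` μm above the electrode plane (z = 0).

    Raises if the target is non-positive or if the translation would push any
    compartment through the electrode plane.
    """
    if target_distance <= 0:
        raise ValueError("target_distance must be positive")
    term = (cell.labels == SectionLabel.AXON_TERMINAL) & cell.is_leaf()
    if not term.any():
        raise MorphologyError("cell has no axon terminals to position")
    z0 = float(electrode_center[2])
    dz = (z0 + target_distance) - float(cell.xyz[term, 2].min())
    moved = cell.translated((0.0, 0.0, dz))
    if float(moved.xyz[:, 2].min()) < z0 - 1e-9:
        raise ValueError(
            "repositioning would place compartments on the electrode side of the plane")
    return moved


def compartment_centers(cell: CellMorphology) -> np.ndarray:
    """(n, 3) centers of each compartment: midpoint of the parent edge
    (the node position itself for the root)."""
    centers = cell.xyz.copy()
    has_parent = cell.parent >= 0
    centers[has_parent] = 0.5 * (cell.xyz[has_parent] + cell.xyz[cell.parent[has_parent]])
    return centers
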