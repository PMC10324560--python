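"""Shared fixtures: small hand-built morphologies and a solved test field."""

from __future__ import annotations

import numpy as np
import pytest

from retisim import field as fld
from retisim import synth
from retisim.morphology import CellMorphology, SectionLabel


def build_cell(rows, cell_class="ON", condition="healthy", cell_id="test"):
    """Build a cell from (label, x, y, z, diameter, parent_index) rows."""
    labels, xyz, diam, parent = [], [], [], []
    for lab, x, y, z, d, p in rows:
        labels.append(int(lab))
        xyz.append((x, y, z))
        diam.append(d)
        parent.append(p)
    n = len(rows)
    return CellMorphology(np.arange(1, n + 1), np.array(parent), np.array(labels),
                          np.array(xyz), np.array(diam), cell_class=cell_class,
                          condition=condition, cell_id=cell_id)


S, A, D, T = (SectionLabel.SOMA, SectionLabel.AXON, SectionLabel.DENDRITE,
              SectionLabel.AXON_TERMINAL)


@pytest.fixture
def y_cell():
    """Soma, 10 μm two-segment stalk, then two 5 μm branches ending in terminals."""
    return build_cell([
        (S, 0, 0, 100, 7.0, -1),
        (D, 0, 0, 103, 1.0, 0),
        (A, 0, 0, 95, 1.0, 0),
        (A, 0, 0, 90, 1.0, 2),      # first branch point (10 μm from soma)
        (T, 3, 0, 86, 0.5, 3),      # 5 μm branch
        (T, -3, 0, 86, 0.5, 3),     # 5 μm branch
    ])


@pytest.fixture
def chain_cell():
    """Unbranched 30 μm axon (3 × 10 μm) ending in one terminal."""
    return build_cell([
        (S, 0, 0, 100, 7.0, -1),
        (D, 0, 0, 103, 1.0, 0),
        (A, 0, 0, 90, 1.0, 0),
        (A, 0, 0, 80, 1.0, 2),
        (T, 0, 0, 70, 1.0, 3),
    ])


@pytest.fixture
def balanced_axon_cell():
    """Balanced binary axonal tree of depth 4: 15 branch nodes, 16 terminals."""
    rows = [(S, 0, 0, 100, 7.0, -1), (D, 0, 0, 103, 1.0, 0)]
    # level-order construction: node index in `rows`, depth
    frontier = []
    rows.append((A, 0.0, 0.0, 95.0, 1.0, 0))
    frontier.append((2, 0, 0.0))
    for depth in range(4):
        nxt = []
        for parent_idx, _, x in frontier:
            for k, dx in enumerate((-8.0 / (depth + 1), 8.0 / (depth + 1))):
                lab = T if depth == 3 else A
                rows.append((lab, x + dx, 0.0, 95.0 - 5.0 * (depth + 1), 1.0, parent_idx))
                nxt.append((len(rows) - 1, depth + 1, x + dx))
        frontier = nxt
    return build_cell(rows)


@pytest.fixture(scope="session")
def on_cell():
    """One calibrated healthy ON cell (fixed seed)."""
    return synth.generate_cell(synth.CALIBRATION[("ON", "healthy")], 1)


@pytest.fixture(scope="session")
def point_source_field():
    """Unit point-ish source in a homogeneous 41³ grid (ρ = 100 Ω·cm)."""
    stack = fld.homogeneous_stack(100.0)
    el = fld.Electrode(diameter=1.0, current=1.0)
    system = fld.assemble_system(stack, el, voxel=5.0, extent=205.0,
                                 z_fraction_below=0.5)
    return system, fld.solve_field(system)
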