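"""Synthetic cone-bipolar-cell morphologies.

Connectome-extracted cells are not publicly retrievable, so this module
generates statistically calibrated stand-ins: for each (cell class,
condition) it draws per-cell morphometric targets — axon-terminal count,
mean root-to-tip path length and pre-bifurcation axon length — from
truncated normal distributions whose means are the published cohort means
and whose per-cell spread is SE·sqrt(n_cells) of the small reported cohorts,
then grows a binary axonal arbor meeting those targets exactly.  Axonal
diameters taper distally inside the published per-class range.

Every generated cell is a valid :class:`~retisim.morphology.CellMorphology`
with a spherical soma, a nominal dendritic tuft (identical across
conditions; dendrites were not compared between cohorts), an unbranched
initial axon and a binary branching arbor whose leaves are the axon
terminals, so n_terminals = n_bifurcations + 1 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .morphology import (
    CellMorphology,
    SectionLabel,
    measure,
    validate,
    write_swc,
)

__all__ = [
    "MorphClassParams",
    "CALIBRATION",
    "calibration_table",
    "generate_cell",
    "generate_cohort",
    "cohort_manifest",
    "write_cohort",
]


@dataclass(frozen=True)
class MorphClassParams:
    """Cohort statistics (mean ± SE) for one cell class and condition.

    ``n_cells_reported`` is the size of the cohort behind the published
    mean/SE pairs; per-cell values are drawn with SD = SE·sqrt(n).
    """

    cell_class: str
    condition: str
    n_cells_reported: int
    mean_terminals: float
    se_terminals: float
    mean_bifurcations: float
    se_bifurcations: float
    mean_path_length: float  # μm, mean root-to-tip
    se_path_length: float
    mean_axon_initial_length: float  # μm
    se_axon_initial_length: float
    diameter_range: tuple[float, float]  # μm, axonal
    # nominal, uncalibrated geometry knobs (see docs/methods.md)
    descent_per_cable: float = 0.15  # μm of descent toward the electrode per
    #   μm of arbor cable: longer axons reach deeper, so the longest-axon
    #   cells carry the terminals closest to the electrode
    arbor_radius: float = 28.0  # μm transverse extent the arbor winds within
    soma_diameter: float = 7.0  # μm
    segment_length: float = 5.0  # μm target edge length at generation

    def __post_init__(self) -> None:
        if self.mean_terminals <= 0 or self.mean_path_length <= 0 \
                or self.mean_axon_initial_length <= 0:
            raise ValueError("cohort means must be positive")
        if min(self.se_terminals, self.se_path_length,
               self.se_axon_initial_length) <= 0:
            raise ValueError("standard errors must be positive")
        lo, hi = self.diameter_range
        if not (0 < lo < hi):
            raise ValueError("diameter_range must satisfy 0 < min < max")

    def sd(self, se: float) -> float:
        return se * math.sqrt(self.n_cells_reported)


# Published cohort statistics for the four class/condition groups.  OFF path
# and initial-axon lengths were reported only as "not significantly
# different" between conditions; the values below are nominal stand-ins,
# identical across conditions, and are flagged uncalibrated in the docs.
CALIBRATION: dict[tuple[str, str], MorphClassParams] = {
    ("ON", "healthy"): MorphClassParams(
        "ON", "healthy", n_cells_reported=5,
        mean_terminals=119.0, se_terminals=10.0,
        mean_bifurcations=108.0, se_bifurcations=9.0,
        mean_path_length=247.9, se_path_length=18.5,
        mean_axon_initial_length=14.0, se_axon_initial_length=1.1,
        diameter_range=(0.2, 1.1), descent_per_cable=0.15,
    ),
    ("ON", "degenerate"): MorphClassParams(
        "ON", "degenerate", n_cells_reported=3,
        mean_terminals=68.0, se_terminals=12.0,
        mean_bifurcations=52.0, se_bifurcations=12.0,
        mean_path_length=169.3, se_path_length=18.3,
        mean_axon_initial_length=23.9, se_axon_initial_length=1.2,
        diameter_range=(0.3, 1.6), descent_per_cable=0.15,
    ),
    ("OFF", "healthy"): MorphClassParams(
        "OFF", "healthy", n_cells_reported=3,
        mean_terminals=112.0, se_terminals=13.0,
        mean_bifurcations=100.0, se_bifurcations=12.0,
        mean_path_length=210.0, se_path_length=25.0,  # nominal
        mean_axon_initial_length=17.0, se_axon_initial_length=1.5,  # nominal
        diameter_range=(0.1, 0.8), descent_per_cable=0.10,
    ),
    ("OFF", "degenerate"): MorphClassParams(
        "OFF", "degenerate", n_cells_reported=4,
        mean_terminals=58.0, se_terminals=7.0,
        mean_bifurcations=49.0, se_bifurcations=8.0,
        mean_path_length=210.0, se_path_length=25.0,  # nominal
        mean_axon_initial_length=17.0, se_axon_initial_length=1.5,  # nominal
        diameter_range=(0.3, 1.2), descent_per_cable=0.10,
    ),
}


def calibration_table() -> pd.DataFrame:
    """The four-class calibration table as a tidy DataFrame."""
    rows = []
    for (cls, cond), p in CALIBRATION.items():
        rows.append({
            "cell_class": cls, "condition": cond, "n_cells_reported": p.n_cells_reported,
            "mean_terminals": p.mean_terminals, "se_terminals": p.se_terminals,
            "mean_bifurcations": p.mean_bifurcations, "se_bifurcations": p.se_bifurcations,
            "mean_path_length": p.mean_path_length, "se_path_length": p.se_path_length,
            "mean_axon_initial_length": p.mean_axon_initial_length,
            "se_axon_initial_length": p.se_axon_initial_length,
            "diameter_min": p.diameter_range[0], "diameter_max": p.diameter_range[1],
        })
    return pd.DataFrame(rows)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float = np.inf) -> float:
    """Rejection-sampled truncated normal (deterministic given rng state)."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(mean, lo), hi))  # pragma: no cover


class _Builder:
    """Accumulates nodes of a cell under construction."""

    def __init__(self) -> None:
        self.parent: list[int] = []
        self.labels: list[int] = []
        self.xyz: list[np.ndarray] = []
        self.diam: list[float] = []

    def add(self, parent: int, label: SectionLabel, pos: np.ndarray, d: float) -> int:
        self.parent.append(parent)
        self.labels.append(int(label))
        self.xyz.append(np.asarray(pos, dtype=float))
        self.diam.append(float(d))
        return len(self.parent) - 1

    def finish(self, cell_class: str, condition: str, cell_id: str) -> CellMorphology:
        n = len(self.parent)
        return CellMorphology(
            np.arange(1, n + 1), np.array(self.parent), np.array(self.labels),
            np.vstack(self.xyz), np.array(self.diam),
            cell_class=cell_class, condition=condition, cell_id=cell_id,
        )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_cell(params: MorphClassParams, seed: int,
                  cell_id: str | None = None) -> CellMorphology:
    """Generate one synthetic cell; deterministic given (params, seed).

    The terminal count T is sampled and the arbor is grown as a binary tree,
    so the bifurcation count is T - 1; path and pre-bifurcation lengths are
    met exactly by construction (every root-to-tip geodesic through the
    arbor equals the sampled path target).
    """
    rng = np.random.default_rng(seed)
    # --- per-cell morphometric targets -------------------------------------
    T = int(round(_trunc_normal(rng, params.mean_terminals,
                                params.sd(params.se_terminals), lo=2.0)))
    L0 = _trunc_normal(rng, params.mean_axon_initial_length,
                       params.sd(params.se_axon_initial_length), lo=3.0)
    P = _trunc_normal(rng, params.mean_path_length,
                      params.sd(params.se_path_length), lo=L0 + 20.0)
    if T < 2:
        raise ValueError("infeasible parameters: terminal target below 2")

    dmin, dmax = params.diameter_range
    drange = dmax - dmin
    d_hi = dmin + drange * float(rng.uniform(0.75, 0.95))
    d_lo = dmin + drange * float(rng.uniform(0.05, 0.25))
    seg = params.segment_length

    def axon_diam(s_frac: float) -> float:
        d = d_hi + (d_lo - d_hi) * s_frac + rng.normal(0.0, 0.02 * drange)
        return float(np.clip(d, dmin, dmax))

    b = _Builder()
    soma = b.add(-1, SectionLabel.SOMA, np.zeros(3), params.soma_diameter)

    # --- dendritic tuft (nominal, identical across conditions) -------------
    trunk = b.add(soma, SectionLabel.DENDRITE, np.array([0.0, 0.0, 3.0]), 1.2)
    for _ in range(3):
        theta = rng.uniform(0, 2 * np.pi)
        direction = _unit(np.array([0.6 * np.cos(theta), 0.6 * np.sin(theta), 1.0]))
        node = trunk
        pos = b.xyz[trunk].copy()
        for _ in range(2):
            pos = pos + direction * 2.5
            node = b.add(node, SectionLabel.DENDRITE, pos, 0.8)

    # --- unbranched initial axon -------------------------------------------
    n_seg0 = max(1, int(round(L0 / seg)))
    ell0 = L0 / n_seg0
    node = soma
    pos = np.zeros(3)
    s = 0.0
    for _ in range(n_seg0):
        step = _unit(np.array([rng.normal(0, 0.08), rng.normal(0, 0.08), -1.0])) * ell0
        pos = pos + step
        s += ell0
        node = b.add(node, SectionLabel.AXON, pos, axon_diam(s / P))
    arbor_root = node  # first branch point: splits immediately below

    # --- binary arbor: every tip ends at geodesic P from the axon origin ---
    remaining = P - L0
    drop_rate = params.descent_per_cable  # μm of descent per μm of cable
    r_max = params.arbor_radius

    def step_heading(hd: float, ps: np.ndarray, noise: float) -> float:
        """Meandering heading with a radial leash keeping the arbor compact."""
        hd += rng.normal(0.0, noise)
        r = math.hypot(ps[0], ps[1])
        if r > 0.5 * r_max:
            inward = math.atan2(-ps[1], -ps[0])
            delta = math.remainder(inward - hd, 2.0 * math.pi)
            hd += delta * min(1.0, (r / r_max) ** 2) * 0.5
        return hd

    def walk(par: int, nt_len: float, hd: float, sd: float, terminal: bool):
        """Lay a chain of ``nt_len`` μm of cable; returns (node, heading, s)."""
        k = max(1, int(round(nt_len / seg)))
        ell = nt_len / k
        nd, ps, ss = par, b.xyz[par].copy(), sd
        for j in range(k):
            hd = step_heading(hd, ps, 0.35)
            dz = -min(0.9, drop_rate * (1.0 + rng.normal(0, 0.2))) * ell
            lat = math.sqrt(max(ell**2 - dz**2, 1e-12))
            ps = ps + np.array([lat * math.cos(hd), lat * math.sin(hd), dz])
            ss += ell
            last = terminal and j == k - 1
            lab = SectionLabel.AXON_TERMINAL if last else SectionLabel.AXON
            d = max(d_lo, dmin + 0.1 * drange) if last else axon_diam(ss / P)
            nd = b.add(nd, lab, ps, float(np.clip(d, dmin, dmax)))
        return nd, hd, ss

    def grow(parent: int, n_tips: int, rem: float, heading: float, s_done: float) -> None:
        stack = [(parent, n_tips, rem, heading, s_done)]
        while stack:
            par, nt, rem, hd, sd = stack.pop()
            if nt == 1:
                walk(par, rem, hd, sd, terminal=True)
                continue
            # stalk (at least one segment so every branch point is binary),
            # then split the tips between two children
            f = float(rng.uniform(0.2, 0.45))
            stalk = max(min(f * rem, rem - 2.0 * seg), min(seg, rem / 3.0))
            nd, hd, ss = walk(par, stalk, hd, sd, terminal=False)
            n1 = int(np.clip(rng.binomial(nt, 0.5), 1, nt - 1))
            spread = float(rng.uniform(0.5, 1.2))
            stack.append((nd, n1, rem - stalk, hd + spread, ss))
            stack.append((nd, nt - n1, rem - stalk, hd - spread, ss))

    n1 = int(np.clip(rng.binomial(T, 0.5), 1, T - 1))
    heading = float(rng.uniform(0, 2 * np.pi))
    grow(arbor_root, n1, remaining, heading + 0.8, L0)
    grow(arbor_root, T - n1, remaining, heading - 0.8, L0)

    cid = cell_id or f"{params.cell_class}_{params.condition}_s{seed}"
    cell = b.finish(params.cell_class, params.condition, cid)
    validate(cell, require_all_sections=True)
    return cell


def generate_cohort(params: MorphClassParams, n: int, seed: int) -> list[CellMorphology]:
    """Generate ``n`` independent cells with per-cell seeds derived from ``seed``."""
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n)
    return [
        generate_cell(params, int(s),
                      cell_id=f"{params.cell_class}_{params.condition}_{i:03d}")
        for i, s in enumerate(child_seeds)
    ]


def cohort_manifest(cells: Sequence[CellMorphology],
                    path_definition: str = "mean_root_to_tip") -> pd.DataFrame:
    """Tidy per-cell morphometrics table for a cohort."""
    rows = []
    for c in cells:
        m = measure(c, path_definition)
        rows.append({
            "cell_id": c.cell_id, "cell_class": c.cell_class, "condition": c.condition,
            "n_bifurcations": m.n_bifurcations, "n_terminals": m.n_terminals,
            "path_length": m.path_length, "axon_initial_length": m.axon_initial_length,
            "diameter_min": m.diameter_min, "diameter_max": m.diameter_max,
            "diameter_mean": m.diameter_mean,
        })
    return pd.DataFrame(rows)


def write_cohort(cells: Sequence[CellMorphology], outdir: str | Path) -> Path:
    """Write a cohort as SWC files plus a CSV manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for c in cells:
        write_swc(c, outdir / f"{c.cell_id}.swc")
    manifest = outdir / "manifest.csv"
    cohort_manifest(cells).to_csv(manifest, index=False)
    return manifest
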