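"""Admittance-method volume conductor for the layered retina.

The bulk tissue is voxelized on a regular grid; each voxel takes the
resistivity of the retinal layer containing its center, and neighbouring
voxel centers are connected by resistors (series combination of the two
half-voxel resistances), giving a 6-neighbour resistive network.  The
stimulating disc electrode injects its total current uniformly over the
voxels it covers in the plane z = 0, the outer boundary of the grid is
grounded (the monopolar return), and the resulting sparse symmetric system
is solved for the node potentials.

Because the tissue is purely resistive, the field is solved once per unit
current and scaled by the stimulus waveform (quasi-static assumption);
potentials are reported in mV per μA of injected current when assembled
with a unit drive.

Layer thicknesses and resistivities are not uniquely established for this
tissue; the defaults in :func:`default_layer_stack` are literature-typical
values and are flagged as uncalibrated in the package documentation.  Every
experiment records the table it used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "Layer",
    "LayerStack",
    "Electrode",
    "AMSystem",
    "PotentialGrid",
    "default_layer_stack",
    "homogeneous_stack",
    "assemble_system",
    "solve_field",
    "sample_potentials",
    "boundary_current",
]


@dataclass(frozen=True)
class Layer:
    name: str
    thickness: float  # μm
    resistivity: float  # Ω·cm

    def __post_init__(self) -> None:
        if self.thickness <= 0 or self.resistivity <= 0:
            raise ValueError("layer thickness and resistivity must be positive")


@dataclass(frozen=True)
class LayerStack:
    """Retinal layers stacked along +z.  The first layer (vitreous) lies
    below the electrode plane z = 0; the remaining layers stack upward from
    z = 0.  Outside the stack the nearest layer's resistivity extends."""

    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("stack needs at least one layer")

    def boundaries(self) -> np.ndarray:
        """Layer interface z-positions, starting at -thickness(vitreous)."""
        th = np.array([l.thickness for l in self.layers])
        z = np.concatenate([[-th[0]], np.cumsum(th) - th[0]])
        return z

    def resistivity_at(self, z: np.ndarray) -> np.ndarray:
        """Resistivity (Ω·cm) of the layer containing each z (μm)."""
        z = np.asarray(z, dtype=float)
        bnd = self.boundaries()
        idx = np.clip(np.searchsorted(bnd, z, side="right") - 1, 0, len(self.layers) - 1)
        rho = np.array([l.resistivity for l in self.layers])
        return rho[idx]


def default_layer_stack() -> LayerStack:
    """Uncalibrated default retina: literature-typical thicknesses (μm) and
    resistivities (Ω·cm) for rabbit retina; see docs/methods.md."""
    return LayerStack((
        Layer("vitreous", 200.0, 70.0),
        Layer("GC", 50.0, 570.0),
        Layer("IPL", 40.0, 570.0),
        Layer("INL", 30.0, 870.0),
        Layer("OPL", 20.0, 570.0),
        Layer("ONL", 50.0, 870.0),
        Layer("PR", 50.0, 1130.0),
        Layer("choroid", 100.0, 250.0),
    ))


def homogeneous_stack(resistivity: float, thickness: float = 2000.0) -> LayerStack:
    """Single-medium stack, mostly for solver verification."""
    half = Layer("medium", thickness / 2.0, resistivity)
    return LayerStack((half, Layer("medium+", thickness / 2.0, resistivity)))


@dataclass(frozen=True)
class Electrode:
    """Stimulating disc electrode in the plane z = 0."""

    diameter: float = 200.0  # μm
    center: tuple[float, float] = (0.0, 0.0)  # μm, in-plane
    current: float = 1.0  # μA injected (cathodic pulses scale this negative)
    distance: float = 60.0  # μm, nominal electrode-to-terminal distance

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("electrode diameter must be positive")
        if self.distance <= 0:
            raise ValueError("electrode distance must be positive")


@dataclass
class AMSystem:
    """Assembled admittance network: G phi = b with grounded outer boundary."""

    matrix: sp.csr_matrix  # conductances in S
    rhs: np.ndarray  # injected currents in A
    axes: tuple[np.ndarray, np.ndarray, np.ndarray]  # node-center coords, μm
    shape: tuple[int, int, int]
    current: float  # μA, total injected
    ground_conductance: np.ndarray  # per-node conductance to the grounded shell, S


@dataclass
class PotentialGrid:
    """Solved extracellular potential on voxel centers, in mV for the
    injected current recorded in ``current`` (μA)."""

    axes: tuple[np.ndarray, np.ndarray, np.ndarray]
    phi: np.ndarray  # (nx, ny, nz) mV
    current: float  # μA
    residual: float

    def interpolator(self) -> RegularGridInterpolator:
        return RegularGridInterpolator(self.axes, self.phi, method="linear",
                                       bounds_error=True)


def _axis(extent: float, voxel: float, offset: float = 0.0) -> np.ndarray:
    n = int(round(extent / voxel))
    if n < 3:
        raise ValueError("grid must be at least 3 voxels across")
    return offset + (np.arange(n) + 0.5) * voxel


def assemble_system(stack: LayerStack, electrode: Electrode, voxel: float = 5.0,
                    extent: float | Sequence[float] = 1000.0,
                    z_fraction_below: float = 0.25) -> AMSystem:
    """Build the sparse conductance matrix and source vector.

    ``extent`` is the grid size in μm (scalar cube or (Lx, Ly, Lz));
    ``z_fraction_below`` is the fraction of the z-extent below the electrode
    plane (vitreous side).  x and y are centered on the electrode.
    """
    if np.isscalar(extent):
        extent = (float(extent),) * 3
    lx, ly, lz = (float(v) for v in extent)
    ex, ey = electrode.center
    x = _axis(lx, voxel, ex - lx / 2.0)
    y = _axis(ly, voxel, ey - ly / 2.0)
    z = _axis(lz, voxel, -z_fraction_below * lz)
    nx, ny, nz = len(x), len(y), len(z)
    rho = np.broadcast_to(stack.resistivity_at(z), (nx, ny, nz)).copy()  # Ω·cm

    h_cm = voxel * 1e-4
    # edge conductance between neighbouring voxel centers: the two
    # half-voxel resistances in series, g = 2 h / (rho1 + rho2)  [S]
    def edge_g(r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
        return 2.0 * h_cm / (r1 + r2)

    n = nx * ny * nz
    idx = np.arange(n).reshape(nx, ny, nz)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    def couple(a: np.ndarray, bidx: np.ndarray, g: np.ndarray) -> None:
        a = a.ravel(); bidx = bidx.ravel(); g = g.ravel()
        rows.extend((a, bidx))
        cols.extend((bidx, a))
        vals.extend((-g, -g))
        np.add.at(diag, a, g)
        np.add.at(diag, bidx, g)

    couple(idx[:-1], idx[1:], edge_g(rho[:-1], rho[1:]))
    couple(idx[:, :-1], idx[:, 1:], edge_g(rho[:, :-1], rho[:, 1:]))
    couple(idx[:, :, :-1], idx[:, :, 1:], edge_g(rho[:, :, :-1], rho[:, :, 1:]))

    # grounded shell half a voxel beyond every outer face
    ground = np.zeros(n)
    for face, r in (
        (idx[0], rho[0]), (idx[-1], rho[-1]),
        (idx[:, 0], rho[:, 0]), (idx[:, -1], rho[:, -1]),
        (idx[:, :, 0], rho[:, :, 0]), (idx[:, :, -1], rho[:, :, -1]),
    ):
        g = (h_cm / r).ravel()  # half-voxel path to the shell
        np.add.at(ground, face.ravel(), g)
    diag += ground

    A = sp.coo_matrix(
        (np.concatenate([np.concatenate(vals), diag]),
         (np.concatenate([np.concatenate(rows), np.arange(n)]),
          np.concatenate([np.concatenate(cols), np.arange(n)]))),
        shape=(n, n)).tocsr()

    # electrode source voxels: centers inside the disc, in the voxel plane
    # nearest z = 0; empty discs (point-like electrodes) use the center voxel
    k0 = int(np.argmin(np.abs(z)))
    r2 = (x[:, None] - ex) ** 2 + (y[None, :] - ey) ** 2
    disc = r2 <= (electrode.diameter / 2.0) ** 2
    if not disc.any():
        disc = np.zeros_like(disc)
        disc[np.argmin(np.abs(x - ex)), np.argmin(np.abs(y - ey))] = True
    b = np.zeros(n)
    src = idx[:, :, k0][disc]
    b[src] = electrode.current * 1e-6 / src.size  # μA → A
    return AMSystem(A, b, (x, y, z), (nx, ny, nz), electrode.current, ground)


def solve_field(system: AMSystem, rtol: float = 1e-8,
                maxiter: int = 20000) -> PotentialGrid:
    """Solve the admittance network by preconditioned conjugate gradients."""
    A, b = system.matrix, system.rhs
    if not np.any(b):
        phi = np.zeros(system.shape)
        return PotentialGrid(system.axes, phi, system.current, 0.0)
    d = A.diagonal()
    M = spla.LinearOperator(A.shape, matvec=lambda v: v / d)
    phi, info = spla.cg(A, b, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
    res = float(np.linalg.norm(A @ phi - b) / np.linalg.norm(b))
    if info != 0 or not np.all(np.isfinite(phi)):
        raise RuntimeError(
            f"admittance solver did not converge (info={info}, residual={res:.2e})")
    return PotentialGrid(system.axes, 1e3 * phi.reshape(system.shape),
                         system.current, res)


def sample_potentials(grid: PotentialGrid, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of node potentials (mV) at (m, 3) μm points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return grid.interpolator()(pts)


def boundary_current(system: AMSystem, grid: PotentialGrid) -> float:
    """Total current (μA) leaving through the grounded boundary shell."""
    phi_v = grid.phi.ravel() * 1e-3  # mV → V
    return float(np.sum(system.ground_conductance * phi_v) * 1e6)
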