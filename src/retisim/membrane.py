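"""Membrane biophysics: calcium channel kinetics, submembrane calcium pool,
Nernst reversal, and the multi-compartment cable integrator.

The model is a passive leak over the whole cell plus a single voltage-gated
calcium conductance confined to the axon-terminal compartments: L-type
(gating m²h) for ON cells, T-type (gating m·h) for OFF cells, both with
peak conductance 0.1 mS/cm².  The reversal potential follows the calcium
Nernst equation from a 0.5-μm submembrane shell whose concentration relaxes
to rest with τ = 1.5 ms.  Membrane capacitance 1 μF/cm², axial resistivity
100 Ω·cm, resting potential −53 mV.

Gating conventions
------------------
The published rate equations for these channels circulate with ambiguous
sign typography.  Taken literally ("printed" convention) the activation
midpoints land at ≈ +30 mV (L) and +37.55 mV (T) — voltages a bipolar cell
never reaches, i.e. channels that can never open.  The "shifted" convention
(default) flips the signs inside the voltage arguments so the midpoints sit
at physiological values (≈ −10 mV for L, −37.55 mV for T) while keeping
every rate coefficient; both variants are selectable everywhere and each
simulation records which one it used.

Extracellular stimulation enters through the interpolated extracellular
potential at each compartment center: the cable equation is written in the
membrane potential Vm with the intracellular potential Vi = Vm + Ve, so the
spatial profile of Ve drives axial current.  Integration is backward Euler
on the cable (one sparse tree factorization, reused every step) with
exponential-Euler gate updates, which keeps the gates in [0, 1] for any
time step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .morphology import CellMorphology, SectionLabel

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "MembraneParams",
    "CaChannelParams",
    "CaPoolParams",
    "ChannelState",
    "TraceSet",
    "gating_rates_L",
    "gating_rates_T",
    "channel_current",
    "nernst_eca",
    "update_ca_pool",
    "simulate",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)

CONVENTIONS = ("printed", "shifted")


@dataclass(frozen=True)
class MembraneParams:
    """Passive membrane and cable constants."""

    cm: float = 1.0  # μF/cm²
    ri: float = 100.0  # Ω·cm axial resistivity
    v_rest: float = -53.0  # mV
    g_leak: float = 0.05  # mS/cm² (not published; configurable)
    e_leak: float = -53.0  # mV; equal to v_rest so the cell rests there
    temperature: float = 22.0  # °C


@dataclass(frozen=True)
class CaChannelParams:
    """Voltage-gated calcium conductance at the axon terminals."""

    kind: str = "L"  # "L" (ON cells) or "T" (OFF cells)
    g_max: float = 0.1  # mS/cm²
    convention: str = "shifted"

    def __post_init__(self) -> None:
        if self.kind not in ("L", "T"):
            raise ValueError("channel kind must be 'L' or 'T'")
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")
        if self.convention not in CONVENTIONS:
            raise ValueError(f"unknown gating convention {self.convention!r}")


@dataclass(frozen=True)
class CaPoolParams:
    """Submembrane calcium shell feeding the Nernst reversal."""

    depth: float = 0.5  # μm
    tau: float = 1.5  # ms removal time constant
    ca_o: float = 1.8  # mM extracellular
    ca_i_rest: float = 1.0e-4  # mM (100 nM)


@dataclass
class ChannelState:
    """Gating and calcium state of the axon-terminal compartments."""

    m: np.ndarray
    h: np.ndarray
    ca_i: np.ndarray  # mM
    e_ca: np.ndarray  # mV


# ---------------------------------------------------------------------------
# Gating kinetics
# ---------------------------------------------------------------------------

def _expm1_safe(x: np.ndarray) -> np.ndarray:
    return np.expm1(np.clip(x, -500.0, 500.0))


def gating_rates_L(v, convention: str = "shifted"):
    """L-type rates: (αm [1/ms], βm [1/ms], h∞, τh [ms]).

    printed: αm = 0.427 (V−63) / (1 − e^(−(V−63)/10.5)),
             βm = 0.0406 e^((70−V)/12).
    shifted: αm uses (V+63); βm unchanged.  In both, h∞ = 1/(1+e^(V/66.4))
    and τh = 292 ms (voltage independent).  The removable singularity of αm
    is evaluated by its limit 0.427·10.5.
    """
    v = np.asarray(v, dtype=float)
    if convention == "printed":
        u = v - 63.0
    elif convention == "shifted":
        u = v + 63.0
    else:
        raise ValueError(f"unknown gating convention {convention!r}")
    with np.errstate(over="ignore"):
        denom = -_expm1_safe(-u / 10.5)
        alpha = np.where(np.abs(u) < 1e-9, 0.427 * 10.5,
                         0.427 * u / np.where(denom == 0.0, 1.0, denom))
        beta = 0.0406 * np.exp(np.clip((70.0 - v) / 12.0, -500, 500))
        hinf = 1.0 / (1.0 + np.exp(np.clip(v / 66.4, -500, 500)))
    tau_h = np.full_like(alpha, 292.0)
    return alpha, beta, hinf, tau_h


def gating_rates_T(v, convention: str = "shifted"):
    """T-type steady states and time constants: (m∞, τm [ms], h∞, τh [ms]).

    printed: m∞ = 1/(1+e^(−(V−37.55)/3.07)),
             τm = 1.36 + 21.68/(1+e^((V−39.96)/4.11)),
             h∞ = 1/(1+e^((V−8.97)/8.42)),
             τh = 65.82 + 0.0023 e^((V−80)/4.78).
    shifted: the voltage arguments become (V+37.55), −(V+39.96), (V+8.97)
    and −(V+80) respectively, moving activation/inactivation midpoints to
    negative voltages.
    """
    v = np.asarray(v, dtype=float)
    if convention == "printed":
        am, atm, ah, ath = v - 37.55, v - 39.96, v - 8.97, v - 80.0
    elif convention == "shifted":
        am, atm, ah, ath = v + 37.55, -(v + 39.96), v + 8.97, -(v + 80.0)
    else:
        raise ValueError(f"unknown gating convention {convention!r}")
    with np.errstate(over="ignore"):
        minf = 1.0 / (1.0 + np.exp(np.clip(-am / 3.07, -500, 500)))
        tau_m = 1.36 + 21.68 / (1.0 + np.exp(np.clip(atm / 4.11, -500, 500)))
        hinf = 1.0 / (1.0 + np.exp(np.clip(ah / 8.42, -500, 500)))
        tau_h = 65.82 + 0.0023 * np.exp(np.clip(ath / 4.78, -500, 500))
    return minf, tau_m, hinf, tau_h


def channel_current(m, h, v, e_ca, params: CaChannelParams):
    """Calcium current density in mA/cm² (negative = inward).

    L-type: g·m²·h·(V−E_Ca); T-type: g·m·h·(V−E_Ca); g in mS/cm², V in mV.
    """
    gate = m * m * h if params.kind == "L" else m * h
    return 1e-3 * params.g_max * gate * (np.asarray(v, float) - np.asarray(e_ca, float))


def nernst_eca(ca_i, ca_o: float, temperature: float = 22.0):
    """Calcium Nernst reversal potential in mV: (R T / 2F) ln([Ca]o/[Ca]i)."""
    ca_i = np.asarray(ca_i, dtype=float)
    if np.any(ca_i <= 0) or ca_o <= 0:
        raise ValueError("calcium concentrations must be positive")
    t_k = temperature + 273.15
    return 1e3 * GAS_CONSTANT * t_k / (2.0 * FARADAY) * np.log(ca_o / ca_i)


def update_ca_pool(ca_i, i_ca, dt: float, pool: CaPoolParams):
    """Implicit step of the submembrane calcium shell.

    d[Ca]i/dt = −i_Ca/(2 F depth) − ([Ca]i − rest)/τ, with i_Ca in mA/cm²
    and depth in μm; concentrations in mM, time in ms.  Inward (negative)
    current raises [Ca]i.  The result is floored just above zero.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ca_i = np.asarray(ca_i, dtype=float)
    depth_cm = pool.depth * 1e-4
    influx = -np.asarray(i_ca, dtype=float) / (2.0 * FARADAY * depth_cm)  # mM/ms
    out = (ca_i + dt * (influx + pool.ca_i_rest / pool.tau)) / (1.0 + dt / pool.tau)
    return np.maximum(out, 1e-12)


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

SECTION_NAMES = {
    SectionLabel.SOMA: "soma",
    SectionLabel.DENDRITE: "dendrite",
    SectionLabel.AXON: "axon",
    SectionLabel.AXON_TERMINAL: "axon_terminal",
}


@dataclass
class TraceSet:
    """Simulation output on a shared time base (ms).

    ``v_sections`` holds area-weighted-mean membrane potential per section;
    ``i_ca_total`` the summed axon-terminal calcium current in pA (negative
    = inward); ``v_terminal_mean`` the plain mean over terminal
    compartments.  Full per-compartment potentials are recorded only when
    ``record_full`` was requested (they grow quickly with cell size).
    """

    t: np.ndarray
    v_sections: dict[str, np.ndarray]
    i_ca_total: np.ndarray  # pA
    v_terminal_mean: np.ndarray  # mV
    v_comp: np.ndarray | None = None  # (n_rec, n_comp) if recorded
    i_ca_comp: np.ndarray | None = None  # (n_rec, n_term) pA
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        data = {"t": self.t, "i_ca_total": self.i_ca_total,
                "v_terminal_mean": self.v_terminal_mean}
        for k, v in self.v_sections.items():
            data[f"v_{k}"] = v
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Cable integrator
# ---------------------------------------------------------------------------

def _axial_conductances(cell: CellMorphology, ri: float) -> np.ndarray:
    """Center-to-center axial conductance (mS) of each parent edge."""
    L_cm = cell.lengths() * 1e-4
    r_cm = cell.diameter * 0.5e-4
    # per-compartment half-resistance; soma treated as a cylinder of length d
    half = np.empty(cell.n)
    for i in range(cell.n):
        li = L_cm[i]
        if cell.labels[i] == SectionLabel.SOMA or cell.parent[i] < 0:
            li = cell.diameter[i] * 1e-4
        half[i] = ri * (li / 2.0) / (np.pi * r_cm[i] ** 2)  # Ω
    g = np.zeros(cell.n)
    for i in range(cell.n):
        p = cell.parent[i]
        if p < 0:
            continue
        g[i] = 1e3 / (half[i] + half[p])  # Ω → mS
    return g


def simulate(cell: CellMorphology, mp: MembraneParams, ch: CaChannelParams,
             pool: CaPoolParams, ve_unit: np.ndarray | None,
             waveform: np.ndarray | None, dt: float, t_stop: float,
             record_every: int = 1, record_full: bool = False) -> TraceSet:
    """Integrate the cable equations under extracellular drive.

    Parameters
    ----------
    ve_unit:
        Extracellular potential at each compartment center for a unit
        (1 μA) electrode drive, mV; ``None`` for an unstimulated cell.
    waveform:
        Stimulus current at each time step (μA), sampled at ``dt`` over the
        simulation; the extracellular potential at step k is
        ``waveform[k] * ve_unit``.  ``None`` means no stimulus.
    dt, t_stop:
        Time step and duration in ms.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(t_stop / dt))
    n = cell.n
    if ve_unit is None:
        ve_unit = np.zeros(n)
    ve_unit = np.asarray(ve_unit, dtype=float)
    if ve_unit.shape != (n,):
        raise ValueError("ve_unit must have one value per compartment")
    if waveform is None:
        waveform = np.zeros(n_steps + 1)
    waveform = np.asarray(waveform, dtype=float)
    if len(waveform) < n_steps + 1:
        waveform = np.concatenate([waveform, np.zeros(n_steps + 1 - len(waveform))])

    area = cell.areas() * 1e-8  # μm² → cm²
    c = mp.cm * area  # μF
    gl = mp.g_leak * area  # mS
    g_ax = _axial_conductances(cell, mp.ri)  # mS per parent edge

    parent = cell.parent
    rows, cols, vals = [], [], []
    diag = c / dt + gl
    for i in range(n):
        p = parent[i]
        if p < 0:
            continue
        rows.extend((i, p)); cols.extend((p, i)); vals.extend((-g_ax[i], -g_ax[i]))
        diag[i] += g_ax[i]; diag[p] += g_ax[i]
    lap = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    M = (lap + sp.diags(diag)).tocsc()
    solver = spla.splu(M)
    # axial Laplacian applied to Ve gives the extracellular driving term
    L_ax = lap + sp.diags(diag - (c / dt + gl))

    term = (cell.labels == SectionLabel.AXON_TERMINAL)
    t_idx = np.flatnonzero(term)
    a_term = area[t_idx]
    v = np.full(n, mp.v_rest)
    if ch.kind == "L":
        a0, b0, hinf0, _ = gating_rates_L(mp.v_rest, ch.convention)
        m = np.full(len(t_idx), float(a0 / (a0 + b0)))
        h = np.full(len(t_idx), float(hinf0))
    else:
        minf0, _, hinf0, _ = gating_rates_T(mp.v_rest, ch.convention)
        m = np.full(len(t_idx), float(minf0))
        h = np.full(len(t_idx), float(hinf0))
    cai = np.full(len(t_idx), pool.ca_i_rest)

    sec_masks = {name: cell.labels == lab for lab, name in SECTION_NAMES.items()}
    sec_w = {name: area[mask] / max(area[mask].sum(), 1e-30)
             for name, mask in sec_masks.items()}

    n_rec = n_steps // record_every + 1
    t_out = np.empty(n_rec)
    v_sec = {name: np.empty(n_rec) for name in sec_masks}
    ica_tot = np.empty(n_rec)
    v_term_mean = np.empty(n_rec)
    v_full = np.empty((n_rec, n)) if record_full else None
    ica_full = np.empty((n_rec, len(t_idx))) if record_full else None

    def record(k_rec: int, t_now: float, i_dens: np.ndarray) -> None:
        t_out[k_rec] = t_now
        for name, mask in sec_masks.items():
            v_sec[name][k_rec] = float(np.dot(v[mask], sec_w[name]))
        ica_pA = i_dens * a_term * 1e9  # mA → pA
        ica_tot[k_rec] = float(ica_pA.sum())
        v_term_mean[k_rec] = float(v[t_idx].mean()) if len(t_idx) else np.nan
        if record_full:
            v_full[k_rec] = v
            ica_full[k_rec] = ica_pA

    e_ca = nernst_eca(cai, pool.ca_o, mp.temperature)
    i_dens = channel_current(m, h, v[t_idx], e_ca, ch)
    record(0, 0.0, i_dens)

    k_rec = 1
    for k in range(1, n_steps + 1):
        vt = v[t_idx]
        if ch.kind == "L":
            alpha, beta, hinf, tau_h = gating_rates_L(vt, ch.convention)
            tau_m = 1.0 / (alpha + beta)
            minf = alpha * tau_m
        else:
            minf, tau_m, hinf, tau_h = gating_rates_T(vt, ch.convention)
        m = minf + (m - minf) * np.exp(-dt / tau_m)
        h = hinf + (h - hinf) * np.exp(-dt / tau_h)
        e_ca = nernst_eca(cai, pool.ca_o, mp.temperature)

        i_dens_expl = channel_current(m, h, vt, e_ca, ch)  # mA/cm²
        i_ca_abs = i_dens_expl * a_term * 1e3  # μA

        ve = waveform[k] * ve_unit
        rhs = c / dt * v + gl * mp.e_leak - L_ax @ ve
        rhs[t_idx] -= i_ca_abs
        v = solver.solve(rhs)
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(f"non-finite membrane potential at t={k * dt:.3f} ms")

        i_dens = channel_current(m, h, v[t_idx], e_ca, ch)
        cai = update_ca_pool(cai, i_dens, dt, pool)

        if k % record_every == 0:
            record(k_rec, k * dt, i_dens)
            k_rec += 1

    meta = {"dt": dt, "t_stop": t_stop, "record_every": record_every,
            "convention": ch.convention, "channel_kind": ch.kind,
            "g_max": ch.g_max, "g_leak": mp.g_leak, "cell_id": cell.cell_id,
            "n_compartments": n, "n_terminals": int(len(t_idx))}
    return TraceSet(t_out, v_sec, ica_tot, v_term_mean, v_full, ica_full, meta)
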