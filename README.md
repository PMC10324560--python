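# retisim

Multi-scale simulation of extracellular electrical stimulation of healthy
and early-degenerate cone bipolar cells (CBCs).

In retinal degenerations such as retinitis pigmentosa, photoreceptors die
while the inner retina survives and remodels.  Retinal prostheses inject
current to activate the surviving neurons; an attractive early-stage target
is the bipolar cell, which still relays to ganglion cells.  This package
asks how the remodeled morphology of early-degenerate ON and OFF CBCs
changes their response to epiretinal current pulses, for people modeling
stimulation strategies for retinal implants.

The model chain:

1. **Synthetic morphologies** (`retisim.synth`, `retisim.morphology`).
   Connectome-derived CBC reconstructions are not programmatically
   retrievable, so cohorts are generated as labeled compartment trees
   (soma / dendrite / axon / axon-terminal, SWC I/O with custom terminal
   type code 5) statistically calibrated to published cohort morphometry:
   bifurcation and terminal counts, mean root-to-tip axonal path length,
   pre-bifurcation axon length, and axonal diameter ranges, per cell class
   (ON/OFF) and condition (healthy/degenerate).
2. **Admittance-method volume conductor** (`retisim.field`).  The layered
   retina plus a 200 μm disc electrode is voxelized into a 6-neighbor
   resistive network G·φ = I with grounded outer boundary, solved once per
   unit drive (the tissue is purely resistive, so waveforms scale the
   field), and sampled by trilinear interpolation at compartment centers.
3. **Cable model with terminal calcium channels** (`retisim.membrane`).
   Per compartment, C_m dV/dt + i_ion(V) = axial coupling of
   V_i = V_m + V_e(t), with C_m = 1 μF/cm², R_i = 100 Ω·cm, rest −53 mV,
   linear leak everywhere, and a single voltage-gated Ca conductance
   (0.1 mS/cm²) confined to axon terminals: L-type i = g·m²·h·(V−E_Ca) for
   ON cells, T-type i = g·m·h·(V−E_Ca) for OFF.  E_Ca follows the calcium
   Nernst relation from a 0.5 μm submembrane shell with τ = 1.5 ms removal
   and [Ca]_o = 1.8 mM.  Integration: backward Euler on the tree (one
   sparse factorization), exponential Euler for gates.
4. **Protocols and metrics** (`retisim.protocol`, `retisim.metrics`).
   Cathodic monophasic pulses (−100 μA; 0.5–100 ms for ON, plus 500 ms for
   OFF); rise constants τ_V-Term and τ_I-Term (time to 63.2 % of the peak
   deflection), peak/tail inward calcium current, exponential decay
   constant, and Welch t-tests between cohorts.
5. **Pipeline** (`retisim.pipeline`, CLI `retisim`).  Generate → solve →
   position (soma fixed in the INL, or all terminals repositioned to a
   common electrode distance) → sweep → compare, with full provenance and
   named directional soft checks.

## Worked example

`python examples/03_single_cell_response.py` stimulates one synthetic
healthy ON CBC (soma fixed in the INL) with a cathodic 100 μA, 100 ms pulse
and prints:

```
cell ON_healthy_s1: 1980 compartments, 254 terminal compartments
membrane potential at end of the 100 ms pulse (rest = −53 mV):
  dendrite         -76.33 mV
  soma             -76.10 mV
  axon             -52.73 mV
  axon_terminal    -47.77 mV
terminal V rise constant τ_V-Term : 0.579 ms
peak inward Ca current per terminal: 0.00005 pA at 100.0 ms after onset
```

The polarization pattern is the physics of extracellular cathodic
stimulation: compartments nearest the electrode (the axon terminals, in the
steepest, most negative extracellular field) depolarize by ~5 mV while the
soma and dendrites, deeper in the retina, hyperpolarize by ~23 mV.  The
depolarized terminals open L-type channels and carry a sustained inward
calcium current — the quantity that would gate transmitter release.  Its
absolute size depends strongly on the (unpublished) leak conductance and
layer resistivities, so cohort *comparisons*, not absolute currents, are
the meaningful output; `examples/04_cohort_comparison.py` runs the
healthy-vs-degenerate comparison and prints the Welch table and the
directional soft checks.

`examples/01_synthetic_morphologies.py` verifies generator calibration
(e.g. healthy ON path length 246.9 μm against the 247.9 ± 18.5 target) and
`examples/02_tissue_field.py` shows the solved field (on-axis Ve falling
from 1.16 mV/μA at 20 μm depth to 0.30 mV/μA at 150 μm, injected current
conserved to 1e-6).

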