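# Methods

## Model overview

The package couples three models: a statistically calibrated generator of
cone-bipolar-cell (CBC) morphologies, an admittance-method (AM) volume
conductor of the layered retina with an epiretinal disc electrode, and a
multi-compartment cable model whose only active conductance is a calcium
channel at the axon terminals.  The chain assumes (i) purely resistive
tissue, so the extracellular field is solved once per unit current and
scaled by the stimulus waveform (quasi-static); (ii) one-way coupling — the
cell does not perturb the tissue field; (iii) no Na⁺/K⁺ channels, spiking,
or synaptic transmission: the terminal calcium current is the output
proxy for release drive.

Coordinates are in μm, right-handed, electrode plane at z = 0, +z pointing
into the retina; a compartment is the cylinder along its parent edge (the
soma is a sphere), and compartment centers (edge midpoints) are where the
extracellular potential is sampled.

## Synthetic morphologies

Connectome reconstructions of the modeled cells are not retrievable, so the
generator emulates their cohort statistics.  For each (class, condition)
the calibration table stores mean ± SE of axonal bifurcations, terminals,
mean root-to-tip path length and pre-bifurcation ("initial") axon length,
the axonal diameter range, and the size n of the reported cohort
(ON: 5 healthy / 3 degenerate; OFF: 3 / 4).  Per-cell targets are drawn
from truncated normals with SD = SE·√n — the between-cell spread implied by
the published standard errors — and the arbor is constructed to meet them
exactly:

* terminal count T is sampled (floor 2) and the arbor is grown as a binary
  tree, so bifurcations B = T − 1.  T and B cannot be sampled independently
  in a binary tree; sampling T and letting B follow keeps both within the
  published 2-SE bands (the printed pairs differ from T − 1 by ~1 SE);
* the unbranched initial axon takes sampled length L0; at its end the tree
  splits immediately (so the measured pre-bifurcation length is exactly L0)
  and every stalk/leaf chain is laid out so that each root-to-tip geodesic
  equals the sampled path target P: mean root-to-tip path length is P by
  construction;
* axonal diameters taper linearly from the upper to the lower part of the
  published per-class range with small jitter, clipped to the range;
  terminal pieces sit near the range floor (terminals are the thinnest
  branches);
* geometry the sources do not quantify is nominal and configurable, chosen
  once: the arbor meanders inside a ~28 μm radial leash (compact transverse
  extent of CBC arbors) and descends toward the electrode at
  `descent_per_cable` = 0.15 (ON) / 0.10 (OFF) μm per μm of cable, which
  realizes the described study geometry in which the cells with the longest
  axons carry the terminals closest to the electrode, and stratifies ON
  arbors deeper than OFF;
* the dendritic tuft is a fixed nominal structure, identical across
  conditions (dendritic morphology was not compared between cohorts);
* OFF path-length and initial-axon values were published only as "not
  significantly different" between conditions; the table carries nominal
  stand-ins (210 ± 25 μm, 17.0 ± 1.5 μm, identical across conditions),
  flagged **uncalibrated**.

What passing the calibration tests shows: 100+-cell cohorts reproduce the
published morphometric means within 2 SE and the diameter ranges.  What it
does not show: the generator carries no information about branch-order
statistics, tortuosity profiles, synapse placement or the aberrant sprouting
of remodeling cells — any response property that depends on such detail is
outside what these synthetic cohorts can certify.

## Tissue field

The AM discretizes the tissue on a regular voxel grid; adjacent voxel
centers are joined by the series combination of their half-voxel
resistances, g = 2h/(ρ₁+ρ₂).  The disc electrode injects its total current
uniformly over the voxels it covers in the plane z = 0 (an equipotential-
disc variant is a config stub; the uniform-density model is simpler and the
difference is confined to the near field).  The grid's outer boundary is
grounded through half-voxel resistors — the monopolar return.  The system
is solved by Jacobi-preconditioned conjugate gradients to a 1e-8 relative
residual; current conservation (boundary outflow = injected current) holds
to solver tolerance and is asserted in tests.

Layer thicknesses and resistivities are **uncalibrated defaults** —
literature-typical values (vitreous 200 μm / 70 Ω·cm; GC 50/570; IPL
40/570; INL 30/870; OPL 20/570; ONL 50/870; PR 50/1130; choroid 100/250) —
because the source study cites them to prior work without printing them.
Every experiment records the table used.  Consequently absolute field
magnitudes (and everything downstream: absolute depolarizations and
currents) are not asserted anywhere; only field *shape* (free-space 1/r law
within 5 % after removing the grounded-boundary offset, monotone decay,
linearity) and model-internal cohort comparisons are.

Defaults: voxel 5 μm with a 1 mm cube extent for the library; the pipeline
default is a 10 μm voxel on a 600×600×450 μm box (one third below the
electrode plane), which grid-refinement checks show changes sampled
compartment potentials by under ~8 % while keeping a field solve at ~2 s.

## Membrane model

Constants: C_m = 1 μF/cm², R_i = 100 Ω·cm, rest −53 mV, [Ca]_o = 1.8 mM,
shell depth 0.5 μm, τ_Ca = 1.5 ms, [Ca]_i,rest = 100 nM (standard neuronal
value), T = 22 °C, g_Ca,max = 0.1 mS/cm² on axon-terminal compartments
only (L-type, m²h, for ON; T-type, mh, for OFF).  The leak conductance is
not published; the default is g_leak = 0.05 mS/cm² with E_leak = −53 mV so
the unstimulated cell rests exactly at −53 mV (verified to ±0.1 mV over
500 ms in a full cell).  Absolute rise-time constants depend directly on
this choice and are therefore never compared against published values.
E_Ca for both channel types is the calcium Nernst potential recomputed each
step from the shell concentration (the sources name only the L-type
construction; using the same rule for T-type is the only consistent
choice), giving ≈ +124.6 mV at rest.

### Gating conventions

The rate equations for these channels circulate with garbled sign
typography.  Both parses are implemented and selectable
(`gating_convention`), and every simulation records its choice:

* `printed` — the literal transcription: L-type
  αm = 0.427(V−63)/(1−e^(−(V−63)/10.5)) (the removable singularity at
  V = 63 is evaluated by its limit 0.427·10.5), βm = 0.0406·e^((70−V)/12),
  h∞ = 1/(1+e^(V/66.4)), τh = 292 ms; T-type
  m∞ = 1/(1+e^(−(V−37.55)/3.07)),
  τm = 1.36 + 21.68/(1+e^((V−39.96)/4.11)),
  h∞ = 1/(1+e^((V−8.97)/8.42)), τh = 65.82 + 0.0023·e^((V−80)/4.78).
* `shifted` (default) — sign-flipped voltage arguments: (V+63) in αm,
  (V+37.55), −(V+39.96), (V+8.97), −(V+80) in the T-type expressions.

The default is `shifted` because the literal parse puts the half-activation
voltages at ≈ +30 mV (L) and +37.55 mV (T): channels that can essentially
never open at voltages a bipolar cell reaches, which contradicts the
pA-scale terminal currents these models are meant to produce.  The shifted
parse restores physiological midpoints (≈ −10 mV high-threshold L-type,
−37.55 mV low-threshold T-type) while keeping every printed coefficient.
The printed-equation constants that are convention-independent or specific
to the literal parse (τh = 292 ms; h∞(0) = 0.5; τh,T(80 mV) = 65.8223 ms)
are asserted against `printed` in the tests.

### Integration

Backward Euler on the cable: the constant part of the system matrix
(capacitive + leak + axial tree Laplacian) is LU-factorized once and reused
every step; the calcium current is treated explicitly (it is ≤ 0.1 mS/cm²
against a membrane time constant of 20 ms, so explicit coupling is far from
the stability limit).  Gates advance by exponential Euler — exact for the
per-step linear relaxation, hence m, h ∈ [0, 1] for any dt — and the shell
concentration by an implicit step of
d[Ca]/dt = −i_Ca/(2F·depth) − ([Ca]−rest)/τ, floored just above zero.
Default dt = 0.01 ms; dt-halving changes the terminal voltage trace by
< 1 % (sup-norm over the smooth part of the response; the two samples
landing exactly on the pulse edges see the discontinuity resolved within
one step and are excluded from that comparison).  The integrator is
verified against the matrix-exponential closed form of a passive
two-compartment cell to 0.5 %.

### Numerical conventions and degenerate inputs

Exponential arguments are clipped at ±500 before `exp`; a zero-drive
simulation short-circuits the field solve; repositioning refuses to move a
compartment through the electrode plane; flat traces yield NaN metrics (not
zero); tied current peaks report the earlier time; the decay fit uses a
log-linear least-squares fit down to 10 % of peak (configurable) and
returns NaN for non-decaying segments; Welch's t-test is used for all
cohort comparisons (unequal sizes and variances; the sources do not state
the variant) with degenerate-variance pairs reported as p = NaN.

## Experiment design and reported quantities

The pipeline fixes each soma on the electrode axis at the INL mid-depth
(the configured stack puts this at z = 105 μm), or — in
`terminals_equidistant` mode — translates every cell along z so its nearest
terminal matches the reference distance of the closest-terminal (longest
axon) cell, never farther than the configured 60 μm default.  Sweeps use
cathodic −100 μA monophasic pulses, onset 1 ms, durations 0.5–100 ms (ON)
plus 500 ms (OFF), post-pulse tail max(50 ms, 3×duration) by default.

Reported calcium currents are **per-terminal-compartment averages** (the
summed terminal current divided by the number of terminal compartments;
`current_metric="total"` selects the whole-cell sum).  The per-terminal
average is the analysed quantity because the compared traces are
compartment averages and because the mechanism under study — fewer
surviving terminals concentrating current through each synapse — is a
per-synapse statement; with the ~1.75× larger healthy terminal count the
whole-cell sum measures arbor size more than channel drive.

The pipeline's problem sizes (8 cells per cohort, 10 μm voxel, dt
0.025 ms, one duration per class for the comparison experiment) were chosen
as the smallest sizes at which the cohort comparisons stabilize; all are
config fields.

## Directional soft checks and known limitations

Four qualitative directions from the source study are evaluated on every
pipeline run and logged (names in the report): `cathodic_polarity`
(axon/terminals depolarize, soma/dendrites hyperpolarize), `on_rise_time`
(healthy ON τ_V-Term < degenerate), `on_peak_current` (degenerate ON peak
terminal Ca current > healthy), `off_peak_current` (no significant OFF
difference).  Under the default configuration the first and third
reproduce; two do **not**, and are deliberately left failing in the
acceptance tests:

* `on_rise_time` comes out inverted: the larger healthy arbor (119 vs 68
  terminals, 248 vs 169 μm paths) equilibrates more slowly in a passive
  cable, so healthy terminals reach 63.2 % of their peak later.  The
  published healthy-faster result evidently rests on morphology detail
  (diameter profiles, tortuosity, terminal clustering) that calibrated
  cohort statistics do not carry.
* `off_peak_current`: the published OFF axonal diameter ranges (healthy
  0.1–0.8 μm, degenerate 0.3–1.2 μm) force degenerate terminal compartments
  to ~2–3× the membrane area, hence systematically larger per-terminal
  currents; the real cells evidently did not differ this way.

Further limitations: absolute potentials and currents are uncalibrated (see
above); the L-type current under the default leak is femtoampere-scale
because synthetic ON terminals depolarize only a few mV, so ON cohort
comparisons ride on small numbers; trifurcations are accepted when reading
external SWC cells but never generated; the subretinal electrode geometry
is a configuration note (flip the stack and polarity), not a validated
mode; and no network (amacrine/ganglion) interactions are modeled.
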