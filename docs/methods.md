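# Methods

`fibrosim` simulates electrical propagation in two-dimensional cardiac
tissue at single-myocyte resolution, with the specific aim of
quantifying when a microfibrotic region — a fine-grained mixture of
excitable myocytes and nonconducting material — becomes a substrate for
reentry and hence an ectopic pacemaker.  Two coupled models share one
microstructure: a subcellular finite-volume monodomain solver and its
equivalent one-node-per-myocyte resistor-network reduction.

## The microstructure

Tissue is a uniform grid of 8 μm × 8 μm × 10 μm finite volumes.  Each
interior face carries one of five connection types: cytoplasm
(conductivity σ_c = 0.4 μS/μm), impermeable membrane (σ_m = 0), or one
of three gap-junction flavours with fixed conductances — plicate
(G_p = 0.5 μS) at longitudinal end-to-end abutments, interplicate
(G_i = 0.33 μS) at the stepped contacts near a cell's longitudinal
ends, and combined plicate (G_c = 0.062 μS) along the lateral
side-to-side borders.

The generator of all tissues is a frozen, tileable basic unit of 32
myocytes (60 × 18 volumes, 480 × 144 μm): eight horizontal strips of
widths (2,2,3,2,2,3,2,2) volumes, four cells per strip with fixed
circular boundaries.  The unit is periodic in both directions; cells
crossing the unit's vertical seam are treated on the torus within one
unit and merged across copy seams when tiled (cells of a tiled tissue
are, operationally, the connected components of volumes joined by
cytoplasm faces — which also makes the clipped fragments at the outer
tissue boundary their own small cells).  Frozen statistics:

| quantity           | frozen unit | design target |
|--------------------|------------:|--------------:|
| mean length        |   120.0 μm  | 120.9 ± 27.8  |
| SD length          |    25.4 μm  |               |
| mean width         |    18.0 μm  | 18.3 ± 3.5    |
| SD width           |    3.46 μm  |               |
| mean neighbours    |     6.0     | 6             |

Two geometric choices matter and were genuinely open:

* **Boundary disjointness.** Adjacent strips (cyclically) share no cell
  boundary.  This alone fixes the mean number of gap-junction
  neighbours at exactly 6 in the infinite tiling, independent of the
  stagger offsets: every cell touches 2 longitudinal and on average 4
  lateral neighbours.
* **Small stagger.** The end-to-end offset between vertically adjacent
  cells is 2–4 volumes.  Large (half-cell) offsets create lateral
  contacts whose lumped network links span >100 μm of fiber direction;
  an isopotential-node model then conducts longitudinally through
  these diagonal relays at speeds that exceed the continuum bound of
  the underlying conductivities, and no calibration can reconcile the
  two models.  Small offsets keep the reduction honest.

Gap-junction placement (the conduction-velocity calibration, frozen):
one plicate plaque per end-to-end abutment column; every face of a
long lateral contact carries a junction — interplicate within 2
volumes of a cell end, combined plicate elsewhere; stepped contacts of
≤5 faces carry a single plaque.  The last rule removes the
current-sink load of the short stepped contacts, which otherwise slows
the transverse wavefront by draining its charge into distant cells.
Every touching pair keeps at least one junction, so the adjacency
graph — and with it the neighbour statistics and all percolation
results — is independent of the placement density.

## Membrane kinetics

The physiological membrane model is a hand port of the Bondarenko et
al. mouse left-ventricular (apex) myocyte: 41 differential variables
(V plus 40 states), 15 membrane currents, Markov-chain descriptions of
the fast Na⁺ channel, L-type Ca²⁺ channel, rapid delayed rectifier and
ryanodine receptor, and full subspace/SR calcium handling.  Units are
mV–ms–μM with currents per unit capacitance (pA/pF).  The stored rest
state is the model's own fixed point, obtained by 1000 ms of quiescent
integration; at rest |dV/dt| < 5×10⁻³ mV/ms.  Single-cell behaviour:
threshold of a 2 ms pulse ≈ 10.4 pA/pF, peak ≈ +33 mV, max upstroke
≈ 170 mV/ms (at 0.1 ms sampling), APD50 ≈ 4 ms, APD90 ≈ 22 ms — a
murine action potential.  Markov-chain occupancy is conserved
structurally (one algebraic complement per chain, every transition
booked with both signs); the tests assert positivity/boundedness over
10⁵ explicit-Euler steps and the hand-derived complement flux
identities of the RyR and delayed-rectifier chains.

A two-variable threshold–recovery surrogate (Mitchell–Schaeffer form,
rescaled to mV) stands in wherever the solver plumbing, not the
electrophysiology, is under test.  Its constants are calibrated to
murine phenomenology as produced by the Bondarenko tissue model:
upstroke time constant τ_in = 0.3 ms, recovery τ_open = 30 ms
(murine-scale refractory period), APD-setting τ_out = 4 ms,
τ_close = 15 ms, threshold 0.22 of the 120 mV rest-to-peak range
(≈ −56 mV).  The threshold choice sets the excitation safety factor so
that a fibrotic maze fractionates the wave — with a very low
threshold the surrogate tunnels through any maze and reentry never
forms, which does not emulate the physiological model's behaviour.
The surrogate is a stand-in for speed only: every number quoted for
the tissue models comes from the Bondarenko kinetics.

## Monodomain solvers

Both models follow β C_m ∂V/∂t = ∇·σ∇V − β(I_ion − I_stim) with
no-flux boundaries, advanced by Godunov splitting: N_o explicit-Euler
reaction substeps (Δt_o = 0.1 μs, forced by the stiff Markov chains;
an optional Rush–Larsen update of the Hodgkin–Huxley-type gates is
available but off by default) followed by one implicit-Euler diffusion
step (Δt_p = 10 μs by default; halving it changes strip traces by well
under 1 mV).  The implicit systems are constant in time, symmetric and
weakly diagonally dominant —

* microscopic: (α + Σ_f σ_f)V_i − Σ_f σ_f V_j = αV_i*, α = βC_m h²/Δt_p,
  with σ_f the face coefficient (conductivity, or junction conductance
  divided by depth d);
* discrete: (α_i + Σ_j G_ij)V_i − Σ_j G_ij V_j = α_i V_i*,
  α_i = βC_m A_i d/Δt_p —

and are factorized once (SuperLU) per mesh/network.  Uniform fields
are exact fixed points; with the reaction off, ΣV (mesh) and ΣA_iV_i
(network) are invariant to the 10⁻⁸ level and the update respects the
discrete maximum principle.

The network reduction follows the series/parallel rule: each junction
k between cells i and j contributes R_ijk = dist_ijk/(σ_c h) + 1/G_k,
where dist is the Manhattan volume count from the cell's reference
volume (the volume nearest the centroid, lowest-(x,y) tie-break) to
the junction volume, on both sides; branches add in parallel.  The
Manhattan path is applied literally (index arithmetic, no path
search).  On hand-checkable two-cell meshes the reduction agrees with
these formulas to 10⁻¹², and sits within ~25 % of exact volume-level
nodal analysis — the expected accuracy of the path approximation,
which the tests report rather than hide.

### Calibration

The published conductance table is never touched.  Free were the
surface-to-volume ratio β (unprinted; C_m = 1 μF/cm²) and the junction
placement density.  With the frozen placement above and
**β = 0.17 μm⁻¹**, the discrete model conducts plane waves at
**LP = 405 μm/ms** along the fibers and **TP = 133 μm/ms** across them
(anisotropy ratio 0.327), against targets of 410/130/0.32.  An initial
value β = 0.14 was tried first and discarded: at that capacitive load
no admissible placement brings both velocities to target.

Stimulus protocols deliver 2 ms pulses at twice the tissue-level
diastolic threshold, found by bisection on the coupled strip
(Bondarenko ≈ 155 pA/pF → default 310; surrogate ≈ 177 → default 355).
Twice the single-cell threshold — the naive choice — cannot launch a
wave from a thin edge band against the gap-junction load in either
model.  Cross-fiber plane waves in the microscopic mesh additionally
need a one-cell-deep (16-volume) stimulus band: a 2-volume band holds
too little charge at physiological current densities.

### Known limitations of the reduction

The two models agree closely where the wavefront is narrow relative to
a cell: mid-strip AP traces superimpose in morphology, and with the
(pre-fix) calibration both models conducted longitudinally within 1 %.
At the final calibration the volume-resolved model conducts
longitudinally ~10–30 % faster than the network (measured 452 vs
405 μm/ms on a 6-unit strip; short strips overestimate the difference
because the subthreshold foot, with a space constant of several
hundred μm, contaminates the launch region) and transversally ~30 %
slower (88 vs 133 μm/ms).  Both gaps have one root: an isopotential
node charges its whole membrane before relaying, where the distributed
cell supports an intracellular gradient.  The microscopic longitudinal
speed depends only on σ along the fiber and β, so no lateral placement
can close the gap without moving the discrete velocities off target.
The acceptance suite asserts the 5 % cross-model agreement and the
5 mV trace superposition as specified and reports these failures
rather than recalibrating around them; the discrete-model velocities,
which the downstream fibrosis analyses use, are the calibrated
quantities.

## Fibrosis, reentry and percolation analyses

A fibrosis realization at fraction φ draws round(φN) cells (round half
away from zero) uniformly without replacement with a seeded generator
and removes every gap junction of the chosen cells — on the mesh the
junction faces become membrane, on the network the incident links are
deleted (nodes are kept and remain locally excitable, so a stimulus
electrode still fires them; they simply cannot propagate).  The two
operators commute with the reduction and use identical draws.

Reentry is declared when any unit is above the activity threshold
(V_act = −60 mV, configurable) at a check time equal to the traversal
time of the slowest coherent plane wave plus 60 ms; for the 1 cm
tissue this reproduces the canonical 120 ms (LP) and 300 ms (TP)
checks, and it scales with tissue size.  Activity classes per unit use
AP counting with hysteresis (count at −30 mV, re-arm at −60 mV): NA
(no AP), A (one AP), and for multiple APs S or NS according to whether
the tissue is still active at the end of the run; NS runs report the
time activity died out.  Conduction velocity of possibly tortuous
waves is measured as the distance between the 20 % and 80 % transverse
planes divided by the difference of median first-activation times.

One caveat of the activity-at-check detector at aggressively scaled
tissue sizes: the margin (60 ms) was designed for the centimetre
tissue, where the spread of maze traversal times is small against it.
On a 0.4 cm tissue near the percolation threshold the slowest seeded
mazes can still be conducting their first passage at the check time,
so a flagged run is not guaranteed to contain re-excitation; the
scaled acceptance test therefore additionally requires a cell with at
least two APs among the intermediate-fraction runs.  The
implication-style invariant (flagged ⇒ some cell fired twice) is
asserted on the ring-circuit construction, where it is unambiguous.

Percolation analysis works on the cell network: side-to-side
connectivity through retained links (union-find), C(φ) over seeded
ensembles, and the threshold φ_c from the 50 % crossing of a straight
line fitted to the transition points C ∈ [0.1, 0.9] (a logistic fit is
available).  On the 1 cm × 1 cm network (≈4.7×10⁴ cells) with 100
realizations per φ ∈ {0.40, …, 0.60}, φ_c(LP) ≈ 0.528 and
φ_c(TP) ≈ 0.473 — removing fewer cells suffices to block cross-fiber
propagation, because a transverse interface crosses ~600 cell rows
against ~80 cell columns for the fiber direction.

## Problem sizes used by the tests

The packaged test suite runs the discrete CV calibration checks on
8×1-unit (LP) and 1×21-unit (TP) strips, the cross-model checks on
4×1- and 2×1-unit strips, percolation at full 1 cm scale with 100
seeds per φ, and the reentry-probability shape on a 0.4 × 0.4 cm
tissue with 20 seeded lesions per φ ∈ {0.30, 0.45, 0.60} using the
surrogate membrane (P = 0, > 0, = 0 respectively).  The corresponding
full-fidelity experiment — 100 Bondarenko lesions per φ from 0.40 to
0.55 in 1 % steps on the 1 cm tissue, where the reentry probability
peaks near φ ≈ 0.48 and vanishes shortly above 0.5 — is what
`fibrosim ensemble --phi 0.40:0.55:0.01 --n 100 --cm 1.0 1.0` runs; it
is a cluster-scale computation.

## Numerical and degenerate-input choices

Solver tolerances: SuperLU direct factorization (no iteration error
beyond round-off); non-finite voltages abort a run with the offending
time; reaction steps name the first non-finite state variable.
Stimulus regions must be nonempty and durations positive.  φ is
validated to [0,1]; φ = 0 leaves the model untouched and φ = 1
isolates every cell.  Ensemble runs that fail are recorded and skipped
by summaries.  Runs can stop early once the tissue has been quiescent
for 20 ms after the last stimulus — a quiescent subthreshold tissue
can only relax to rest — and reentry queries after an early stop
return False.  Seeded ensembles are bit-reproducible; per-run seeds
derive from (base seed, φ index, repetition) through a SeedSequence
and stay below 2³¹.
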