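# Methods

`fibrovw` simulates how the spatial organization of fibrosis inside a healed
myocardial infarct shapes arrhythmia vulnerability in two-dimensional human
ventricular tissue. This note records the model, the numerical choices, the
defaults and their rationale, and what the shipped reduced-scale runs do and
do not demonstrate.

## Electrophysiological model

Each excitable node carries the ten Tusscher–Panfilov 2006 (TP06) human
ventricular myocyte model: 12 gating variables, intracellular Ca²⁺ handling
(cytosol, SR and dyadic subspace with instantaneous buffering in derivative
form), Na⁺/K⁺ balances, and the standard current set (I_Na, I_CaL, I_Kr, I_Ks,
I_to, I_K1, I_NaCa, I_NaK, I_pCa, I_pK, background Na/Ca). The exact constants
table is in `src/fibrovw/_tp06_core.py`; the endo/M/epi variants differ in
g_to, g_Ks and the kinetics of the slow inactivation gate *s*.

**Infarct remodeling.** Infarcted (border-zone surviving) myocytes down-scale
the four remodeled peak currents multiplicatively on the maximal conductances:
g_Na to 38%, g_CaL to 31%, g_Kr to 30% and g_Ks to 20% of the reference
values. Peak-current scaling is realized as maximal-conductance scaling, the
standard implementation; no other parameter (pumps, exchangers, Ca handling,
ion-concentration dynamics) is altered. At a cycle length of 1000 ms this
yields a weaker upstroke (peak ≈ +21 mV vs ≈ +43 mV) and a slightly different
APD90 for the M cell, and markedly slower tissue conduction (below).

**Integration.** Rush–Larsen exponential updates for the voltage-gated
Hodgkin–Huxley gates against tabulated steady states and rate exponentials;
forward Euler for the Ca-dependent f_Cass gate, the RyR adaptation variable
and all concentrations; forward Euler for the membrane potential. Stable and
accurate at Δt = 0.02 ms (halving Δt changes planar CV by < 2%, asserted in
tests). Voltage-dependent quantities are tabulated on a 0.05 mV grid over
[−100, 100] mV with linear interpolation; the inward-rectifier curve is
tabulated against V − E_K. Tables bake Δt into the gate exponentials and are
rebuilt per Δt.

An independent cross-check lives in `tests/oracle_tp06.py`: a literal scalar
transcription of the model equations integrated with SciPy's implicit BDF
solver. The production kernel agrees with it to < 0.001 mV at rest and
< 0.3 ms in APD90 (asserted at 1 mV / 5 ms tolerances).

**Pre-pacing.** Tissue runs start every node from the single-cell state
reached after 100 paced beats at a cycle length of 1000 ms (per cell subtype
and remodeling status), the protocol's steady-state initialization.

## Tissue model

The monodomain equation ∂V/∂t = D∇²V − I_ion is solved on a uniform 2D grid
by forward Euler with a 5-point Laplacian. TP06 currents are per-capacitance
(pA/pF ≡ mV/ms at C_m = 1 µF/cm²), so I_ion enters without further scaling;
stimuli use the same convention (−150 pA/pF for 3 ms in tissue, −52 pA/pF for
1 ms in single cells).

- **Diffusion coefficient.** D = 0.154 mm²/ms everywhere by default. (A
  second value, 0.54, circulates for this model family; it is available via
  `SolverConfig.D` but 0.154 is the value tied to the tissue studies and gives
  a planar CV of ≈ 0.70 mm/ms in normal tissue at dx = 0.25 mm.)
- **Grids.** dx = 0.25 mm for the square (ideal) tissue, dx = 0.35 mm for the
  ring and slice-like tissues. Full-scale domains are 1000² nodes (250 mm) and
  600² nodes (210 mm). The stability ratio D·Δt/Δx² (0.0493 and 0.0251) is a
  hard precondition checked against the bound 1/(2d) = 0.25.
- **Boundaries and obstacles.** No-flux (Neumann) closure at domain edges and
  at every face shared with a fibrotic or void node, implemented by
  self-substitution in the neighbour stencil (mirroring). This makes the
  diffusion operator exactly conservative over excitable nodes (asserted to
  1e-9 relative) and keeps the field inside its initial bounds in
  diffusion-only runs.
- **Fibrosis.** Zero-sided coupling: a fibrotic node is an unexcitable 1×1
  obstacle carrying no membrane state and exchanging no current. Fibroblast
  membrane models and one/two-sided myocyte–fibroblast coupling are out of
  scope.

## Geometries and the synthetic-data stage

All tissues are generated programmatically and deterministically per seed
(exact-count sampling without replacement, so a "p%" region has exactly
round(p/100·N) fibrotic nodes and seed variance reflects placement only).

- **Square tissue:** central circular infarct rasterized by center-in test;
  five concentric equal-width circles (radii 70…350 nodes at full scale)
  partition it into annuli with area ratios 1:3:5:7:9. Gradient fibrosis
  assigns 35/30/25/20/15% inside→outside, whose area-weighted mean is 21%;
  `match_gradient_to_mean` rescales the profile (ratios preserved) to match
  any random-distribution level.
- **Ring tissue:** annular wall with an arc-shaped infarct parameterized by
  length (arc/circumference), width and distance-from-inner-wall. The wall
  dimensions are not part of the published design, so they are package
  assumptions exposed on `RingSpec`: outer radius 0.45 × domain side, inner
  radius half the outer. The width/distance fractions are taken relative to
  the *wall thickness*, so width 100% is transmural — this makes the width
  sweep's 25–100% range geometrically meaningful.
- **Synthetic scar:** a seeded emulator of a short-axis ventricular slice — an
  annular wall holding one connected irregular scar (thresholded smoothed
  random field seeded by a radial bump), split into 4 onion layers by distance
  from the scar centroid for the 35/25/15/5% gradient profile. It reproduces
  the *structure* of a patient slice (single connected scar of plausible size
  inside a closed wall), not patient anatomy: no trabeculation, no papillary
  muscles, no measured scar outline. Results on it therefore test the
  pipeline, not patient-specific claims.
- **Transmural subtypes:** wall nodes are binned by normalized depth
  (distance-to-cavity / wall thickness via Euclidean distance transforms,
  which generalizes beyond ideal rings) into endo/M/epi bands of 25/35/40%.
  The shipped studies use M cells only, matching the single-cell-type
  experiments.

## Protocols and measurements

- **S1–S2 scan.** S1 (and S2, same site and amplitude) are −150 pA/pF, 3 ms;
  the square stimulus is a 3-node-wide full-height left-edge band, the ring
  stimulus a 10×10-node block on the endocardial surface (12.25 mm²), placed
  by default opposite the infarct's angular center (the angular placement is
  unpublished; it is a config default). Coupling intervals are scanned from
  480 ms upward (step 1 or 5 ms at full scale).
- **Reentry criterion.** Excitation sustained more than 800 ms after S2 onset,
  operationalized on the active-fraction trace (fraction of excitable nodes
  above −40 mV, sampled every 1 ms): reentry iff activity is nonzero at
  S2 + 800 ms, with an optional trailing persistence window that can only
  demote a verdict. Both thresholds (0 mV for activation maps, −40 mV for
  activity) are conventional choices exposed in `SolverConfig`. Because no
  stimulus follows S2, a trial may stop as soon as the active fraction reaches
  zero — this early exit is exact, not an approximation — and the S1 prefix is
  shared across intervals by checkpointing.
- **VW bookkeeping.** Width = max − min reentrant interval, 0 when none; the
  smallest conducting interval is reported alongside (the "lower bound of
  conduction" convention used with 0-ms windows). Seed aggregation reports the
  sample mean and n−1 SD.
- **Conduction velocity.** Planar wavefront between two probe lines on a
  strip; probe separation does not change the estimate (±2% asserted), and an
  unactivated probe reports a block rather than raising.

## Desk-scale realization and its limits

The `scale` factor shrinks grid sizes and radii while keeping dx, Δt and all
membrane parameters fixed: conduction velocity, APD and wavelength are
unchanged, path lengths shrink. The shipped desk-scale defaults — ring grid
120 (42 mm), square grid 100 (25 mm), scan step 40 ms over 480–520 ms, 100
pre-pacing beats — were sized so a full scan finishes in about a minute on one
CPU; they are the configuration used by the tests and by
`scripts/acceptance.py`.

What survives scaling, and is verified at desk scale: conduction slowing by
remodeling and by fibrosis (CV 0.70 → 0.50 → 0.33 mm/ms for normal → infarct
→ infarct + 20% fibrosis), activation delay by fibrotic obstacles, exact
fibrosis accounting, thin-infarct (width 35%) immunity to reentry, and all
solver/cell-model invariants.

What does not: the vulnerable-window *location and width* themselves. Direct
probes at ring grids up to 300 nodes (105 mm) show the S2 outcome flips from
local capture failure to full conduction within ~5 ms of coupling interval,
with every conducted wave quiescing ≈ 500 ms after S2 — the unidirectional
block that seeds reentry requires the conduction-delay accumulation of the
full 210–250 mm domains, where the infarct's latest-activating regions recover
hundreds of ms after the stimulus site. Reduced-scale VW widths are therefore
legitimately 0 across all conditions, the directional VW inequalities
degenerate to 0 ≥ 0 ties, and the full-domain window (520–560 ms for the
25/60/10% surrogate with 20% fibrosis) is only reachable through the
full-scale configurations (`--scale 1 --step 5` on the analysis scripts;
roughly 16 min per coupling interval on one CPU, hours per scan). The
corresponding acceptance test states the full-scale expectation and is
expected to fail at desk scale.

## Known limitations

- 2D only; the 3D ventricular reconstruction stage is out of scope.
- Isotropic diffusion; no fiber architecture or anisotropy.
- Zero-sided fibroblast coupling only.
- Single-cell-type tissue by default (M cells); the transmural-subtype map is
  available but the three-cell-type slice study is not shipped as a default.
- The ring wall thickness and stimulus angle are assumptions (exposed in
  config), as the published geometry does not fix them.
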