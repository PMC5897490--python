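# Methods

This note documents the models, parameter choices, calibrations and known
limitations behind `anophys`.

## Buffered free-Ca²⁺ equilibrium

Pipette solutions set free Ca²⁺ with chelators whose apparent affinity is
strongly pH dependent.  The solver treats, per ligand L (EGTA, HEDTA),
the stepwise proton associations H_iL and the 1:1 complexes CaL and MgL.
With pH fixed (HEPES-buffered; recipes state it), the unknowns are the
free metal and free fully deprotonated ligand concentrations, solved by
damped fixed-point iteration (damping 0.7 in log space, ≤200 iterations,
mass-balance tolerance 10⁻¹² M) with a MINPACK-hybr Newton fallback on
log concentrations for the stiff regime near ligand saturation.
`total_for_free` inverts the solver by bracketing root search.

Corrections, all on by default and individually switchable
(`BufferOptions`):

* **Davies activity correction** moves each stepwise constant from its
  reference ionic strength (0.1 M) to the recipe's, using
  log γ = −A z² (√I/(1+√I) − 0.3 I), A = 0.51.
* **pH scale**: the recipe pH is treated as a proton *activity* and
  converted to concentration with the Davies γ_H.
* **van't Hoff** temperature correction with tabulated reaction
  enthalpies (small at 22 °C vs the 25 °C references).
* **Ionic strength estimate**: 1:1 salts contribute their concentration;
  a chelator is counted as its dominant near-neutral species HL^(1−n)
  with monovalent counterions; buffered metal chloride contributes the
  ML complex plus chloride.  The standard intracellular recipe evaluates
  to ≈0.165 M.

The bundled constants (`src/anophys/data/binding_constants.csv`) follow
the critically evaluated stability-constant compilations.  Published
values for Ca·HEDTA span log K ≈ 8.0–8.2 (25 °C, I = 0.1) depending on
source and correction convention; within that range we adopt **8.04**,
the value at which the solver reproduces the reference pipette recipe
(3.2 mM total CaCl₂ → 3 µM free Ca²⁺ in 10 mM HEDTA at pH 7.2) to well
under 1%.  This anchoring stands in for the unknowable constant set and
correction options of the original chelator program; all other constants
are standard.  Only Ca, Mg, H with EGTA and HEDTA are supported —
general metal panels are out of scope.

## Generative model for whole-cell currents

Per sweep the simulated current is

I(t) = g_leak·V + noise + capacitative transient
     + G · φ_GHK(V) · p(t),

with

* **φ_GHK**: the Goldman–Hodgkin–Katz constant-field current summed over
  an ion panel (default: Na⁺/Cs⁺/K⁺/Cl⁻ at the standard recipe
  concentrations), RT/F = 25.43 mV (22 °C).  This produces the outward
  rectification and the reversal-potential behaviour of a large, poorly
  selective pore.
* **p(t)**: open probability relaxing single-exponentially (τ = 60 ms,
  voltage-independent by default — measured relaxations show only weak
  voltage dependence at this scale and no kinetic scheme is established)
  toward a Boltzmann p∞ centred on `true_threshold(Ca) + δ` with slope
  k = 14 mV.
* **true_threshold(Ca)** = (V_max − ΔV) + ΔV / (1 + (Ca/EC₅₀)^h): the
  Hill-type Ca²⁺ dependence of the *measurable* activation threshold,
  with EC₅₀ = 2.9 µM and h = 1.5 for wild type.
* noise: white Gaussian, SD 10 pA; capacitative transients: 500 pA per
  100 mV step, τ = 0.5 ms; leak: 0.5 nS (1 nS for non-transfected
  controls).  Controls are leak + noise only, except at ≥50 µM Ca²⁺
  where a small endogenous outward component appears at the topmost
  steps only.

This is a phenomenological gating model chosen to exercise the analysis
operators, not a mechanistic claim about the channel.

### Detection offset δ and its calibration

The gating midpoint sits far above the detectable threshold (currents do
not saturate inside +180 mV), so the model separates the threshold curve
from the midpoint by a construct-specific offset δ:
V_mid(Ca) = true_threshold(Ca) + δ.  `calibrate_detection_offset` finds
δ by common-random-number Monte-Carlo bisection such that the population
mean of the *detected* threshold (difference current > 2 × noise SD)
equals the anchor mean.  Because the GHK flux grows with voltage, the
detected threshold tracks only ~0.9 of a midpoint shift; the Boltzmann
slope default of 14 mV keeps this compression small enough that a single
scalar δ anchors a construct's reported threshold means to within a few
mV across its Ca²⁺ range.  Constructs with two anchor conditions
(the CHO-series plateaus at 0/240 µM; the mutant at 0/3 µM) combine the
per-condition offsets by inverse-SEM² weighting.

### Populations

A cohort draws per cell a Normal midpoint offset (SD = reported
SEM × √n for the corresponding group) and a log-normal conductance
factor (unit mean, CV 0.3).  Cell *i* uses seed `base_seed + i`; all
randomness flows through seeded NumPy generators, so populations are
bit-reproducible.

Named parameter sets (`src/anophys/data/param_sets.json`) anchor the
threshold curves to measured population means: WT-HEK (88.1 mV at 3 µM,
125.2 at zero Ca), WT-CHO (127 → 62 mV plateaus, EC₅₀ 2.9 µM, h 1.5),
WT-CHO-anchored (75.0 mV at 3 µM — the CHO 3-µM group mean sits below
the fitted Hill curve, so it gets its own anchored set), WT-913 (118.3
mV, reduced conductance), T498I (82.3 mV at zero Ca, 59.6 at 3 µM,
saturating ≈43 mV — constitutively active), a TMEM16B-like
anion-selective set, and a leak-only control.  Conductance scales target
~2 nA peak current (0.6 nA for the weakly expressed WT-913).
`scripts/calibrate.py` regenerates all calibrated entries.

### Permeation specs and the amplitude-calibrated anion ratio

The default `nonselective` spec uses equal cation and anion
permeabilities, which reproduces the defining selectivity observation:
the tail-current reversal potential moves < 5 mV when bath NaCl drops
from 140 to 10 mM (sucrose-substituted), while an anion-only spec shifts
by the Nernst prediction.  A second spec, `nonselective_calibrated`,
carries the anion:cation ratio (≈0.47) that reproduces the measured
+140 mV prepulse-current ratio of 0.69 between the two baths.  A single
GHK ratio cannot satisfy both observations at once (0.47 would predict a
≈ −15 mV reversal shift); the pair of specs makes the tension explicit
instead of hiding it, and the selectivity behaviour was given priority
in the default.

## Current analysis

* **Amplitude windows**: instantaneous = mean 5–10 ms after step onset;
  steady = mean 275–300 ms (threshold statistic) or 280–300 ms (I–V
  amplitudes); both configurable.  Noise SD is computed per sweep on
  linearly detrended steady-window samples (a per-sweep choice; pooling
  across sweeps would also be defensible).
* **Threshold rule**: first step, in ascending voltage order, whose
  positive difference current exceeds multiplier × noise SD (default 2).
  Only outward differences count (activation is outward).  If the first
  tested voltage already qualifies the result is flagged left-censored.
  Cells with no qualifying step return an explicit "none detected" and
  are dropped from group means (range censoring).
* **Relaxation fits**: lmfit single exponentials, first 5 ms after each
  transition blanked; fits whose amplitude is within the residual noise
  or whose τ sits at its bounds are flagged, not raised.
* **Reversal potentials**: each post-prepulse tail is fitted with a
  decaying exponential and extrapolated to the step onset (channels
  still open); V_rev is the zero crossing of a linear fit within ±40 mV
  of the crossing, re-centred once.  The ±40 mV window matches
  experimental practice; on noiseless GHK simulations a narrower window
  (15 mV) removes the curvature bias of the wide window and recovers the
  analytic zero-current potential to < 0.5 mV.  Leak is not subtracted;
  selectivity tests therefore use leak-free simulations.
* **Hill fits**: lmfit on the modified Hill equation with exact
  zero-concentration handling (y → max), plateaus seeded from the data
  extremes, EC₅₀ from a log-interpolated midpoint, h ∈ (0.1, 10).  The
  concentration-series pipeline fits group means weighted by their
  inverse SEMs.

## Scrambling assay

Transfected cells: F(t) = background + drift·t +
plateau·(1 − e^{−(t−L)/τ_rise}) for t > L, with lag L from a truncated
Normal (SD 2.21 min = 0.7 × √10; location calibrated so the population
mean lag is 5.2 min; support 1–22 min), τ_rise = 6 min, plateau 1000
a.u. (CV 0.25), noise 10 a.u., drift 0.1 a.u./min, 1-min sampling over
25 min.  Controls omit the rise.  ΔF_norm subtracts each cell's first
sample and divides by the transfected cohort's mean maximal change
(cohort mean of maxima = 1 by construction).

Onset detection: first interpolated crossing of baseline mean +
3 × baseline SD (first 5 samples; SD floored at 0.01 normalised units so
a quiet baseline cannot produce a vanishing criterion), sustained for 2
samples, minus a calibrated detection delay (≈0.7 min) that removes the
bias introduced by the finite rise time and by lags that begin inside
the baseline window.  With that correction the mean detected latency is
unbiased on the default cohort; on noiseless traces the estimator is
accurate to within one sampling interval.

## Statistics

Mean ± SEM with n = cells; Shapiro–Wilk normality reported (n ≥ 3,
non-degenerate) but never used to auto-switch tests; two-sided paired
*t* and Mann–Whitney *U* (exact null for tie-free groups of ≤8,
otherwise normal approximation with tie correction); no
multiple-testing correction.  Zero-variance paired differences return an
explicit undefined flag.

## Reproducibility, problem sizes, and limitations

The test suite and `scripts/acceptance.py` simulate populations at the
study's per-group cell counts (e.g. 31 WT cells at 3 µM; 7,5,10,7,7,7
for the concentration series; 10 scrambling cells), with 10–20 seeded
replicates where a stochastic quantity is aggregated; everything runs in
seconds on one CPU at the default 5 kHz sampling.

What passing tests show — and what they do not: the generator reproduces
the *statistical structure* the analysis consumes (threshold means and
spreads, relaxation kinetics, reversal potentials, onset latencies), not
raw-data realism.  It omits series-resistance and space-clamp artifacts,
seal drift, rundown, capacitance compensation errors, pipette-to-cell
diffusion delays and cell-to-cell kinetic variability; real recordings
would stress the analysis in ways these simulations cannot.

Known quantitative limitations:

* The median Hill coefficient of the concentration-series pipeline has a
  sampling SD ≈ 0.2 across 20-replicate runs at those group sizes
  (the n = 5 group at 1 µM dominates the fitted steepness), so single
  runs can land 15–30% from the generative h = 1.5; the half-maximal
  concentration is much more stable.
* The single scalar detection offset leaves residual plateau errors of
  ±3–5 mV at the ends of the CHO series (detection compression).
* The buffer solution's 3-µM recipe total is reproduced to ~0.3% by
  construction of the adopted Ca·HEDTA constant; with other published
  constant sets the answer moves by up to ~15%, which is the real
  uncertainty of such calculations.
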