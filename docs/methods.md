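# Methods

## The kinetic model

The pore is a continuous-time Markov chain over blocked/open states. With one
intracellular blocker the states are `O` (open, conducting) and `B` (blocked);
with two blockers, `O`, `M` (Mg²⁺-bound), `S` (SPM-bound) and `MS` (both
bound, either binding order). Transitions and their rates (V in mV, thermal
voltage `vt`, blocker concentration [B] in molar):

* **Blocking** (entry from the cytoplasm over an entry barrier at electrical
  distance δ_on): `k_on(V) = kon0·[B]·exp(Z·δ_on·V/vt)`.
* **Unblocking** (return to the cytoplasm):
  `k_off(V) = koff0·exp(−Zδ_off·V/vt) · exp(−θ·S((V−E_K)/vs))` with
  `S(x) = max(tanh(x), 0)`.
* **Punch-through** (outward escape of the blocker through the selectivity
  filter): `k_exit(V) = kexit0·exp(zδ_exit·V/vt)`; `kexit0 = 0` for Mg²⁺,
  which cannot traverse the filter.

Occupancies evolve by the master equation `dp/dt = p·Q`; the package solves
it by eigendecomposition of the generator (matrix-exponential fallback for
near-defective cases), so simulated relaxations are exact up to numerical
round-off, not integrator output. Steady states solve `pᵀQ = 0` with the
normalization row appended. The apparent dissociation constant has the closed
form `Kd(V) = (k_off + k_exit)/(kon0·exp(Z·δ_on·V/vt))` (the concentration
halving the steady-state open probability).

### Assumptions

* Channels are identical, independent, and always available (no intrinsic
  gating): macroscopic current is `N·P_O(t)·i_open(V)`.
* Open-channel current follows the Goldman–Hodgkin–Katz constant-field form
  with a lumped permeability scale (pA/mM); it exists only to give sweeps a
  realistic inward/outward asymmetry and reversal at E_K.
* `vt` is fixed at 25 mV exactly — the convention in which all rate-voltage
  parameters here are expressed — rather than RT/F ≈ 25.7 mV at room
  temperature.
* One blocking site per blocker; blocker association is one-to-one, hence the
  Hill slope is fixed at 1 throughout the pipeline (a free-slope Hill fit is
  available as an off-pipeline option of `fit_hill` but never used by it).
* In `MS`, each blocker unbinds to the inside at its single-bound rate, but
  SPM punch-through is occluded (`ms_blocks_exit=True`): with Mg²⁺ resident
  behind it, SPM cannot exit outward. This minimal occlusion is the only
  blocker–blocker interaction in the scheme; setting `ms_blocks_exit=False`
  yields exactly independent sites and serves as the no-interaction null.
  Whether the occlusion is steric or conformational is deliberately not
  represented — only its kinetic consequence.

### The flux-coupling law (a modelling decision)

Flux coupling — permeant K⁺ ions dragging the blocker along the pore axis —
has no agreed closed form. We model it as a bounded multiplier on the
unblocking rate, `exp(−θ·S((V−E_K)/vs))`, centred on the reversal potential
(zero net flux ⇒ no effect) and saturating within a few `vs` of E_K. The
rectified form `S(x) = max(tanh(x), 0)` was chosen over an odd (two-sided)
saturating function for two reasons:

1. *Physics*: outward flux pins the blocker against the outer site of the
   flux-coupling segment and plausibly retards its return to the cytoplasm;
   inward flux merely restores the normal exit pathway — there is no
   additional driving mechanism to accelerate unbinding beyond the Woodhull
   voltage dependence once net flux is inward.
2. *Identifiability*: unblocking rates are measured from tails at
   V ≤ −20 mV. An odd law multiplies every such rate by ≈ e^{+θ} (tanh is
   saturated there), so the extrapolated `off rate(0)` of a Woodhull fit
   would estimate `koff0·e^θ`, not `koff0` — a ~4.6-fold bias for the WT Mg²⁺
   preset. The rectified law leaves V ≤ E_K unbinding purely Woodhull, so the
   tail analysis estimates the model's own parameters exactly, which is what
   the parameter-recovery tests verify.

Both forms produce the characteristic kink of the Kd–V curve at E_K, a
bounded IR index, and Kd decreasing with V above E_K.

## Parameters

Blocker parameters (WT channel), `src/kirblock/data/presets.json` version 1.0:

| parameter | unit | Mg²⁺ | SPM | origin |
|---|---|---|---|---|
| Z (valence) | — | 2 | 4 | effective charges |
| kon0 | M⁻¹s⁻¹ | 1.843×10⁷ | 1×10⁷ | Mg²⁺: 1.2×10⁶ (published, E224G) ÷ E224G rate scaling; SPM: plausible |
| δ_on | — | 0.075 | 0.06 | published (exponent 0.15/25 mV at Z=2; SPM entry nearly voltage-free) |
| koff0 | s⁻¹ | 4300 | 30 | Mg²⁺: published WT value; SPM: plausible (Kd(0) ≈ 3 µM) |
| Zδ_off | — | 0.48 | 2.32 | Mg²⁺: published WT value; SPM: δ≈0.58 × Z=4 |
| θ | — | 3.155384 | 7.412613 | calibrated (below) |
| vs | mV | 15 | 15 | sets the width of the Kd–V kink around E_K |
| kexit0 | s⁻¹ | 0 | 5×10⁻⁴ | Mg²⁺ cannot punch through; SPM value sets escape onset ≈ +40 mV |
| zδ_exit | — | 0 | 2.2 | steep enough that SPM escape dominates its unbinding at +100 mV |

**Calibration of θ.** With every other parameter fixed, θ is solved (once,
by bisection on the closed-form Kd ratio) so that the IR index
Kd(−30)/Kd(+30) in symmetric 100 mM K⁺ equals the published magnitudes:
95 for Mg²⁺ and 1.02×10⁵ for SPM. These two numbers are therefore
*calibration targets, not predictions*; reproducing them verifies that the
model family can express the observed rectification, nothing more. Everything
downstream of the presets (curve shapes, kinetics, synergy) is then genuine
model output.

**Genotypes** are positive multipliers on blocker parameters — barrier-height
and coupling-strength scalings only, no structural modelling. WT, E224G,
M183W and E224G/M183W carry the published per-genotype unblocking pairs
(off rate(0), Zδ) = (4300, 0.48), (370, 0.56), (2800, 0.46), (230, 0.62).
Two published estimates exist for E224G — (280, 0.67) from the
single-genotype kinetic analysis and (370, 0.56) from the multi-genotype
comparison; the preset adopts the latter for consistency of the per-genotype
table, and the former appears as literal values in unit tests of the fitting
functions. E224-family and E299-family mutants set θ = 0 (flux coupling
abolished — the Kd–V kink disappears) and scale kon0/koff0 jointly
(correlated slowing of blocking and unblocking). All other multipliers are
plausible invented values. The negative-cooperative double mutants
(E224G/G177N, E224G/M183N) carry an extra unblocking factor solved so their
coupling coefficients at +40 mV are 0.08 and 0.14 — magnitudes matching the
published cycle analysis; because the underlying single-point Kd values are
not tabulated anywhere, these are illustrative presets, not reproductions.
The additive pairs (E224G/D172N, E224G/A184Q) are exact multiplier products
of their singles, so Ω = 1 by construction.

## The synthetic-data generator

`simulate_sweep` composes exact per-segment relaxations (initial occupancy =
steady state of the first segment; occupancy continuous across boundaries)
and adds i.i.d. Gaussian current noise. Protocol presets follow the study
design: a step family (hold 0 mV, −100 mV pre-pulse 20 ms, test pulses
−150…+100 mV in 10 mV steps, 150 ms) and a two-pulse protocol (hold 0, −100
mV 20 ms, +100 mV of variable length, negative test pulse). Default sampling
is 0.1 ms (10 kHz); tail-kinetics designs sample at 2–10 µs because the
fastest unblocking relaxations in the presets (WT Mg²⁺ at −100 mV,
τ ≈ 33 µs) are unresolvable at 10 kHz. Seeding: one master seed per
experiment; per-sweep seeds derived by stable enumeration order
(`SeedSequence`), so experiments are bit-for-bit reproducible.

**What is deliberately not emulated:** capacitive transients and series
resistance, leak, the ~2 kHz analogue filter, single-channel stochasticity
(currents are ensemble means plus Gaussian noise), K⁺-concentration effects
on Kd beyond E_K (the competition of permeant ions for the flux-coupling
sites, which raises Kd with ambient K⁺, is outside the model), multi-ion
single-file permeation, and the very fast initial phase of repolarization
tails (the model's tails are as many-exponential as the state space allows;
relaxation fits skip a configurable blank window after each step for this
reason). Passing tests therefore demonstrate correctness of the estimators
on data generated by this model class — not robustness to the artefacts of
real recordings.

## Estimators and numerical choices

* **Relaxation fits** (`fit_relaxation`): nonlinear least squares of
  `baseline + Σ aᵢ·exp(−t/τᵢ)` with deterministic multistart (log-spaced τ
  guesses between 5 samples and half the window; pairs thereof for two
  components), τ fitted in log space so it stays positive; 1 vs 2 components
  chosen by BIC; default blank window 1 ms (0.02–0.05 ms in tail designs,
  which have no settling artefact). Non-convergence from all starts raises a
  fit-failure error.
* **Steady-state current**: mean of the final 10% of a segment, with a
  stationarity warning when the preceding 10% differs materially.
* **Unblocking rates from tails** (`unblock_rates`): the tail relaxes at
  `k_on[B] + k_off`, not `k_off`; the pipeline multiplies the fitted rate by
  the steady relative current vs the blocker-free control — exactly `k_off`
  for the two-state scheme. Without a control the raw rate is reported and
  flagged uncorrected.
* **Hill fits** (`fit_hill`): least squares on f with Kd in log space,
  unweighted residuals, analytic starting point from the median half-block
  concentration; standard error from the Jacobian. Dose series entirely
  above f≈0.95 or below f≈0.05 raise an unidentifiability error; series not
  spanning f = 0.5 warn.
* **Kd–voltage curves**: fitted only inside the identifiable window
  (default −60…+60 mV in symmetric 100 mM K⁺, from −100 mV in 20/100);
  excluded voltages are reported with reasons. The IR index interpolates
  log Kd (with a warning) only if ±30 mV are absent.
* **Rate–voltage fits** (`fit_rate_voltage`): default is linear regression of
  ln(rate) on V (robust, equal log-weights). A linear-scale nonlinear option
  (`method="nls"`, the default behaviour of common curve-fitting software) is
  used for the headline on-rate summary because it reproduces published fits
  of this form at the printed precision, where the log-linear slope rounds
  one digit high. Both invert noise-free model data exactly.
* **Kd–V shift**: coarse 0.05 mV grid search of the log-Kd alignment SSE
  followed by bounded refinement; evaluated on the overlapping voltage
  support at each candidate shift.
* **Synergy nulls**: two standard steady-state nulls bracket "no synergy" —
  independent sites (`f_A·f_B`) and mutually exclusive competition
  (`1/(1+[A]/Kd_A+[B]/Kd_B)`, Kds inferred from the single-blocker groups);
  the synergy flag requires the measured two-blocker f below both.
* **Macroscopic binding rates**: fitted 1/τ contains the unbinding rate, so
  sums of 1/τ are not additive at sub-Kd concentrations. The additivity flag
  uses the initial slope of the normalized fitted decay,
  `Σ aᵢ/τᵢ / I_control` — exactly `k_on[B]` for the two-state scheme and
  exactly additive over blockers in the model (tolerance 20%, reflecting the
  "roughly additive" claim being tested). Raw 1/τ values are reported
  alongside.
* **Ensemble averaging** (`average_experiments`): replicate experiments are
  averaged sample-wise (noise ↓ √n), mirroring per-point patch counts of
  4–8 in this kind of study.

## Validation scale

The test suite validates the solver against an explicit RK4 micro-step
integration of the master equation (1 µs steps, 10⁻⁶ absolute) and against
aggregated exact stochastic simulation of 10⁵ independent channels (3 Monte
Carlo SE); steady states against hand-solved balance equations (10⁻⁹
relative). Parameter recovery runs the full pipeline on WT and E224G presets
at 5% recording noise with 5 averaged replicates per estimate over 100 seeds
(median relative errors ≈ 1–4%, asserted < 10%; noise-free recovery is exact
to < 0.1%). Hill/Kd recovery uses 100 seeds at noise SD 0.02 on f. These
problem sizes keep the whole suite around two minutes on one CPU.

## Known limitations

* The flux-coupling law is phenomenological; θ and vs are calibration
  constants, and alternative bounded laws fit the same constraints.
* Absolute Kd scales for SPM at positive voltages are very small (sub-nM at
  +30 mV in symmetric K⁺): with the Woodhull part fixed by the published
  Zδ values, the enormous rectification ratio must be carried by the flux
  factor, compressing Kd at depolarized potentials. Trends and ratios are
  meaningful; absolute SPM Kd values at V > 0 should not be read as
  physiological affinities.
* Mutant multipliers other than the four published unblocking pairs are
  invented; cycle-analysis Ω values for the negative-cooperative doubles are
  calibrated magnitudes, not measurements.
* No modelling of K⁺-occupancy competition, pore conformational dynamics, or
  structural interpretation of coupling coefficients.
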