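# Methods

`channelphys` re-implements, as a tested pipeline with synthetic ground
truth, the quantitative procedures used to characterize a Golgi-resident,
voltage-dependent, inwardly rectifying cation channel: single-channel
gating and kinetics, whole-cell I-V and pharmacology, boost-potential
enhanced-sampling mechanics, linear-interaction-energy (LIE) binding
energetics, lipid-binding geometry, and ratiometric organelle-pH
analysis. This note records the models, their assumptions, and the
numerical choices made where the design was genuinely open.

Units are fixed package-wide: pA, mV, ms, pS, kHz, Å, kJ/mol (boost
parameters in kcal/mol by field convention; 1 kcal = 4.184 kJ exactly).
Inward current is negative.

## Markov gating and trace synthesis

Single-channel gating is modelled as a continuous-time Markov chain over
states labelled `closed`, `open` and `sub` (a half-conductance
sublevel). Realizations are generated event-driven (Gillespie):
exponential holding times from each state's total exit rate, categorical
jumps from the off-diagonal rates. This is exact — dwell-time
distributions are exactly exponential — which is what the downstream
maximum-likelihood recovery tests require; a fixed-step discretization
would bias short dwells.

The default voltage-dependent model is a C ↔ O ↔ O_sub chain tabulated
over the step family +90 … −150 mV. Its defining features mirror the
recorded phenotype: zero opening rate at 0 mV (so Po = 0 exactly), a
U-shaped Po-voltage relation with maximum Po = 0.6 at +90 mV and
Po = 0.3 at −150 mV, brief flickery openings on the positive limb (mean
open time 26 ms) versus long sparse openings on the negative limb
(421 ms), and a subconductance level (0.5× the full conductance)
reachable only at positive potentials. One caveat is intrinsic to the
source data: the printed dwell-time constants at +90 mV (26/41 ms) imply
a *two-state* open fraction of 0.39, not the printed maximum Po of 0.6 —
the real channel's kinetics are evidently not two-state. The generators
therefore pin **either** the stationary Po (`two_state_model_from_po`)
**or** the dwell times (`two_state_model`), never both at once, and the
default model pins Po per voltage while keeping the open-time constants.
The O ↔ O_sub exchange rates are not constrained by any printed value
and are config-exposed (stationary sub/open occupancy ratio 0.25, sub
exit rate 0.1 ms⁻¹ by default).

Rendering maps each sample to the conductance of the active state,
`i = g·(V − E_rev)·10⁻³` pA, adds independent Gaussian noise, and
optionally applies a zero-phase 4-pole Bessel-style low-pass (default
2 kHz, requiring ≥ 2× sampling headroom). No attempt is made to emulate
recording artifacts (capacitance transients, drift, mains hum).

## Single-channel analysis

Idealization is the field-standard half-amplitude threshold, sign-aware,
with a hysteresis band of 0.1× the unitary amplitude straddling the
half level (suppresses noise chatter at the threshold), followed by
dead-time merging: runs shorter than the dead time are absorbed
shortest-first into their neighbours. No hidden-Markov idealization and
no missed-event correction beyond the fixed dead time.

Dwell-time constants are estimated by closed-form MLE on event
durations: for a left-truncated exponential sample the MLE is
`mean − dead_time` (memorylessness). This is unbiased given truncation
but does not correct missed-event inflation; the recovery tests
therefore keep the dead time ≤ 3 sample periods, where the residual bias
is well inside the 3σ CLT band. Open probability is time in conducting
states over total time, with subconductance occupancy counted as open
(a flagged choice — the source analysis does not state its convention);
per-level occupancy is available separately.

Amplitude histograms are fitted by Gaussian-mixture EM (k-means++
initialization, 5 seeded restarts, components reported sorted by mean,
peak separation in pooled-SD units as a quality metric). Unitary I-V
curves are least-squares polynomials, default degree 3 (the source
states only "a polynomial"); the macroscopic reconstruction is the
elementwise product of the unitary polynomial and the Po curve, whose
rectification index |I(−150)|/|I(+100)| quantifies how a weakly
rectifying unitary current combined with a strongly asymmetric Po yields
a strongly rectifying ensemble current.

## Whole-cell analysis

Ramp recordings (+100 → −150 mV, 1000 ms by default) are mapped
sample-by-sample to the instantaneous command voltage and averaged
across sweeps. Reversal potentials are linear interpolations at the
zero-current crossing; with multiple crossings the one nearest 0 mV is
returned with a warning.

Permeability ratios use the bi-ionic GHK reduction
`P_X/P_Na = exp(FΔE_rev/RT)`, valid for the equimolar substitution
design (150 mM external test cation, fixed internal solution). From the
mean reversal-potential shifts this yields P_K/P_Na = 1.4; the same
arithmetic applied to the Cs⁺ shift (−3.5 vs −7.7 mV) gives 1.18, lower
than the reported 1.6 — per-cell paired shifts rather than means
presumably underlie the reported value; we document and do not
reconcile. Temperature defaults to 298.15 K (RT/F ≈ 25.7 mV); the K⁺
result is insensitive over 22–25 °C. A two-term GHK form accepting full
solution data is provided; its internal terms cancel under the bi-ionic
design.

Hill inhibition fits minimize least squares of
`Y = 100/(1 + (IC50/X)^h)` with the slope kept *signed* (negative for
inhibition, matching the convention in which the gadolinium and
gluconate slopes are −1.498 and −1.301). Multi-start over both slope
signs and a concentration-spanning IC50 grid makes the fit insensitive
to initialization.

Liquid-junction potentials use the Henderson mixture formula with a
bundled, versioned limiting-conductivity table (CRC values for the
inorganic ions; standard patch-clamp relative-mobility compilations for
gluconate, isethionate and NMDG). The returned sign convention is bath
minus pipette: a slow pipette anion (K-gluconate internal) against a
NaCl bath gives +15.1 mV here, against the +13 mV used in the source —
within the scatter expected from mobility-table choice. Solutions are
validated for electroneutrality (warning above 1% imbalance).

## Boost-potential mechanics and LIE energetics

The Gaussian-boost scheme adds `ΔV = ½k(E − V)²` wherever `V < E`, with
`(E, k)` selected from potential statistics under the canonical
constraint `Vmax ≤ E ≤ Vmin + 1/k`: the effective constant
`k0 = min(1, (σ0/σV)(Vmax − Vmin)/(Vmax − Vavg))`, `k = k0/(Vmax − Vmin)`,
and E at the lower (`Vmax`) or upper (`Vmin + 1/k`, more aggressive)
bound; σ0 defaults to 6.0 kcal/mol. Under the constraint the map
V → V + ΔV is monotone, so boosting never reorders potential levels.

The demonstrator is 1-D overdamped Langevin (Euler-Maruyama) on a
double-well `a(x² − 1)²` — the smallest system exhibiting barrier
crossing — with a single boost term; dihedral/total dual-boost
decomposition and any reweighting of boosted statistics are out of
scope. The test suite checks the mechanics invariants (ΔV ≥ 0, monotone
V*, bound satisfaction) and that boosting accelerates barrier crossings
in ≥ 95% of matched-seed pairs.

The LIE estimator combines post-burn-in average coulombic and van der
Waals interaction energies of five subsystems (protein-lipid p-L, bare
protein p*, isolated lipid L(g), membrane-lipid m-L, bare membrane m*):
`ΔE_{L→p} = E_{p-L} − E_{p*} − E_{L(g)}`, likewise `ΔE_{L→m}`, their
difference `ΔE_{m→p}`, and
`ΔF_{m→p} = 0.5·ΔE^Q + 0.16·ΔE^vdW` (kJ/mol). For the fully bound
phosphatidylethanolamine case, ΔE^Q = −40 and ΔE^vdW = −77.5 kJ/mol give
ΔF = −32.4 kJ/mol; against the phosphatidylcholine value of −13.2 the
transfer preference is 19.2 kJ/mol in favour of PE.

## Lipid-binding geometry

The transmembrane domain's long axis is the eigenvector of the smallest
eigenvalue of the mass-weighted inertia tensor about the selection's
center of mass (sign fixed toward +z; near-degenerate tensors are
rejected as ambiguous). Binding is summarized per frame by two
perpendicular point-to-line distances: the lipid phosphorus atom (dP)
and the mass-weighted center of the second acyl chain (dR2-Cent). The
axis is recomputed per frame; no cross-frame alignment is performed (the
alternative — aligning all frames to a reference before a single axis
computation — would matter only if the domain deformed, which the
synthetic generator does not model).

States are thresholded local maxima of the 2-D (dP, dR2-Cent) histogram
(default 0.5 Å bins, ≥ 1% of frames, non-maximum suppression within
2 bins), labelled S1…Sn by descending population — deterministic, unlike
a clustering initialization. Frames are classified to the nearest mode
center within a cutoff (default 5 Å); the classification reports visit
order, per-state dwell totals and the first-passage path into S1, which
on the staged synthetic trajectories reproduces stepwise entry
(e.g. S4 → S3 → S1).

## Ratiometric pH analysis

The 405:475 nm excitation ratio is mapped to pH through a Boltzmann
sigmoid `pH(r) = pH_min + (pH_max − pH_min)/(1 + exp((r_half − r)/s))` —
the field-standard shape for ratiometric pHluorin calibrations, fitted
to ≥ 4 monotone standards and analytically invertible. Linear or
near-linear standards degrade gracefully to a near-linear segment of the
sigmoid (the fit is still accepted; residuals are reported). Resting pH
is the mean over the 10 s preceding the weak-base (NH4Cl, onset 30 s)
pulse; the post-stimulus pH is read at a configurable offset (default
10 s) after onset, and their difference is the buffering-response
magnitude. Inputs are per-cell intensity traces; no image processing.

## Synthetic-data generators and what passing tests show

Every analysis input can be generated with known truth: CTMC gating
events and rendered traces; Hill-model dose-response tables
(multiplicative Gaussian noise, cv 5% in the standard conditions, 5
replicates at the tested concentration grids); Gaussian
interaction-energy series; piecewise-stationary 2-D Gaussian
(dP, dR2-Cent) emissions with matching 3-D coordinate frames (a
cylindrical cage realizes the axis, markers realize the exact emitted
distances); and two-channel fluorescence with a pH step mapped through
the inverse calibration. Noise models are the simplest consistent with
the data class: additive Gaussian on current, multiplicative Gaussian on
fluorescence and dose-response.

Recovery tests on these fixtures demonstrate estimator correctness —
that the pipeline recovers what generated the data at the stated
tolerances — not that the models capture every property of real
recordings (multi-component kinetics, baseline drift, spectral offsets
between sensor constructs, correlated noise are all absent by design).

## Problem sizes and determinism

Default test and reproduction sizes are desk-scale: 60 s simulated
records at 10 kHz for Po recovery, ≥ 5000-event records for dwell
recovery (sampling chosen so the dead time is ≤ 3 sample periods),
5 × 5-point dose-response tables, 30k-step Langevin runs. All
generators take explicit seeds and are bit-reproducible for a fixed
seed and parameter set. `scripts/acceptance.py` derives per-quantity
sub-seeds deterministically from its `--seed` argument.

## Known limitations

- Two-state fixtures cannot reproduce the printed Po and dwell times
  simultaneously (see above); the discrepancy is inherited from the
  source values, not the estimators.
- The dwell MLE corrects truncation, not missed events; at dead times
  beyond a few percent of the dwell constant the estimate inflates.
- The Henderson LJP depends on the mobility table at the ±2 mV level.
- The GHK reduction assumes ideal, equimolar bi-ionic conditions;
  activity coefficients are ignored.
- The boost demonstrator is 1-D and single-boost; it validates the
  mechanics, not any molecular observable.
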