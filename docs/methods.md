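# Methods

## Model

The cell cycle is reduced to the two phases a G1/S reporter can
distinguish: G1 and the combined S-G2.  Each phase is a chain of
exponential subphases (linear chain trick), so a cell's phase transit
time is Erlang when the subphase rates within a phase are equal and
hypoexponential otherwise.  Subphases are grouped into 4 parts per
phase (2 G1 subphases and 5 S-G2 subphases per part by default) so a
drug can act differently at the beginning, middle, or end of a phase;
each part carries one progression rate and one death rate.  Division at
the end of the last S-G2 subphase produces two newborn G1 cells.

The mean-field system is linear, `dx/dt = A x`, with A assembled by
`build_generator`.  The state is augmented with two absorbing
compartments that integrate the per-phase death fluxes exactly, so the
accumulated-dead series carries no quadrature error.  A discrete-sum
accounting mode (`accumulate_dead_discrete`) is also provided: it sums
the instantaneous death counts n(t) = Σ parts G_part(t)·γ_part over the
grid.  The default weights the sum trapezoidally by the grid step,
which converges to the absorbing-compartment value as dt → 0 and is
within 0.03% of the closed form on the pure-death benchmark at
dt = 0.5 h; a bare unit-weighted running sum is available as
`weight="unit"` for compatibility with conventions that report the raw
sum.

Propagation uses one matrix exponential per step size applied
repeatedly, which is exact for any uniform grid; non-uniform grids are
rejected rather than silently re-exponentiated.  The live system is
28-dimensional by default — dense `scipy.linalg.expm` with no stiffness
handling is ample.

The initial condition is one expected cell split `initial_g1_fraction`
: 1 − fraction between the phases.  The within-phase spread is not
determined by population data; the default spreads mass uniformly over
the subphases of each phase (the least committal choice), with
`first_subphase` and `stationary` (dominant-eigenvector, renormalized
per phase) as alternatives.  The spread shifts the phase of the
early-time G1-fraction oscillation, so it is an explicit argument
everywhere.

The two-state exponential baseline (one memoryless compartment per
phase) is the same machinery with a 1-part/1-subphase structure.  Its
printed form elsewhere reuses γ₁ in the S-G2 loss term; we implement
the symmetric form with γ₂ and provide `strict_paper_gamma=True` to
reproduce the asymmetric variant.  This model cannot sustain G1-fraction
oscillations — the test suite verifies the detrended amplitude decays —
which is precisely why the chain model exists.

## Dose response

Every rate responds to concentration via a four-parameter Hill curve;
C = 0 is special-cased to E_min rather than evaluated through the power
law.  Per drug, one EC50 and one steepness are shared across all 16
rate slots, E_min values are the globally shared drug-free rates, and
E_max is free per slot but maskable (a "G1-only" drug frees only the α
slots).  This sharing scheme is a design choice: it keeps the per-drug
parameter count at 2 + (free slots) while allowing part-resolved
effects.  Drug-free death rates default to zero, reflecting negligible
death in untreated controls over assay timescales.

## Stochastic simulator and synthetic data

`simulate_cells` is the exact stochastic counterpart of the ODE system:
within each subphase a cell draws competing exponential progression and
death times at its part's rates; exit from the last S-G2 subphase
spawns two daughters.  Expectation equivalence with the mean-field
model is therefore a theorem, and the test suite verifies it:
per-founder ensemble means of G1/S-G2/dead counts agree with the
mean-field trajectories within 3 Monte-Carlo SE at every 30-minute
timepoint for randomized rate sets with 10,000 founders.  (That bound
is applied simultaneously at ~580 correlated timepoints, so occasional
single-point exceedances of 3 SE are expected sampling behavior of the
max statistic, not model error; bias checks at fixed timepoints average
to zero.)

The dataset generator emulates the imaging experiment: populations per
concentration and replicate on a 30-minute cadence over 96 h, an
8-point dose series, 3 replicates, counts normalized to the mean of the
first three timepoints.  Observation noise is multiplicative lognormal
on counts (default CV 5%, a typical counting-pipeline magnitude; the
true value for any real pipeline is unknown and the setting is recorded
in dataset metadata) and binomial sampling on the G1 fraction.  Founder
cells default to 1,000 per condition.  A population cap (default
50,000 cells) uniformly subsamples newborn cohorts purely as a runtime
guard; it biases late-time counts downward and is flagged in metadata
whenever triggered.  Cells alive at the horizon are censored, mirroring
incomplete-lineage exclusions in manual tracking.

What the generator does *not* emulate: segmentation/tracking errors
with temporal structure, mother–daughter duration correlations,
cell-to-cell rate heterogeneity, drug decay between media changes, and
spatial effects.  Passing recovery tests on these data therefore
demonstrates correctness of the inference machinery under the model's
own assumptions, not robustness to real-data artifacts.

## Preprocessing

Fixed pipeline: normalize (first-three-timepoints rule) → smooth →
average replicates → split into phase counts via g1 = total·fracG1.
Smoothing is Savitzky–Golay, default window 11 samples (~5 h at the
30-minute cadence — short against the ~24 h cell-cycle oscillations it
must preserve) and polyorder 3, with polynomial edge handling; negative
smoothed values are clamped to zero and logged.  Because the filter is
linear, smoothing each replicate before averaging equals averaging
first except where clamping engages; both orderings are available and
recorded in provenance.

## Subphase counts from single-cell data

The number of subphases per phase is estimated, not chosen: a gamma
distribution is fitted (MLE, location fixed at 0) to complete
single-cell phase durations and the shape is rounded to the nearest
integer ≥ 1 (ties round up; the original rounding rule is unstated).
Only durations fully observed inside the assay window enter, which
right-truncates long durations — a bias that matters at durations
comparable to the window.  Independence of G1 and S-G2 durations is
checked by Pearson correlation (Spearman optional) on paired per-cell
durations.  At n = 10,000 the integer shape is recovered essentially
always for shape 8 and in ≈90–95% of runs for shape 20, where the MLE's
sampling SD (~0.28) approaches the rounding half-width.

## Fitting

The cost is the plain SSE between model and observed G1 and S-G2
counts over all drugs, doses and timepoints, with drug-free rates and
the initial G1 fraction shared across drugs.  Optimization is seeded
differential evolution under box bounds — rates on a log scale in
[1e-4, 10]/h, EC50 log-bounded to [min dose/10, max dose×10],
steepness in [0.1, 10], the G1 fraction on a logit scale — followed by
an explicit L-BFGS-B polish whose gradient convergence provides the
`converged` flag.  Default budget (popsize multiplier 12–15, 150–200
generations) recovers control phase durations to well under 1% and
EC50 to under 1% on noiseless single-drug data; out-of-bound or
non-finite parameter vectors receive a large finite penalty.

Identifiability is assessed by local sensitivity: each fitted parameter
is scaled over a log grid spanning [0.1, 10]× its optimum with the
others fixed, and a parameter is flagged identifiable when the cost
rises by more than 1% at both 0.5× and 2× (the 1% threshold is a
package choice).

## Combination prediction

Bliss additivity is applied per part-rate slot to the fractional
progression effects (the finest granularity consistent with a shared
control), and death-rate increments add — death is treated as
non-saturable, whereas progression inhibition saturates at full block.
Drugs that *accelerate* a progression rate have no Bliss representation
(the scaled effect would be negative) and are rejected explicitly.
The count-based baseline applies the same scaling formula to
control-normalized counts per timepoint, with the endpoint typically
reported.  Both routes reduce exactly to the single drug when either
dose is zero.

## Problem sizes and numerics

Default analyses use the 0.5 h grid over 96 h (193 points), 8-dose
series, 10,000-founder ensembles for oracle comparisons, and n = 10,000
duration samples for shape estimation — sizes at which Monte-Carlo
error is comfortably below the tolerances quoted above while a full
fit-plus-validation cycle completes on a laptop-class CPU.  Matrix
exponential propagation agrees with step-composition to 1e-8 relative;
trajectory mass balance holds to solver precision (total ≡ 1 with
division gain off and no death).

## Known limitations

Phase parts are phenomenological, not mechanistic checkpoints.  The
shared-EC50/steepness scheme cannot represent drugs whose potency
differs between targets.  Combination prediction requires both profiles
to share one control rate set, and inherits Bliss's assumption of
independent action.  No pharmacokinetics: concentration is constant
over the assay.  Heterogeneous subpopulations and dose scheduling are
out of scope.
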