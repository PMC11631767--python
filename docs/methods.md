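# Methods

## Switch thermodynamics

A two-component LOCKR sensor is modelled as a single cage molecule in
equilibrium over five states: closed (latch in the groove, TBD occluded),
open/empty, open/target-bound, key-bound without target (the false-positive
state) and key-bound with target. The closed state carries weight
exp(−ΔG_close/RT) relative to the open/empty reference; target and key
binding contribute factors T/K_d,target and K/K_d,key. Two structural
assumptions close the scheme: the target cannot bind the closed cage (the
TBD is fully occluded by the cage), and the key cannot bind while the latch
is closed — there is no ternary latch+key state. This is the simplest
scheme consistent with the three named functional states (closed, open,
false-positive); whether target binding to the closed state is strictly
zero or merely weak is not observable at the level of this model, and zero
is adopted.

ΔG_close is G(closed) − G(open) in kcal/mol (negative favours closed);
dissociation constants and all concentrations are molar. RT is computed
from the temperature (default 298.15 K, giving RT = 0.593 kcal/mol, the
standard biochemical convention).

**Finite concentrations.** Free key and target concentrations satisfy
mass balance against total cage, key and target. With the other free
variable held fixed, each balance is a quadratic with a unique non-negative
root (because the bound fraction is a saturating rational function of the
free concentration), so the solver alternates the two exact one-dimensional
solves. This Gauss–Seidel fixed point converges in a handful of iterations
across the tested regimes; if the residual contract (relative mass-balance
error < 1e−9) is not met within 10,000 sweeps, the solver falls back to
bracketed bisection on the target balance with the exact inner key solve.
Both balances are monotone in their own free variable, which guarantees
uniqueness. The test suite checks the solver against an independently
coded nested interval-halving oracle on random instances.

**Readout.** The measurable signal is the key-bound fraction
P(S4) + P(S5). A FRET-like ratio is an affine map R_min + (R_max −
R_min)·signal; linearity of the ratio in the key-bound fraction is an
assumption of convenience, not a measured property.

**Mutations.** Interface-weakening mutations carry a positive ΔΔG.
Latch:cage mutations add to ΔG_close; key:cage mutations multiply K_d,key
by exp(ΔΔG/RT). Effects at the same interface are treated as additive —
multi-mutation constructs are routinely described by their per-interface
counts without interaction terms, and nothing in the model constrains
non-additivity. The model then reproduces the observed tuning directions
as theorems: raising ΔG_close (weaker latch) increases the background
(zero-target) signal and shifts the response to lower target
concentrations; raising K_d,key (weaker key) lowers both background and
saturating signal.

**Tuning search.** `tune` enumerates all subsets of a mutation library
(capped at 20 effects) and maximises signal(T_hi) − signal(T_lo) subject to
signal(0) ≤ cap, breaking ties towards fewer mutations then lexicographic
names. Because additivity makes subsets with equal per-interface ΔΔG sums
equivalent, objectives are cached by those sums. An infeasible cap returns
the lowest-background subset flagged infeasible rather than failing.

**EC50** is computed by linear interpolation of the signal on log10 dose at
the half-rise between basal and plateau; a curve that never crosses the
half-rise returns NaN with a warning rather than extrapolating.

**Reference sensor.** Examples, simulations and the acceptance script use
ΔG_close = −3 kcal/mol, K_d,key = 1 µM, K_d,target = 100 nM, and 1 µM total
cage and key. The target affinity reflects the ~100 nM affinity typical of
Ras-binding domains for Ras·GTP and places the sensitive region of the
sensor in the physiologically relevant nanomolar-to-micromolar window; the
micromolar totals reflect transient-expression levels.

## Motif grafting

Sensor specificity comes from threading the N-terminal 7–11 residues of a
target-binding motif into a latch window (residues 610–644 in the reference
construct, a 35-residue span). Since an α-helix turns every 3.6 residues,
each start offset presents the motif on a different helical face;
`enumerate_placements` therefore emits one candidate per (prefix length,
start offset) pair — Σ_L (span − L + 1) candidates, 135 for the reference
window — ordered by length then offset. The heptad class (offset mod 7) is
attached as a face label only; no energetic filtering is performed, because
ranking grafts requires structure-based scoring that is out of scope here.
Candidates round-trip through FASTA with coordinates encoded in headers.

## FRET quantification

Per frame and channel, the mean intensity of a cell-free background region
is subtracted (mean, not median; values may go slightly negative and are
left so — clipping is a display concern). The per-cell ratio is
mean(FRET channel)/mean(donor channel) within the ROI; the FRET channel is
the acceptor-emission-under-donor-excitation channel and the division
orientation is configurable since conventions differ between labs. R0 is
the single frame immediately preceding stimulation (an option averages the
baseline instead). Normalisations: `r0` divides each trace by its own R0;
`minmax` affinely maps the pooled dataset to [0, 1]; `ref_min` subtracts
the pooled dataset minimum so 0 marks the lowest ratio in the dataset
(attained in the condition with the largest decrease) — the scale factor is
deliberately left at 1 as no further definition is available. SNR is the
maximum post-stimulus rise over the sample s.d. of a ≥3-frame baseline
window. The brightness QC rule excludes cells whose acceptor intensity
strictly exceeds the population mean + 3 s.d.; note that a single outlier
can only exceed 3 sample s.d. in populations of ≥ 12 cells, so the rule is
skipped (with a warning) below 3 cells and is naturally inert in very small
populations. Pixel-wise ratio images mask non-positive donor pixels and
return the numeric field separately from the colormapped render.

## Imaging statistics

Pearson's coefficient is the sample correlation of two channels over a
mask; Manders' M1 is the fraction of channel-a intensity in pixels where
channel b exceeds its threshold (M2 symmetric), thresholds defaulting to
per-channel Otsu within the mask. Note M1 = M2 = 1 for identical channels
only when all intensity is supra-threshold (objects on zero background).
Particle analysis thresholds the image (Otsu by default, pluggable), labels
8-connected components, and retains those with circularity 4πA/P² > 0.5 and
area > 1 µm² (both strict). The perimeter uses the Crofton estimator;
digitised perimeters bias circularity for small regions (a few-pixel disk
can exceed 1, so values are capped at 1, and digitised disks approach
circularity 1 from below as radius grows). The thresholding algorithm and
connectivity of the original ImageJ-based analyses are not recorded, so the
defaults here are declared choices, not inferences. Nucleus exclusion for
co-localization is the caller's responsibility via the mask argument.

## Proteomics

Zeros in MaxQuant intensity columns denote non-observation and are treated
as missing. Rows flagged `Potential contaminant`, `Reverse` or
`Only identified by site` are dropped (overlapping flags counted once).
Each sample column is log2-transformed and centred on its median
(idempotent; |median| < 1e−9 afterwards). Replicate QC computes pairwise
Pearson r over mutually observed rows; within each experiment a replicate
whose mean pairwise r deviates from the experiment-wide mean of those means
by more than 0.25 is excluded, in a single pass. The alternative reading —
any single pairwise r deviating by 0.25 — would exclude both members of a
discordant pair; the per-replicate mean pinpoints the outlier, so it is the
implemented rule. Missing cells are imputed per sample from
N(m − 1.8·s, (0.2·s)²) where m, s are that sample's observed mean and
s.d. — the downshift and width are in units of the per-sample s.d.,
the convention of the software that popularised these constants — and
imputed cells are tracked in a mask so observed values are never
overwritten.

Differential enrichment reports the difference of condition means on the
log2 scale with Benjamini–Hochberg adjustment. The default test is a
moderated two-sample t-test: per-protein pooled variances are shrunk
towards a prior fitted across the table by matching the moments of
log s² to its scaled-F sampling distribution, and the statistic is referred
to a t distribution with correspondingly augmented degrees of freedom.
With 3–4 replicates per condition a plain t-test has ~6 degrees of freedom,
which floors attainable p-values near 1e−3 and cripples FDR-controlled
discovery even for 4-fold effects; variance moderation is the field's
standard remedy and is calibrated under the null (permutation and Welch
tests remain available via `method=`). With a single protein the moderated
test degenerates to the ordinary pooled t-test.

## Synthetic data

The microscopy generator draws ellipsoidal cells on a jittered grid with a
uniform donor level, a per-cell true ratio trajectory (baseline plus a step
at the stimulus frame), optional 1-µm-scale puncta that multiply the local
ratio, an acceptor channel with an optional planted over-bright cell, a
constant background offset, and signal-proportional Gaussian noise with an
additive floor. It emulates the geometry and noise scale of ratiometric
epifluorescence data but none of the optics: no PSF, no photobleaching, no
shading, and cell interiors are flat. Passing recovery tests therefore
demonstrates correctness of the quantification arithmetic and filters, not
robustness to real optical artefacts. The dose-response generator applies
unit-mean lognormal noise of specified CV to the model signal. The
proteomics generator draws per-protein lognormal baselines, adds a fixed
log2 effect to a planted set in one condition, censors low intensities with
a logistic intensity-dependent probability (the missing-not-at-random
regime that motivates downshifted imputation) and writes a
MaxQuant-dialect TSV with optional flagged rows. All generators are
bit-reproducible from (config, seed).

## Problem sizes and numerics

Default verification sizes — 100 random instances for the solver oracle,
1,000 for the tuning-direction sweep, 100 titration refits, 20-cell stacks
at 420×420 px, 1,000-protein tables — were chosen so the full suite and the
acceptance script each complete in well under a minute on a laptop-class
CPU while keeping Monte-Carlo noise far from the asserted tolerances.
Solver tolerances: free-concentration fixed point to 1e−12 relative,
mass-balance contract 1e−9 relative, oracle agreement asserted at 1e−6.
Degenerate inputs are flagged rather than silently handled: zero-variance
channels (Pearson), zero total intensity (Manders), all-missing columns
(normalisation), <2 observed values (imputation), baseline s.d. of zero
(SNR reported as infinite).
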