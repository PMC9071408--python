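# Methods

This note records the models, parameter choices and numerical conventions
behind `epimark`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Quantification ladder

**SILIS ratio.** Each analyte's light-channel area is divided by the area
of its ¹³C-labelled counterpart co-injected with every sample.  The heavy
channel cancels injection volume, ionisation efficiency and detector
drift per compound.  Modifications without a heavy partner keep their raw
area; they are carried through relative analyses but excluded from
absolute quantification, because without an internal reference their
areas are not commensurable across runs.

**UV normalization.** The ratio is divided by the mean 254 nm UV area of
the four canonical nucleosides, which is proportional to the amount of
RNA actually digested and injected.  The internal standard itself
contributes UV signal; we subtract an explicit term
`uv_response_per_ng × 50 ng` from the canonical mean.  The published
phrase describing this correction does not pin down its functional form,
so the response is a configuration parameter with default 0 (no
correction): the term is visible, testable, and off unless calibrated.
A non-positive corrected normaliser marks the sample unusable rather than
producing a sign flip downstream.

**Mean scaling.** Each modification row is divided by its own mean across
the compared samples.  This is idempotent, invariant to rescaling a row's
raw inputs by a positive constant, and leaves all-zero rows untouched
(with a warning) rather than producing NaNs.  Matrices carry their stage
(`ratio → uv_normalized → mean_scaled → absolute_percent_A`) and may only
advance through it; profiling an absolute-stage matrix re-bases it first,
which is harmless because mean scaling is row-scale-invariant.

**Absolute branch.** An ordinary least-squares external calibration line
(ratio vs ng; ≥ 3 points, ≥ 2 distinct amounts, slope > 0, R² reported)
is inverted to an injected amount and expressed as a percentage of the
adenosine UV area.  Ratios at or below the intercept report
below-detection; amounts outside the calibrated span are computed but
flagged.  The combined internal/external calibration published elsewhere
is richer than one OLS line; ours is a documented stand-in with the same
interface.

**Peak integration** (for simulated traces): trapezoidal integral of
baseline-subtracted intensity in the retention window, baseline = median
intensity outside the window, S/N = baseline-subtracted apex over a
MAD-based robust SD of the out-of-window residuals (1.4826 × MAD).  A
flat zero trace scores (0, 0).  Median/MAD were chosen over mean/SD so
that a peak's own tail cannot inflate its noise estimate.

## Degradation QC

A tRNA-size gel fraction should contain no m⁶,⁶A or Am; what it does
contain arrived by rRNA fragmentation.  The degradation index is the
geometric mean of the two markers' fold changes over a pristine baseline
(the mean profile of samples taken at time 0 and processed without
freezing; any 0 h samples serve when unfrozen ones are absent).  The
geometric mean keeps the two markers symmetric and makes the index 1 for
a sample identical to baseline.  Only the marker rows enter, so unrelated
modifications cannot move the verdict.

The published exclusion rule is qualitative ("high levels").  We default
to a 2-fold cutoff, report the index itself so users can re-threshold,
and record in the QC provenance that the original rule was not numeric.
m³U is tracked but excluded from the index because the large-subunit
marker demonstrably does not follow the small-subunit pair.  The S/N
inclusion filter is a floor: ≥ 5 in at least one compared sample keeps a
modification, below in all samples drops it (reported for grey-bar
annotation).

## Profiling

Hierarchical clustering uses average linkage on euclidean distances of
mean-scaled rows by default; both are parameters, and the correlation
metric falls back to euclidean (with a warning) when a constant vector
makes it undefined.  Rows, columns, or both can be clustered; k-means row
labels are capped at 300 clusters and seeded for determinism.  PCA treats
samples as observations and modifications as features, centers each
feature, and takes components from the SVD; loadings are orthonormal with
the largest-magnitude loading of each component made positive, and five
components are the default.  Per-modification group comparisons use
two-sided Welch t-tests at α = 0.01 with no multiple-testing correction
gating significance — mirroring the workflow this package reimplements,
which applied a raw 0.01 cutoff to a small modification panel —
while Benjamini–Hochberg q-values are attached as a supplementary column.
Groups with fewer than three replicates are skipped and reported, and
identical zero-variance groups give p = 1.

Tissue discrimination removes the rRNA marker rows (they report
degradation, not tissue), optionally restricts to a caller-supplied row
set (e.g. the tRNA-core panel), mean-scales, clusters the columns, cuts
the tree at the number of tissues and reports majority-label purity, plus
3-component PCA scores.  A permutation null for purity (label shuffling
against the fixed clustering) quantifies whether the separation exceeds
chance; note this is a significance statement with the usual α-level
false-positive rate over repeated draws.

## Synthetic degradome

**Pool.** Five species with standard mouse lengths — tRNA 75 nt (10% of
pool mass), mitochondrial tRNA 70 nt (3%), 18S rRNA 1870 nt (25%), 28S
rRNA 4718 nt (57%), mRNA 2000 nt (5%) — so rRNA carries > 80% of the
mass.  Per-nt modification densities are seeded from the packaged
absolute-quantification reference matrix (value in % of adenosine ≈
density × 400, treating A as a quarter of residues), with
literature-magnitude densities for panel modifications the reference does
not quantify.  Am, m⁶,⁶A and m³U densities are zero in the tRNA-size
species by construction: their measured traces in real tRNA fractions are
precisely the contamination the QC detects.  The brain-tissue scenario
applies fixed per-tissue multipliers (0.70–1.40) to six tRNA-core
densities each for cerebellum and hippocampus, with cortex as reference.

**Kinetics.** Cuts are a Poisson process along each molecule with per-nt
density `u = s · (ρ₀ + r·t [+ freeze-thaw extra])`: ρ₀ = 5×10⁻⁵ cuts/nt
is an isolation-induced baseline present at t = 0 (so the gel windows are
populated from the onset), r is the tissue rate — liver 7×10⁻⁵, brain
2×10⁻⁶ cuts/nt/h post mortem, 0.2 cuts/nt/h for the in-vitro RNase
setting — and s is a species susceptibility: 1.0 for rRNA/mRNA, 0.05 for
the tRNA-sized species post mortem (compact, protein-bound RNA inside
dying cells), 0.3 in vitro (deproteinised but base-paired).  Freezing and
thawing adds 2×10⁻⁵ cuts/nt in liver only.  These constants were chosen
analytically so that the generator reproduces the qualitative kinetics the
markers rely on: the liver index rises within 1 h and liver integrity
collapses by 24 h while brain stays near-intact; and — the subtle one —
the rRNA-marker concentration in the 15–50 nt RF window stays nearly
constant in time.  That steady state requires the strong tRNA protection:
were tRNA cut as readily as rRNA, its end fragments would flood the RF
window early and dilute the markers there at t = 0 but not later.

**Fragmentation sampling.** Per molecule, a Poisson-count of cuts at
uniform random internal bonds; coincident cuts collapse.  The
implementation concatenates all cut positions and molecule endpoints on
one global axis, sorts, and differences — exact integer mass conservation
by construction.  Molecule counts adapt to the cut rate (2 000–400 000
per species, bounded by a total-draw budget) so that lightly cut, short
species are sampled deeply enough for stable window masses while heavily
cut long species stay cheap.  Closed-form expectations (internal
fragments of length l at density `u²(L−l)e^{−ul}`, end fragments
`2u·e^{−ul}`, intact `e^{−uL}`) back the ground-truth labels and the
rate-fitting oracle.

**Fractionation and integrity.** Window mass of a species is its pool
mass fraction times the fraction of its own mass at fragment lengths
inside the window (tRNA window 60–75 nt, RF 15–50 nt, inclusive).  The
integrity proxy is `1 + 9 ×` (pool mass fraction in fragments of at least
half the parent species' length): 10 when intact, 1 when atomised,
strictly decreasing in the cut rate.  It shares only orientation with
electrophoretic RNA integrity numbers; it is not a vendor algorithm.

**Measurement.** Light-channel area = gain × per-nt modification
concentration of the window × injection scale, with multiplicative
lognormal noise (σ = 0.08) and a per-sample injection-scale term
(σ = 0.10) that the UV normaliser is there to remove; the heavy channel
sits at a constant internal-standard level (σ = 0.05) unaffected by
sample load; UV areas split the injected amount into four equal bases
(σ = 0.03).  S/N is the light area over a noisy floor.  RF-window light
areas receive an extra lognormal heterogeneity term (σ = 0.35) emulating
the empirically incoherent behaviour of heterogeneous fragment pools in
that window — this is what keeps the RF fraction an effective negative
control for tissue discrimination.  With all noise at zero the full
ladder returns ground-truth concentrations exactly, up to one constant
per modification branch.

**Rate recovery.** `fit_cleavage_rate` grid-searches (141-point
log-spaced coarse grid, one local refinement) the analytic integrity
expectation against an observed time course; at default noise it recovers
the liver rate to within a few percent.

**What the generator does not emulate.** Modification residues are
assumed uniformly distributed along each molecule, whereas real sites are
clustered; positional structure would change window densities and is left
as a pluggable density choice.  There is no sequence, no secondary
structure protection, no exonucleolytic trimming (the RF steady state
emerges from continued endonucleolytic cleavage alone), and no retention
time drift or isotope-pattern structure in the measurement model.
Passing tests therefore demonstrate that the pipeline's arithmetic, QC
logic and statistics behave correctly under a faithful abstraction of the
study designs — not that the specific kinetic constants describe any real
tissue.

## Problem sizes and determinism

The default study designs are the packaged ones: post-mortem — 2 tissues
× (4 timepoints frozen + 0 h unfrozen) × 4 replicates × 2 windows = 80
measured samples; brain tissues — 3 × 4 × 2 = 24; in vitro — 4 timepoints
× 3 replicates × 2 windows.  Monte-Carlo depth follows the per-species
adaptive rule above.  All randomness flows from a single integer seed
through `numpy`'s `SeedSequence`; repeated runs are byte-identical, and
the acceptance script derives every simulation from its `--seed`
argument.
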