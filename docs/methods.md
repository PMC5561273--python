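# Methods

This note documents the models, defaults and design choices behind
`hostdiscrim`, and what the synthetic benchmark does and does not show.

## Behavioural profiles

An EPG recording yields ~119 behavioural variables per aphid (counts and
durations of stylet-activity waveforms over a 6-hour window). Cleaning
proceeds in the order: imputation, zero-inflation filter, correlation
pruning.

**Imputation.** Proximity-based iterative tree-ensemble imputation with a
median start: each of 3 iterations fits a classification forest (default
300 trees) predicting plant species from all variables, derives the case
proximity matrix (fraction of trees in which two recordings share a leaf),
and replaces each missing cell by the proximity-weighted mean of the
observed values in its column. Observed cells are never altered; a fully
missing variable is an error. The procedure is deterministic given its
seed. The E2 column must be complete (it is the response anchor and is
never imputed).

**Zero filter.** A variable with ≥ 50% zero values is removed (the
boundary case counts as removed). Zeros are counted on the imputed table.

**Correlation pruning.** A single greedy pass in column order: for every
pair with Pearson |r| strictly above 0.80 in which both members are still
present, the later column is dropped. After the pass no surviving pair
exceeds the threshold; every (kept, dropped, r) decision is recorded in the
cleaning report. Which member of a pair is redundant is not identifiable
from the data, so "drop the later column" is fixed purely for
reproducibility. Zero-variance variables cannot enter a correlation and are
kept with a warning. The combined pass is idempotent.

**E2 profile.** Total E2 duration in minutes, validated to lie in
[0, 360] (the recording window).

**LD1 profile.** Fisher LDA of the cleaned variables within one race, plant
species as groups: the first generalised eigenvector of the among-species
scatter against the pooled within-species covariance. A ridge of
`1e-8 · trace(Sw)/p` guards near-singularity; consequently LD1 is invariant
to affine rescaling of any input variable only up to ~1e-5, which is the
tolerance used in tests. The axis sign convention inside `SpeciesLDA`
(largest-magnitude loading element positive) makes a single fit
reproducible, but cannot align axes *across* independently fitted races.
`compute_ld1` therefore (a) flips each race's axis so LD1 correlates
positively with E2 — positive LD1 = acceptance for both races — and (b)
z-scores the per-recording scores within race, since scores from separate
discriminant fits carry arbitrary scale. Both steps matter: without them
the race-mean sum (acceptability) absorbs part of the race-mean difference
(discrimination), because a sign flip swaps the two roles algebraically
and a scale mismatch leaks the difference into the sum. Raw axes are
available via `orient_by=None, standardize=False`.

## Species-level scores

Per (species, race) cell: mean, SD, SE = SD/√n. Discrimination is the MS
minus TP race-mean difference, acceptability their sum; SEs propagate in
quadrature, and the identity `discrimination + acceptability = 2·mean_MS`
holds to machine precision. A species missing one race cell is dropped
with a warning; a race missing entirely is an error. Correlations with
aphid performance (fecundity) use species-level means; Pearson P-values
use the t approximation, Spearman P-values are exact (full permutation
enumeration) for n ≤ 10 and t-approximate above.

## Spectra

Peak lists are binned into half-open 0.2-Da bins anchored at 50 Da, labelled
by left edge (one decimal) with the nominal integer bin = floor(m/z) carried
alongside, since bins are conventionally quoted by integer mass. Binned
intensities are converted to %TIC, which removes any global per-spectrum
intensity scale. Technical replicates of a plant are combined as the mean
of %TIC, renormalised to 100; bins whose replicate CV exceeds 0.5 at mean
%TIC > 0.01 are flagged (never removed) as a concordance report. The
replicate-combination rule is this package's own concretisation — the mean
is the obvious unbiased choice, and the CV flag approximates a
technical-repeatability check; both thresholds are configurable.

PCA (column-centred) provides the overview; plants whose robust z-score
(median/MAD) of score distance on the first two components exceeds 3.5 are
flagged as outliers, never auto-removed. PLS-DA is a NIPALS PLS2 regression
of centred X on one-hot species membership, with VIP scores (mean squared
VIP equals 1 by construction).

## Resampled random-forest ranking

Rows are individual plants; every plant inherits its species' response
draw. Per resample r = 1..R (default 500): draw a response per species from
Normal(mean, SE²), fit a regression forest (default 1000 trees,
mtry = floor(M/3), minimum leaf size 5 — standard regression-forest
defaults), and rank bins by importance with rank 1 = most important and
average ranks for ties. Importance is the total node-impurity (RSS)
decrease attributable to splits on a bin, summed over nodes and averaged
over trees without per-tree normalisation — the regression analogue of
"mean decrease in Gini". Medians over resamples order the bins; IQRs
measure consistency. A master seed spawns per-resample sub-seeds, so runs
are exactly reproducible.

The jack-knife stability analysis deletes one random recording per
species × race cell, recomputes point scores (no SE draw), and refits one
forest per replicate. The forest seed is held fixed across replicates so
that rank variability reflects data sensitivity, not forest randomness
(identical jack-knife datasets give identical ranks, and the zero-noise
limit gives IQR = 0 exactly). Cells of size 1 are an error; species × clone
cells are available via `cell_columns`.

Top-k selection breaks median ties by smaller IQR, then ascending bin
label. Follow-up statistics: OLS R² of the species-level score on the
species-mean %TIC of the selected bins (the design's condition number is
checked; the species count must exceed the bin count + 1), and per-bin
Spearman ρ with Benjamini–Hochberg q-values (constant bins are reported as
missing with a warning). Polar and non-polar fractions are analysed
separately and merged only at top-bin selection.

## Annotation

Molecular formulas (flat element-count strings) are parsed and summed over
a bundled monoisotopic mass table (C, H, N, O, P, S, Na, K). The default
adduct is [M+H]+ (proton mass 1.00727646 Da), appropriate for positive-mode
MALDI with an α-CHCA matrix; [M+2H], [M+Na]+ and [M+K]+ are available
behind the adduct argument. Forward queries report the 0.2-Da bin and the
nominal bin of each adduct; reverse queries return compounds whose adduct
m/z falls inside (or within a 0.1-Da tolerance of) a queried bin, where
integer queries denote nominal 1-Da bins. The bundled compound table holds
the phenylalanine/tyrosine pathway members used in the group comparisons;
users may supply their own CSV.

Group comparisons between species sets (e.g. the three most
*Medicago*-shifted vs the three most *Trifolium*-shifted species) report
log fold change of mean %TIC (base 2 by default; an ε = 1e-6 pseudo-count
is added and logged when a group mean is zero) and an OLS F-test of
log(%TIC + ε) on the group indicator across individual plants, df1 = 1,
df2 = nA + nB − 2 derived from the data.

## Synthetic data generator

The generator emulates the study design: 19 plant species (9 *Medicago*,
10 *Trifolium*), two aphid races with 2 clones each and 8 recordings per
race × species cell, 6 plants per species with triplicate spectra in two
fractions over 50–1000 Da.

Latents: acceptability `a_j ~ N(0, 1)`; discrimination
`d_j ~ N(±1.5, 1)` with genus-dependent sign, so discrimination separates
the genera. Race means `m_MS = (a+d)/2`, `m_TP = (a−d)/2` are stored such
that sum and difference recover `a_j` and `d_j` exactly in floating point.
Per aphid, the latent adds a clone effect (SD 0.2) and individual noise
(SD 0.8); E2 = 360·logistic(latent) minutes, which bounds E2 within the
recording window. Note the logistic's curvature makes the *sum* of E2 race
means depend weakly on |d| — a structural consequence of a bounded
acceptance measure, visible in strongly discriminated species.

The EPG variable block contains ~30% informative variables (linear in the
latent with random slopes, unit noise), ~20% zero-inflated variables (zero
with probability 0.6), 10 near-duplicate pairs (population r ≈ 0.995,
targets of the pruning rule) and pure-noise variables, with optional MCAR
missingness (default 2%).

Spectra: each planted compound k has a true m/z (kept ≥ 2 m/z-jitter SDs
away from bin edges unless `edge_stress` places it exactly on an edge) and
a per-species mean log-abundance `γ·direction·latent + z_kj`, where the
latent is `d_j` for discriminative compounds (both signs), `a_j` for
acceptability compounds, 0 for nuisance compounds, and
`z_kj ~ N(0, sigma_species²)` (default 0.5) is a species-level effect
unrelated to behaviour carried by *every* compound. The z term reflects
that real leaf metabolomes differ among species in essentially every
compound; without it, planted compounds would be the only bins with
species-level structure and would dominate any species-level regression
regardless of response, making specificity untestable. Plants add
lognormal biological noise (CV 0.3), replicates add technical noise
(CV 0.1), per-peak m/z jitter (SD 0.03 Da) and a global lognormal TIC
factor (log-SD 0.5) that %TIC normalisation must remove. Fecundity is
Poisson with log-mean 1.5 + 0.5·race mean.

Within-cell variance components are not reported quantities for this
system; the defaults above are plausible placeholders chosen once, not
estimates, and recovery results should be read as demonstrating that the
machinery works under its assumed signal-to-noise, not as predictions of
field effect sizes. Other simplifications: no isotope patterns or multiple
charging, no ion suppression, MCAR (not informative) missingness, and a
single global TIC factor per replicate.

## Benchmark problem sizes

The end-to-end benchmark in the acceptance tests uses 19 species ×
6 plants with ~198 planted compounds in one fraction, E2-based scores,
R = 50 response draws and 200-tree forests over 10 seeds — sizes at which
the full suite completes in minutes while leaving the planted-signal
recovery unambiguous (discriminative bins reach median rank ≤ 4 under
discrimination responses). The E2 profile is used in that benchmark
because it involves no axis estimation; the LD1 path is exercised
separately by the module tests. At the full 119-variable default the
per-race LDA (≈60 surviving variables against ~150 recordings per race)
is appreciably noisier, which is faithful to the method rather than a
defect of it.

## Known limitations

- Ranks from forests on strongly compositional data (%TIC) inherit
  closure effects: a very abundant compound depresses all other bins'
  %TIC in the species where it peaks.
- With ~19 species, chance alignment between score estimation noise and
  any species-structured bin produces occasional spurious mid-rank
  elevation; the resampling quantifies but cannot remove this.
- The exact-permutation Spearman P is enumerated for n ≤ 10 and can take
  seconds at n = 10.
- PLS-DA VIP is reported for completeness; the ranking inference does not
  depend on it.
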