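# Methods

This note records the models, conventions and open design choices behind
`spectradiet`, in the spirit of a package's statistical documentation: what is
computed, under which assumptions, and what the synthetic data do and do not
establish.

## Study system and scope

The package models the classification of pure plant fractions separated from
rock ptarmigan crop contents: seven taxa (*Betula nana*, *B. pubescens*,
*Empetrum nigrum*, *Vaccinium* spp., *Salix herbacea*, *S. phylicifolia*,
*Dryas octopetala*) and five parts (infructescence, catkin, berry,
stem-with-buds, leaf), of which exactly eight taxon-part combinations occur.
Crop contents are used because the food items are still macroscopically
identifiable, which provides ground-truth labels; fecal samples, mixtures and
digestion effects are out of scope.

## Synthetic spectra

**Generative model.** A replicate spectrum of class *c* is

    y(w) = Σ_j f_j · h_cj · exp(−(w − μ_j)² / 2σ_j²) + b(w) + ε(w)

with band centers μ_j and widths σ_j shared across classes, class heights
h_cj, per-sample multiplicative jitter f_j (log-normal, mean exactly 1,
coefficient of variation `sample_jitter_cv`), one broad random-Gaussian
baseline b(w) per replicate (amplitude uniform in ±`baseline_amplitude`,
center uniform over the grid, width uniform 300–800 cm⁻¹) and iid Gaussian
noise ε (sd `noise_sd`). Replicates of a sample share the jittered heights
and differ only in baseline and noise, mirroring repeated ATR presentations
of one powder. Bands are Gaussian rather than Lorentzian/Voigt: the features
downstream are peak heights, for which the simplest symmetric line shape
suffices.

**Defaults and units.** Grid 4000→400 cm⁻¹ descending at 2 cm⁻¹ (the
instrument resolution of 4 cm⁻¹ does not fix the encoder spacing; 2 cm⁻¹ is a
common export spacing, and operations never assume ascending order);
5 replicates per sample (the protocol took five to ten); 30 samples per class
for the default dataset; jitter CV 0.10, noise sd 0.01 and baseline amplitude
0.05 absorbance units — visible but modest disturbance relative to planted
heights of ~0.05–0.2 after scaling, which we consider realistic for dried,
ground, homogenized material on a maintained ATR unit.

**Planted heights are conventions.** The source material reports *orderings*
of band heights across classes (e.g. oxalate: stems > leaves > all others;
fructose bands present only in berries; cutin: *B. pubescens* catkins >
*B. nana* catkins > rest), not absolute intensities. Heights were chosen to
satisfy every encoded ordering and then rescaled per class so each noiseless
class spectrum has unit Euclidean norm on the default grid. Because every
measured spectrum is vector-normalized before analysis, this equalization
makes the planted cross-class orderings equal the orderings of the measured
normalized features; without it, a class with many strong bands would be
scaled down by its own norm and could invert tight orderings. The profile
library is serializable to YAML and user-replaceable.

**Known mismatches with real data.** The generator does not model: mixture
spectra of several diet items, digestion or fecal matrices, atmospheric CO₂
features (the excised region is generated flat), detector drift across
sessions, water-vapor lines, wavenumber calibration shifts between sample
sets, or correlated (pink) noise. Passing the classification checks on these
data therefore shows the pipeline is correct and that the planted fingerprint
structure is recoverable at the stated noise — not that real crop spectra
reach any particular accuracy.

## Preprocessing

Order is normalize → average → excise. Normalizing each replicate first
weights replicates equally regardless of absolute signal level (the test
suite asserts that the reversed order differs in general). Two normalization
modes exist because vendor implementations of "vector normalization" differ:
`plain_unit_norm` (default) divides by the Euclidean norm;
`center_then_unit_norm` subtracts the mean first. Both pass the suite; all
shipped defaults and reported numbers use the plain mode.

The excision interval [1800, 2500] cm⁻¹ is closed on both ends — boundary
points are removed — which is deterministic and matches the stated "from 2500
to 1800" reading. On the default grid this removes exactly 351 points.

Second derivatives use a Savitzky–Golay filter (default 9-point window — the
standard chemometrics reading of "nine smoothing points" — with quadratic
fit, the minimum order for a second derivative), scaled by the physical grid
spacing (units absorbance·cm²). The output shrinks to interior points: no
padding, because band windows never touch the grid edges. Non-uniform grids
(e.g. after excision) are refused; `resample_uniform` interpolates linearly
to the modal spacing, and resampling is always explicit, never implicit.

Peak search reports local maxima above a topographic-prominence threshold,
sorted by descending height — an automated surrogate for a vendor single-peak
search plus manual inspection.

## Band-aggregate features

The default table has 21 windows reconstructed from the published band
assignments: ranged assignments keep their printed bounds, single wavenumbers
are widened to ±4 cm⁻¹ (one resolution element; a zero-width window is
unusable on a discrete grid). The exact aggregation windows used in the
original analysis are not printed in the main text, so the table is
explicitly user-replaceable via `read_band_table`.

"Absolute peak height" is read as the un-baselined signed maximum of the
vector-normalized absorbance within the closed window — "absolute" contrasting
with baseline-corrected heights in chemometrics usage. A local-baseline-
corrected variant (straight line through the window endpoints) is available
behind a flag.

Two windows overlap by construction (fructose 772–780 and Ca-oxalate
776–784, bands 4 cm⁻¹ apart): features in that region carry cross-talk — a
berry's fructose band contributes to its oxalate-780 feature. Planted heights
keep the oxalate ordering (stems > leaves > berries' leak) intact, but users
replacing the band table should keep this overlap in mind.

## PCA

Covariance-mode (column-mean-centered, unscaled) PCA via SVD — the default of
common spectroscopic workflows, where all variables share absorbance units;
correlation scaling is deliberately not applied. Percent variance explained
is always relative to total variance, so retained components sum to ≤ 100 %.
Signs of scores/loadings are convention-dependent; we fix them by flipping
each loading so its largest-magnitude element is positive, and comparisons in
tests are made on separations and magnitudes, never raw signs.

## Random-Forest models

Two labelings of the same feature table: RFp (5 parts) and RFtp (8 taxon-part
classes). The workflow: deterministic stratified 80/20 split (per class,
`round(0.8·n)` to training, both sides at least one); exhaustive grid search
over mtry × ntree × maxnodes × nodesize (3·3·2·3 = 54 combinations) scored by
mean 10-fold stratified-CV accuracy on the training part; refit on the full
training part with the winner. `maxnodes` caps terminal nodes per tree
(`max_leaf_nodes`), `nodesize` is the minimum samples per terminal node
(`min_samples_leaf`), `mtry` the candidate features per split; values of mtry
exceeding the feature count are clipped and logged. Tie-breaking is not
standard anywhere, so it is fixed deterministically toward the cheaper model:
smaller ntree, then mtry, then maxnodes, then nodesize. Classes are trained
unweighted. One user-visible seed drives generation, split, fold assignment
and forest randomness.

**Metrics.** Overall accuracy with the exact Clopper–Pearson interval (beta
quantiles; lower bound 0 at 0 successes, upper bound 1 at n successes);
Cohen's κ from the marginal-product expected agreement, with the degenerate
all-one-class table defined as κ = 1 when observed agreement is also perfect;
per-class sensitivity (recall), specificity and balanced accuracy — reported
per class because "accuracy" of a single class is ambiguous, and balanced
accuracy is the convention of the usual by-class model summaries. OOB error
is the misclassification rate of majority votes over trees that did not see a
sample; per-tree out-of-bag membership is reconstructed from each tree's
bootstrap seed and verified in the suite against the fitted forest's stored
OOB records. Permutation importance (mean decrease in accuracy) defaults to
the classic per-tree OOB mode — each tree scored on its own out-of-bag
samples before and after permuting one feature — with a whole-forest holdout
mode as an alternative, since the evaluation set for importances is a genuine
ambiguity.

## Problem sizes and determinism

The default dataset is 8 classes × 30 samples × 5 replicates (240 samples,
1200 spectra); the full double tuning (RFp and RFtp, 54 combinations × 10
folds each) completes in a few minutes on one CPU. Tests use smaller
configurations (reduced grids, 3–6 samples per class) except the end-to-end
discrimination checks, which run the full default once and reuse the chosen
hyperparameters across additional seeds. All stochastic tests are seeded;
property-based tests run derandomized.

## Known limitations

- Band windows are a reconstruction; the original aggregation table is not
  public in the main text, so feature values are comparable in structure, not
  numerically, to the original analysis.
- The PCA percent-variance figures on synthetic data (~31 %/20 % for
  PC1/PC2 at defaults) depend on the planted between-class structure and are
  not calibrated to reproduce any particular instrument dataset.
- `find_peaks` on heavily overlapping bands (e.g. the 1700–1750 cm⁻¹ ester
  region) merges shoulders into their neighbors; band-aggregate features, not
  the peak list, are the classification inputs.
- The OOB-membership reconstruction relies on scikit-learn's documented
  bootstrap (n draws with replacement, per-tree integer seed); the suite
  fails loudly if that contract changes.
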