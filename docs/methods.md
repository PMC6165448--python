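# Methods

## Texture features

All 22 texture features are computed on a grayscale image (luma weights
0.299/0.587/0.114, rounded, 256 levels). First-order statistics use
population moments of the raw histogram; kurtosis is raw (normal → 3),
not excess, because only trend direction matters downstream and the raw
form keeps the limiting two-point value at 1.

Co-occurrence and run-length statistics need a quantization depth,
offset and direction convention, none of which is dictated by the
problem; the package fixes:

* **quantization**: 32 uniform levels from 256. For the ~10⁵-pixel ROIs
  this keeps a 32×32 co-occurrence matrix statistically filled;
* **offset** d = 1, directions {0°, 45°, 90°, 135°}, matrix symmetrized;
  features are computed per direction and averaged, which makes the
  vector exactly invariant under 90° rotation;
* **entropy base 2** throughout. IMC1 is a ratio of entropies and hence
  base-invariant; IMC2 keeps the classic natural-log form;
* **ROI**: a central crop covering 60% of each dimension by default, to
  exclude background around the slice.

Because these are conventions, absolute feature values are not
comparable across implementations — only orderings and trends are, and
those are what the tests assert. Degenerate images (zero variance)
yield NaN for correlation/IMC1/IMC2/skewness/kurtosis; such patterns
are rejected from classification with a warning, never zero-filled.

The run-length matrix counts maximal collinear runs per gray level and
length; with N total runs, SRE = (1/N)ΣR/l², LRE = (1/N)ΣR·l²,
GLNU = (1/N)Σ_g(Σ_l R)², RLNU = (1/N)Σ_l(Σ_g R)², RP = N/pixels.
Run-length extraction is implemented directly (line scans per
direction); no installed library provides it. The 13 co-occurrence
statistics are authored here on top of scikit-image's co-occurrence
counting; tests check them against an independent loop transcription of
the original formulas and against scikit-image's own four overlapping
properties.

## Colorimetry

C* = √(a*²+b*²); h = atan2(b*, a*) in degrees wrapped to [0, 360);
ΔE* is the CIE76 Euclidean distance to a configurable reference,
defaulting to the white calibration plate (97.83, −0.45, +1.88).
Recomputing ΔE* from the published class means under CIE76 does *not*
reproduce the published ΔE* column (e.g. 33.12 vs 45.59 for boiled
turkey) — the published ΔE* basis is unstated — so ΔE* is reported
under the documented default and excluded from reference checks.
Likewise the published boiled-pork C*/h pair is inconsistent with its
own a*, b* means (14.35/32.65 recomputed vs 13.02/36.66 printed) and is
excluded. The other four classes agree within 1.5% relative error.

## Spectra

Band intensity is the **window maximum** (Table intensities are
peak-scale, 0.01–0.15 AU; integrals would be an order larger), after
optional linear baseline subtraction anchored at 3800/520 cm⁻¹ (on by
default for measured spectra, off for synthetic tests whose baseline is
exactly zero). Single-wavenumber regions expand to ±8 cm⁻¹ (twice the
nominal 4 cm⁻¹ resolution). The registry of 15 regions plus the 717 and
1083 cm⁻¹ auxiliaries is a CSV data file, editable without code
changes.

Band presence (for the 717 cm⁻¹ marker) requires a local maximum within
±8 cm⁻¹ whose prominence exceeds k× the noise scale (median absolute
successive difference), k = 5 by default — calibrated only by the
requirement that flat noise triggers in ≤5% of cases, which the tests
check by simulation.

The carbonyl/phosphate rule attributes P=O to phospholipids iff
I(1744)/I(1240) ∈ [1.9, 2.3], else to nucleic acids. Note the published
per-class means give ratios 1.31–1.58; only the classes at or below 1.4
(smoked turkey, roasted pork) are used in the reference checks, since
the ratio basis behind the published "≈1.3–1.4 for all samples" summary
is unstated.

## Classification

PNN with equal priors; scores as in the README. Classification is
computed after subtracting the per-query minimum squared distance
(a positive per-query factor that cannot change the arg-max), which
makes the σ→0 limit numerically exact: the rule then reduces to
1-nearest-neighbour, verified against an independent implementation.
Ties break to the first registered class; subset ties to fewer
features, then lexicographic order — fixed constants, not options, so
results are bit-stable.

Normalization is pooled z-scoring over the patterns of the classes
involved. Inside LOO the default recomputes μ, σ from each fold's n−1
training patterns (no leakage); a `pooled` mode normalizes once over
all patterns for the literal single-pass procedure. Both are exposed
and tested; on the synthetic study they agree.

Kernel width: grid {0.05, 0.1, 0.2, 0.5, 1, 2}×√p. The subset search
selects σ by the same LOO accuracy that ranks subsets (one grid pass
per subset); a `nested` policy that re-selects σ per fold by inner LOO
on the training patterns only is implemented for single-subset
evaluation, where its n-fold extra cost is affordable. The exhaustive
search over sizes > 6 (≥376k subsets) requires an explicit `force`
flag.

The LOO core is vectorized: per-feature squared differences and
per-fold inverse variances (leave-one-out mean/variance in closed form)
are precomputed once, so each subset evaluation is one einsum plus one
kernel matrix product per σ — the full ≤3-of-28 search over 90 patterns
takes a few seconds.

## Trends and group comparison

Quadratic least squares per feature over storage day; goodness of fit
is the Spearman correlation of observed vs fitted values, accepted when
|r| > 0.2 (the fitted-values pairing and the magnitude criterion are
the package's choices; observed-vs-day is available behind a flag, and
the signed r is always reported).

Group comparison: one-way ANOVA, then Tukey–Kramer HSD at α = 0.05
using the studentized-range critical value (cached per configuration;
decisions verified identical to statsmodels' implementation, which is
too slow per call for simulation-scale use). The compact letter display
is a greedy insert-and-absorb over groups sorted by descending mean;
sharing a letter is exactly the complement of Tukey significance, which
a property test asserts. When every group is internally constant the
comparison degenerates to exact equality of the constants.

`day_effect_scan` flags a variable when its across-day ANOVA has
p < 0.05 (so its type-I error is calibrated at α, checked on
day-shuffled nulls); the direction of change is the sign of the
last-minus-first day means, with the Tukey first-vs-last decision
reported alongside.

## Synthetic study

The generator encodes the study conditions: five classes × 30
replicates, sampled every 3 days for three weeks.

* **Color**: L*, a*, b* independent normals at the published class
  means/SDs (no covariances are published; a correlation hook exists
  but defaults to identity). C*, h, ΔE* are always derived, never
  sampled.
* **Spectra**: sums of Gaussian bands (FWHM 15 cm⁻¹, a typical
  condensed-phase mid-IR width) at the registry region centers snapped
  to the 4 cm⁻¹ grid (so a noise-free spectrum round-trips its
  amplitudes exactly through the window-max reader), amplitudes drawn
  at the published means/SDs, white noise SD 0.001, grid 4000→500 cm⁻¹.
  Turkey classes add the 717 cm⁻¹ marker (0.020 ± 0.002, comparable to
  the weak 966 band). Storage drift multiplies drifting bands by 1
  until day 10 then linearly to 1 ± 10% at day 20 — the published
  record states direction and significance but not magnitude; ±10% is a
  package default, configurable per band.
* **Images**: a smoothed Gaussian random field (correlation length =
  blob scale) plus horizontal streaks modulates L* around the class
  mean; a*, b* are the class means; Lab→sRGB via the standard D65
  transform. The texture parameters are presets chosen so the
  documented class orderings hold robustly (50/50 seeds in tests):
  boiled pork most homogeneous (highest ASM), smoked pork longest
  structures (highest LRE among pork), boiled turkey noisier than
  smoked (higher SD, hence lower GLNU). Absolute texture values carry
  no meaning; only these orderings do.
* **Scale**: images default to 96×96 px and are generated once per
  replicate (the discrimination analysis has no day dimension; storage
  texture trends are exercised through directly generated feature
  series). Spectra and color cover the full class × day × replicate
  cross. These sizes keep the full suite and the end-to-end analyses in
  the seconds-to-minutes range while leaving every statistical check
  well powered.

What passing tests show — and don't. The generator draws independent
normals per channel and per band; real slices have correlated color
channels, covarying bands, illumination gradients and non-rectangular
regions of interest. Perfect single-feature discrimination of the
synthetic classes therefore demonstrates that the pipeline finds and
exploits planted structure, not that real hams separate that easily;
the published discrimination accuracies (95.5%, 98%, 100%) are not
reproducible without the original images, and no attempt is made to
match them numerically.

## Known limitations

* No slice segmentation beyond the rectangular ROI; no channel-wise
  color texture; no spectral preprocessing suite (ATR correction,
  derivatives) or full-spectrum chemometrics — band intensities only.
* The published ΔE* column and the boiled-pork C*/h row cannot be
  reproduced from the published inputs (see Colorimetry) and are
  excluded from checks rather than fitted.
* Tukey letter displays from the published L* moments split boiled from
  roasted pork, whereas the published table shows all pork classes
  sharing a letter; simulation from the printed moments cannot
  reproduce that shared letter, so tests assert only the turkey split.
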