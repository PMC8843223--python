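# Methods

This note records the models, defaults and numerical choices behind
`ligamentnirs`, and what the synthetic validation does and does not show.

## Measurement model

A dual-detector diffuse-reflectance system is assumed: detector 1 (silicon,
2048 pixels, 350–1100 nm, ~0.37 nm spacing) and detector 2 (InGaAs, 256
pixels, 1000–2400 nm, ~5.5 nm spacing).  Each sample is measured at five
equispaced sites; dark (non-reflective) and white (diffuse reflectance)
standards accompany every record.  Absorbance is

    A(λ) = −log10((S − D)/(R − D)),

computed per wavelength.  Points where the transmittance ratio is ≤ 0 are
carried as an explicit invalid mask; a white standard that equals the dark
standard anywhere is a hard error (zero dynamic range).  Sites are averaged
in absorbance space, after the absorbance transform, because tissue
properties are assumed uniform over the sampled midsection; masked points
are excluded pointwise.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated.

**Reference table.**  12 properties per sample, drawn from a multivariate
normal with the assay means/SDs (water 74.7 ± 5.6 %, wet-weight
hydroxyproline 32.5 ± 7.5 µg/mg, crimp angle 27.1 ± 6.5°, …) and clipped to
physical bounds.  Clipping, not truncation, is used for speed; with all
means several SDs inside the bounds, clipping events are rare and the
marginals stay within sampling error of their targets.  The default
correlation structure has two non-zero couplings: water ↔ wet-weight
hydroxyproline r = −0.8 (dilution: wetter tissue has less organic mass per
wet weight; the magnitude is a design default, the real pair is known only
to be strongly negatively coupled) and wet- ↔ dry-weight hydroxyproline
r = +0.5.  Ligament type has no effect on composition: each sample is
treated as independent ligamentous tissue.

**Spectra.**  True absorbance is a Beer–Lambert superposition of Gaussian
bands, linear in concentration.  Water: five bands at 760, 970, 1190, 1450,
1940 nm, σ = 40 nm, amplitude 0.004 AU per % (≈ 0.3 AU per band at the mean
water content).  Collagen (keyed to wet-weight hydroxyproline): five bands
at 1224, 1643, 1682, 1688, 1874 nm, σ = 25 nm, amplitude 0.009 AU per
µg/mg.  Elastin and proteoglycan (uronic acid) carry token bands scaled to
10 % of the *effective* additive-noise floor — the per-point noise in
absorbance after 5-site averaging and a typical 49-point smoothing window —
so they are genuinely below the pipeline's detection limit.  Crimp angle
and crimp length appear in the reference table but in no band.  Raw counts
invert the absorbance equation exactly:

    S(λ) = D + (R − D) · g · 10^(−A(λ) − b) + ε,

with flat standards (white 60 000 counts, dark 1000 counts plus additive
noise, chosen arbitrary-but-fixed so the dark term is exercised), per-site
gain jitter g ~ 1 + N(0, 0.03), per-site absorbance baseline offset
b ~ N(0, 0.02 AU), per-site concentration jitter (3 %), and additive
detector noise ε with SD 10 counts.

**Noise defaults and why.**  The additive SD of 10 counts (≈ 0.02 % of the
white level) reflects a benchtop instrument co-adding 100 scans per
spectrum: at that SNR, sample-to-sample variation in the feature space is
dominated by composition and low-dimensional scatter artefacts, which is
the regime in which the (deliberately leaky — see below) selection
procedure behaves the way it does on real tissue data.  At substantially
higher pixel noise the feature space acquires hundreds of independent
chance directions and the full-data selection steps can dredge up
cross-validated "signal" for *any* reference variable — a textbook
selection-bias failure mode, not a property of the tissue problem this
generator emulates.

**What the generator does not emulate.**  Radiative transfer and
scattering physics, probe-contact and immersion-fluid artefacts,
wavelength-dependent scatter slopes, instrument drift, non-linear
concentration–absorbance relations, and ligament-type composition
differences.  Passing recovery tests therefore show that the pipeline's
statistics are implemented correctly and behave sanely under a linear
high-SNR model — not that any particular accuracy will be reached on real
spectra.

## Preprocessing

Fixed stage order, asserted in tests: Savitzky–Golay → SNV (optional) →
crop → resample → concatenate.  SG windows are specified in nm and
converted to an odd point count via the detector's median sampling
interval (18 nm ≈ 49 points on detector 1, 58 nm ≈ 11 points on detector
2); derivatives are scaled per nm.  Half a window at each edge is masked
invalid, and cropping is applied after filtering so edge artefacts fall
outside the retained band.  Resampling interpolates linearly onto a grid
starting at the first valid wavelength; output points interpolated across
a masked gap wider than twice the step are masked (a native grid coarser
than the step is not a gap).  Detector features are concatenated without
wavelength deduplication — the detectors overlap around 1000–1100 nm and
each keeps its own labelled features.

The canonical search grid pairs, by index, 4 SG windows per detector
(17.7/40.5/63.3/86.1 nm on d1, 57.7/104.7/151.7/198.7 nm on d2) with
3 derivative orders, 2 SNV settings and 4 crop options (three printed
ranges per detector plus the full valid range; the d2 range starting at
900 nm is clipped to the detector's 1000 nm limit), giving 96
configurations — the pairing is the only construction consistent with that
count.  Second-derivative configurations are enumerated first so the first
config is the known-optimal water/collagen pipeline.  The default resample
step is 2.5 nm; the reduced 12-config grid used for quick searches and the
validation runs uses 6.5 nm, which yields ≈ 230 concatenated features for
the widest crops, the scale of the full study's wavelength counts.

## Model construction

Each reference variable is standardized once, globally, before model
construction (ddof = 1).  The selection chain is:

1. **Variance filter** — reject floor(0.10 · p) lowest-variance features;
   ties reject the lower wavelength first.
2. **Univariate selection** — keep ceil(0.875 · p′) by the F statistic of
   the per-feature simple regression (monotone in |r|, so p-value or |r|
   would rank identically); ties keep the lower wavelength.
   Floor-for-reject, ceil-for-keep is the rounding pair consistent with
   "reject"/"keep top".
3. **Latent variables** — 5-fold CV over 1..20 components, taking the
   smallest count whose mean CV RMSE is within one standard error of the
   minimum.  Exact RMSE ties never occur in floats; the one-SE rule is the
   standard realization of "prefer the simpler model on a near-tie".  It
   matters: for a response unrelated to the spectra the CV curve is flat
   noise, a strict argmin picks an arbitrary component count, and a large
   count hands the subsequent elimination step enough flexibility to
   overfit the (full-data) selection leak into the final cross-validation.
4. **Backwards elimination** — at the fixed component count, repeatedly
   drop the feature with the smallest |PLS coefficient| (refit each step;
   coefficient ties drop the higher wavelength, so duplicated features
   resolve to the lowest-wavelength copy), down to the component count;
   the retained set is the step with minimal 5-fold CV RMSE along the path
   (one fixed seeded partition; RMSE ties, within 1e−9 relative, resolve
   to fewer features).
5. **Evaluation** — 10-fold CV repeated 10 times with randomized seeded
   splits, model refit per training fold; per-fold explained variance,
   Pearson r, R² and RMSE; summaries are medians over the 100 fold records
   with percentile-bootstrap CIs (1000 resamples of the median, 2.5/97.5
   percentiles).  A fold with constant held-out y records NaN correlation
   metrics and is excluded from medians.

Steps 1–4 run once on the full data before the final cross-validation, so
fold metrics share information with selection.  This mirrors the evaluated
procedure as published; it is documented rather than corrected, and the
generator's validation shows its consequences directly (see below).

PLS is single-response NIPALS on mean-centered, unscaled data — derivative
spectra are already commensurate across wavelengths, so per-feature
scaling would only amplify dead regions.  For one response each component
is available in closed form; the implementation returns the coefficient
path for all 1..a components from a single decomposition, which is what
makes the per-step refits of backwards elimination and the per-component
CV curves cheap.  If the y-residual is numerically exhausted the
coefficient path freezes (a zero response yields an all-zero model);
exhausting the rank of X raises.

The best configuration per property is chosen by the highest median
cross-validated explained variance, `1 − Var{y−ŷ}/Var{y}` — offset-
invariant, unlike R², and the quantity reported by the summary figure
style of output.

## Validation under the generator's conditions

The acceptance suite runs the full search (reduced grid, 10 joints, seeds
1–5) for four properties.  Across seeds, median cross-validated explained
variance is ≈ 0.99 for water and wet-weight hydroxyproline, and ≈ 0.02 for
crimp angle and elastin; the recovered water models place (median) 3 of
their top-5 |coefficient| wavelengths within 50 nm of an injected water
band.  Occasional single-seed excursions of the non-encoded properties up
to EV ≈ 0.6 are the expected signature of the procedure's selection
leakage at n = 50 and are why the acceptance checks aggregate by median
over the seed set.

## Known limitations

- The selection leakage discussed above means reported CV metrics are
  optimistic for small n; a flag for fold-wise standardization exists, but
  fully nested selection is deliberately out of scope.
- The univariate and variance filters assume a dense, informative grid;
  tiny feature sets (p ≤ 10) make the floor/ceil counts coarse.
- The resample step bounds feature counts; very fine steps on detector 2
  interpolate between native points without adding information.
- Bootstrap CIs of a median on 100 fold records are discrete; intervals
  are clamped to bracket the sample median.
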