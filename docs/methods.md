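# Methods

## The measure

Brain entropy (BEN) here is an image-domain statistic: the Shannon entropy
of the 256-bin pixel-intensity distribution of an activation overlay after
segmentation has restricted it to meaningful pixels,

    H = − Σ_i p_i log2 p_i ,  p_i = n_i / N ,  i ∈ {0..255},

with 0·log 0 = 0. H ∈ [0, 8] bits; BEN = H / log2(256) ∈ [0, 1]. It is
**not** the time-series (sample/approximate) entropy of BOLD signals — the
input is a rendered ICA spatial component, one scalar intensity per pixel.

Normalization by log2(256) = 8 is a modelling choice: subject-level values
in the literature this targets lie in [0, 1], far below the 8-bit maximum,
and division by the maximum attainable entropy is the minimal hypothesis
consistent with that scale. Raw bits are always reported alongside
(`entropy_bits` columns, `normalize=False` model flag, `--no-normalize`)
so the choice can be audited.

## Segmentation

Pixels are classified to the nearest of five reference colors in Euclidean
RGB distance. Default profiles are maximally separated:
background (0,0,0), white (255,255,255), grey (128,128,128),
blue (0,0,255), red (255,0,0); they are user-overridable per dataset
(`--profiles name,R,G,B` CSV) because real renderers differ. Ties are
broken by the fixed class order background < white < grey < blue < red,
purely for reproducibility — with the default palette ties require exactly
equidistant integer pixels and essentially never occur.

White, grey and blue pixels are retained; background is excluded (pixels
outside the head would otherwise dominate the histogram and depress the
statistic's sensitivity), and red is removed as artifact. Removal is
idempotent and leaves the per-class pixel counts untouched as an audit
record. Retained pixels become intensities via ITU-R BT.601 luminance,
round(0.299 R + 0.587 G + 0.114 B), the standard 8-bit convention
(half-up rounding, clamped to [0, 255]).

A subject's BEN is the arithmetic mean over their configured number of
images (default two — the two best-matched sequential component
renderings). Which two images represent a subject is an upstream, partly
manual decision; this package takes the images as given. A subject with an
image whose segmentation retains nothing is flagged excluded and dropped
from group statistics (with the reason logged), not an error.

## Synthetic generator

The generator emulates the *output* of an fMRI ICA pipeline, not the
physics: an elliptical brain (semi-axes 0.42·H, 0.38·W) of grey tissue with
smooth white-matter regions (top-k pixels of a Gaussian-smoothed random
field; default fraction 0.25), blue activation blobs confined to the lower
third of the ellipse ("occipital" — cosmetic, since entropy is
location-invariant), and red speckle elsewhere. Class fractions are exact
by construction (top-k selection), and every image carries its ground-truth
label grid.

Entropy is driven by `intensity_heterogeneity`: i.i.d. Gaussian RGB noise
(per-channel SD = the parameter) added to non-background pixels. Noise
vectors are rescaled so their norm never exceeds 40% of the minimum
inter-reference-color distance (≈88 for the default palette, against a
flip margin of ≈110 including rounding), so the intended class of every
pixel survives nearest-color classification exactly — the property the
segmentation round-trip tests rely on. At zero heterogeneity each retained
class contributes a single intensity (white 255, grey 128, blue 29), so a
single-retained-class image has BEN exactly 0; the default multi-class map
has a floor of ≈0.16 from the class mixture alone. `white_matter_fraction`
exists (beyond the core geometry knobs) precisely so that single-class
degenerate configurations are expressible.

Mean BEN is empirically monotone non-decreasing in the dispersion (checked
at curve-build time; a violation raises). Calibration to a target BEN
estimates the dispersion→mean-BEN curve by Monte Carlo on a 13-point grid
(30 maps/point, seeds derived from the config seed), takes the running
maximum to absorb residual jitter, and inverts by interpolation;
`calibrate_heterogeneity` refines by bisection with fresh 50-map
evaluations to a ±0.02 tolerance. Targets outside the achievable range
raise a calibration error naming that range. The curve is cached per
configuration.

Cohorts: default ADHD group n=25 (20M/5F, ages 20–50, BEN 0.56 ± 0.14) and
control n=19 (8M/11F, ages 18–46, BEN 0.64 ± 0.11); a flag switches the
control group to the as-recruited composition (n=20, 8M/12F) for designs
without the post-hoc exclusion. Gender counts are exact; ages and
per-subject BEN targets are truncated-normal draws (ages truncated to the
group range, BEN targets to the generator's achievable range — the
truncation bias at these parameters is < 0.002). Each subject's images are
generated at the dispersion interpolated from the curve for their target.

What the generator does **not** emulate: real tissue texture and partial
voluming, renderer-specific colormaps, spatial autocorrelation of noise,
registration error, or any 4D/ICA step. Passing tests therefore certify
the measurement and statistics machinery on images with known structure,
not claims about fMRI physics; on real data the segmentation profiles and
the normalization are the components to validate first.

## Statistics

* **t-test** on BEN: pooled-variance by default (the common statistical
  package default), Welch available.
* **Mann–Whitney U** on age and BEN: U of the first (ADHD) sample, normal
  approximation with tie correction, no continuity correction, two-sided
  p. Z is negative when ADHD values run lower.
* **Pearson χ²** on the gender×group 2×2 table **without** Yates
  correction — [[20,5],[8,11]] gives 6.699, the value a continuity
  correction would not reproduce. A zero margin raises a degenerate-table
  error.
* **Phi** is the Pearson correlation of the coded binary variables;
  |phi| = sqrt(χ²/N) exactly (property-tested to 1e-10). Its p-value uses
  the correlation t-test with N−2 df (which is why the same table yields
  p = 0.010 under χ² and p = 0.009 under the correlation test).
* **Point-biserial** BEN–group correlation, p via t = r√(n−2)/√(1−r²).
* Signs of phi and point-biserial depend entirely on the coding; the
  default (male=1/female=2, control=1/ADHD=2) is explicit configuration,
  chosen so a male-dominated, lower-entropy ADHD group yields negative
  correlations.
* All p-values are two-sided.

The printed summary table shows Mann–Whitney Z for the age and BEN rows and
χ² for gender, with the t-test and correlations reported beneath — both
families are always computed, since the two-group comparison of a
continuous outcome is legitimately done either way.

Power at the study design (0.56 ± 0.14, n=25 vs 0.64 ± 0.11, n=19):
analytic power uses the noncentral t with df = n1+n2−2 and noncentrality
(μ1−μ2)/(s_p·√(1/n1+1/n2)) with s_p the pooled SD — the denominator the
pooled test actually uses; this agrees with vectorized Monte-Carlo
rejection frequencies to well under 0.03 at 2000 replicates (power ≈ 0.52,
i.e., the published design is underpowered for its own effect size, which
is why a single synthetic cohort will not always reproduce a significant
BEN difference).

## Numerical choices and problem sizes

Default maps are 128×128 (≈8,000 retained pixels — entropy estimation bias
(K−1)/(2N ln 2) < 0.01 bits); tests use 64×64 where only mechanics matter.
Histogram bins are 0–255 (1-based intensity labeling maps onto the same
256 levels). Entropy sums run over occupied bins only and are floored at
exactly 0 to absorb round-off; the uniform 256-level histogram evaluates
to exactly 8.0 in double precision. The calibration curve uses 30
maps/grid point; verification oracles use 50-map Monte Carlo. Test-suite
Monte-Carlo sizes (100-map segmentation sweeps, 50-subject-per-group
cohorts, 2000-replicate power runs) keep the full suite under a minute on
one core while holding Monte-Carlo standard errors a factor of a few below
the tolerances they check.

## Known limitations

* The nearest-color rule is a declared substitute for whatever
  thresholding a particular renderer implies; with overlapping or
  gradient colormaps it needs per-dataset profiles.
* Normalization by 8 bits is a hypothesis (see above); comparisons across
  studies using a different intensity support are not scale-free.
* The subject aggregate assumes the two images are exchangeable
  measurements of one underlying state; no weighting by retained pixel
  count is applied.
* Mann–Whitney p-values use the normal approximation (appropriate for the
  n≈20–25 groups here), not the exact distribution at very small n.
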