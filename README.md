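# benmap

Shannon brain-entropy (BEN) analysis of rendered ICA component activation
images, with a calibrated synthetic cohort generator and the full two-group
(ADHD vs control) statistical battery.

## The problem

Resting-state fMRI studies of brain complexity often summarize a subject's
functional activity by the entropy of an activation image: an ICA spatial
component rendered on anatomy, where white/grey pixels are brain tissue,
blue marks occipital (visual) activation, and red is artifact signal. Lower
entropy means a more regular, less complex intensity distribution — a
pattern reported in ADHD relative to healthy controls.

For an image restricted to its meaningful pixels, brain entropy is

```
BEN = − Σ_{i=1..256} p_i log2 p_i ,     p_i = n_i / N ,
```

the Shannon entropy of the 256-bin pixel-intensity histogram (`n_i` pixels
at intensity `i`, `N` retained pixels), in bits ∈ [0, 8], reported both raw
and normalized by log2(256) = 8 to a dimensionless value in [0, 1]. The
pipeline is:

1. **Color segmentation** — classify every pixel to the nearest of five
   reference colors (background, white, grey, blue, red; Euclidean RGB
   distance, ties broken by fixed class order), keep white/grey/blue.
2. **Artifact removal** — red pixels never enter the histogram.
3. **Entropy** — BT.601 grayscale of the retained pixels → 256-bin
   histogram → Shannon entropy; a subject's BEN is the mean over their two
   component images. Subjects whose segmentation retains nothing are
   excluded, not fatal.
4. **Group statistics** — pooled/Welch t-test on BEN, tie-corrected
   Mann–Whitney Z on age and BEN, Pearson χ² (no continuity correction) and
   phi on the gender×group 2×2 table, and the BEN–group point-biserial
   correlation.

A seeded synthetic generator produces component images with known
ground-truth classes and cohorts whose subject-level BEN distributions are
calibrated to prescribed mean ± SD targets, so the whole pipeline is
testable without any imaging data.

## Worked example

```python
import benmap as bm

cohort = bm.generate_cohort(bm.CohortGenConfig(seed=1))   # 25 ADHD / 19 control
results = bm.BrainEntropyModel.from_cohort(cohort).fit()
print(results.summary())
```

```
Brain-entropy analysis: 44 subjects, 88 images analysed

Group comparison (ADHD vs control)
==========================================================================
characteristic        ADHD (n=25)     control (n=19)     Z/chi2        p
--------------------------------------------------------------------------
age                   34.90 ± 7.34    30.52 ± 6.53        2.073    0.038
gender (male/female)  20/5            8/11                6.699    0.010
brain entropy (BEN)   0.57 ± 0.13     0.66 ± 0.09        -2.026    0.043
--------------------------------------------------------------------------
t-test on BEN (pooled, df=42): t = -2.571, p = 0.014
BEN-group point-biserial: r = -0.369, p = 0.014
gender-group phi: r = -0.390, p = 0.009
==========================================================================
```

The cohort was generated at BEN targets 0.56 ± 0.14 (ADHD) and 0.64 ± 0.11
(control); the fitted group means (0.57, 0.66) recover them within sampling
error, the ADHD deficit is significant (t = −2.57, p = 0.014), and the
gender table (20/5 vs 8/11) gives χ² = 6.699, phi = −0.390 — exact
functions of the counts. Negative signs follow the documented default
coding (male=1/female=2, control=1/ADHD=2).

The same analysis runs on real component images exported from any fMRI
toolchain via `bm.BrainEntropyModel.from_csv("subjects.csv")`, where the
CSV has columns `subject_id,group,age,gender,image_1,image_2` pointing at
PNG renderings, or from the shell:

```bash
benmap generate --outdir fixtures --seed 3          # synthetic PNGs + CSV
benmap analyze --mode from-images --table fixtures/subjects.csv --outdir out
benmap analyze --mode synthetic --seed 3 --outdir out   # one-shot
```

Outputs per run: per-image and per-subject BEN CSVs, a group-comparison
CSV/JSON report, a plain-text summary, indexed label-map PNGs for
segmentation audit, the resolved YAML config, and a log listing retained
pixel counts and exclusions.

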