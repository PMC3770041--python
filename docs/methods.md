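# Methods

## Scope and model

`gliomorph` reproduces the analysis pipeline of a nuclear-morphometry
study of diffusely infiltrating gliomas: three groups — non-neoplastic
control brain tissue (CG, n = 10), low-grade glioma (LGG, WHO II,
n = 14) and high-grade glioma (HGG, WHO III–IV, n = 16; 3 anaplastic
astrocytoma, 13 glioblastoma) — each case contributing five high-power
fields and 100 selected nuclei. Because no image data from such studies
is deposited, the input side is a synthetic-cohort simulator whose
generative parameters are calibrated to the published group summary
statistics (`gliomorph.reference`); every downstream stage is then
testable against exact per-nucleus ground truth.

## Synthetic cohort generator

**Shape model.** A nucleus outline is a radial-Fourier perturbed
ellipse: `r(θ) = s(θ)·(1 + Σ_{k=2..6} a_k cos(kθ + φ_k))`, with `s(θ)`
the ellipse radius for the group's aspect ratio and `Σ a_k` equal to
the `irregularity` parameter, drawn as Dirichlet-weighted amplitudes
with uniform phases. Keeping the total amplitude below 0.5 guarantees a
positive radius, hence star-shaped, simple outlines; harmonics 2–6
emulate lobulated pleomorphic nuclei without self-intersection (k = 1
would only translate the centroid). Polygons carry 96 vertices and are
rescaled so the shoelace area matches the drawn target to < 0.1%. All
ground truth (area, perimeter, moment axes via exact polygon second
moments, roundness) is analytic.

**Sampling hierarchy.** Per case: mean nuclear area ~ truncated
Normal(group mean, group SD) and placement density ~ truncated
Normal(group density, density SD) — the published SDs are between-case
SDs of per-case means, so they parameterize this level. Per field: a
field-level mean area ~ truncated Normal(case mean, `field_cv` × case
mean), a nucleus count ~ Poisson(density × field area), and nucleus
areas ~ truncated Normal(field mean, `within_sample_cv` × field mean).
Truncation is redraw-until-positive; at the default CVs the truncated
mass is negligible (< 0.1%), so drawn means are essentially unbiased.

**Defaults and why.** Nucleus-level spread is not published;
`within_sample_cv` defaults to 0.30 for tumours and 0.15 for controls,
qualitatively matching the wider tumour area distributions. The
field-level CV (`field_cv`) is 0 for controls and 0.15 for tumours:
infiltrating gliomas are regionally heterogeneous, so pooling a case's
fields yields a mixture of normals rather than one normal — this is the
mechanism behind the non-Gaussian tumour area distributions. Aspect
ratios (≈ 1.5, SD 0.15) follow the published MAJX/MINX ratios;
irregularity rises with grade (CG 0.10, LGG 0.16, HGG 0.20), which
drives the negative roundness–grade correlation. The field is
346 µm × 260 µm (≈ 0.09 mm², a typical 400× digital-camera field) at
0.25 µm/px; the source study does not state its field geometry, so
absolute density reproduction is conditional on this configurable
choice. With it, a control field holds ~100 nuclei.

**Placement.** Nuclei are placed by rejection sampling with a minimum
inter-boundary gap of one pixel and a cap of 1000 attempts per nucleus;
at high-grade densities (~24% area coverage) a handful of nuclei per
cohort hit the cap and are dropped with a warning (density saturation).
Pixel membership is pixel-center-in-polygon, 0-based indices, x along
columns, physical origin at the top-left pixel center. Rasters are
uint16 label images, background 0.

**What the simulator does not emulate:** H&E colour/texture, staining
variation, focus blur, touching or overlapping nuclei, vasculature, and
segmentation error. Passing recovery tests therefore validates the
measurement and statistics layers on cleanly separated nuclei, not
robustness to real-world segmentation noise.

## Measurement

Area is the pixel count × pixel area. Axes are the moment-equivalent
ellipse axes (exact for ideal ellipses, rotation-stable; users
comparing against Feret-diameter tools should expect small systematic
offsets). The perimeter estimator is the 0.5-level marching-squares
contour smoothed by a circular moving average over five contour points:
the naive boundary-pixel count overestimates circle perimeters by up to
~27%, Crofton-style multi-directional estimators still miss the
digitized-disk roundness band [98, 102] at radii 10–13 px under
worst-case sub-pixel offsets, while the smoothed contour stays within
1% of the true circumference over radii 10–100 px. The cost is corner
rounding on right-angled shapes (a 10×10 px square reads ≈ 36.2 µm
instead of 40 µm); nuclei have no sharp corners, so the disk
calibration takes precedence. A single-pixel region returns the
smoothed unit-pixel diamond, 2√2/5 ≈ 0.566 × the pixel pitch.
Degenerate regions (< 3 px, collinear, disconnected) raise typed errors
and are excluded from shape records while still counted in ND and %TNA.

Selection rules make the human protocol deterministic: fields ranked by
nucleus count (ties to the lower field id), nuclei filtered to
`separated` (no 8-adjacent foreign label) and not `border_touching`,
ranked by area descending. Taking the *n* largest is a size-biased
proxy for "relatively larger in size" and inflates per-case mean NA
relative to the population mean — a deliberate, documented property of
the protocol being emulated. %TNA uses all nonzero pixels (whether the
source protocol used all or only selected nuclei is unstated); ND is
computed per field and then averaged, not pooled.

## Statistics

Pairwise group comparison is the unpaired pooled-variance Student
*t*-test, two-sided, df = n₁+n₂−2, computable directly from printed
(mean, SD, n) cells; this choice — not Welch — reproduces the published
P values (e.g. the nuclear-area LGG/HGG cell is 0.0042 pooled vs
~0.0035 Welch). Welch is available as an option. SDs use the n−1
denominator throughout. Grade correlation is Pearson's r with the exact
t-based P on n−2 df, controls coded grade 0, plus an OLS line. The
raw-vector t-test path computes summaries and calls the
summary-statistic routine, so the two paths agree to machine precision
by construction. No multiple-testing correction is applied (matching
the reference analysis); with 7 parameters × 3 pairs this inflates the
family-wise error rate, a documented limitation. The published grade
correlations (r ≈ 0.7–0.83, −0.42 for roundness) depend on the real
per-case joint distribution, which group summaries do not determine;
the package asserts only their signs on synthetic cohorts.

## Area distributions

Histograms use uniform left-closed bins, default width 5 µm²
(configurable; the source figures' binning is unstated). The Gaussian
overlay for a group is `n·(Φ((b_hi−μ)/σ) − Φ((b_lo−μ)/σ))` per bin with
the group's mean and SD and n = 100 — peak height scales as 1/σ, which
yields the CG > LGG > HGG peak ordering directly from the published
SDs. The deviation-from-Gaussianity score is `√n × D`, with D the
Kolmogorov–Smirnov distance against a Normal fitted to the same data:
the raw distance shrinks as 1/√n and tumour samples carry several times
more nuclei than controls, so the unscaled statistic would be
sample-size-confounded; the scaled version is asymptotically n-free
under the null. The reported P value uses the Lilliefors correction for
estimated parameters and is labelled approximate. Deviation scores are
computed on all measured separated, non-border nuclei rather than the
100 largest: the size-biased selection truncates the lower tail for
every group and would mask the group contrast.

## Problem sizes and determinism

All randomness flows from one `numpy` `Generator` seeded by the config,
so cohort regeneration is reproducible and rendered TIFFs are
byte-stable. The test suite runs reduced cohorts (2 cases per group,
120×100 µm fields) for structural checks and the full reference-scale
single-group cohorts (16 HGG / 10 CG cases, five 346×260 µm fields at
0.25 µm/px) for the stochastic recovery checks; the qualitative
tumour-vs-control deviation ordering uses 173×130 µm fields over three
seeds. The recovery tolerance on the high-grade grand mean area (±4 µm²
at n = 16, between-case SD 13.48) is ≈ 1.2 standard errors, so it is
inherently seed-sensitive; the acceptance script accepts any seed and
recomputes everything from scratch.

## Known limitations

- Inputs are already-labelled rasters; no segmentation of real stained
  slides is attempted or claimed.
- Synthetic absolute values of MAJX/MINX/NP/NR are consequences of the
  shape model, not calibrated targets; only area and density are
  calibrated to the published group parameters, so shape-parameter
  comparisons are checked for ordering/sign, not magnitude. In
  particular the measured roundness of smooth synthetic outlines
  (~85–95) sits well above the published ~60–66, which reflects the
  jagged boundaries of manually outlined real nuclei.
- Reports are CSV tables; no plot rendering is bundled.
- The grade mixture within HGG (3:13 grade III:IV) does not modulate
  generative parameters per grade — per-grade parameter breakdowns are
  not published.
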