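# Methods

This note documents the models and procedures `gliaphen` implements, the
parameters that matter, what the synthetic generators do and do not emulate,
and the design choices made where the design was genuinely open.

## 1. Marker segmentation

### Phansalkar local threshold

Phenotype (and optionally glial) marker channels are binarized with the
Phansalkar local adaptive threshold. The image is first normalized to [0, 1]
by its **global maximum** (rather than a fixed bit depth), which makes
floating-point synthetic fields and 8/16-bit TIFFs behave identically and
renders the mask invariant under global positive rescaling of intensities.
Pixel (x, y) is foreground iff its normalized value exceeds

    T(x, y) = m (1 + p e^(−q m) + k (s / r − 1)),

with m, s the mean and population standard deviation of the normalized image
over a **circular window** of radius ⌈radius_fraction · width⌉ pixels
(mirror padding at borders). Defaults: `radius_fraction = 0.05`,
`k = 0.25`, `r = 0.5`, `p = 2`, `q = 10` — the de-facto constants of the
widely used auto-local-threshold implementation; all four are exposed in
config. On a uniform region (s = 0) the formula reduces to
`m (1 + p e^(−q m) − k)`, so a uniform normalized value of 0.5 yields
T ≈ 0.3817 and is entirely foreground; a normalized background below ~0.21
yields T > m and stays background.

The windowed mean and variance are computed by FFT convolution of the
mirror-padded image with a disc kernel (variance clipped at zero to absorb
convolution round-off, ~1e−9 relative). The test suite checks the result
pixel-for-pixel against a naive per-pixel double-loop oracle that enumerates
each window explicitly; on continuous-valued images the two agree exactly
because a threshold tie has probability zero.

An all-zero image thresholds to all-background by definition (not an error).

### Nucleus detection

The protocol this package models specifies the colocalization rule but not
the nuclear segmentation method, so the default is the simplest defensible
pipeline: optional Gaussian denoising, global Otsu threshold, 8-connected
component labelling, physical-area filter (default 20–500 µm², configurable;
the filter is expressed in µm² so it is calibration-aware), and an optional
distance-transform watershed for touching nuclei (off by default — the
synthetic generator plants non-overlapping nuclei, and splitting is a
segmentation concern tested separately). Phansalkar-on-DAPI is available as
a config alternative; neither is asserted to be the original choice.

## 2. Nucleus-anchored phenotyping

For each detected nucleus the **overlap fraction** is
|nucleus pixels ∩ marker mask| / |nucleus pixels| — pixel-count, computed
over the nucleus pixel set only, with no perinuclear dilation (the
classification is anchored on DAPI-positive objects). A nucleus is glial iff
the fraction meets the marker-specific closed bound: **≥ 0.70 for IBA1,
≥ 0.40 for GFAP**. Phenotype positivity applies the same rule to the
phenotype-marker mask, restricted to glial nuclei.

The phenotype-positivity bound has no published numeric value; the package
default is **0.25 with a closed bound**, chosen for consistency with the
glial rule and because a nonzero bound resists single-pixel noise. It is
surfaced in every config and report. Whether the original colocalization was
pixel-count or intensity-weighted is likewise unstated; pixel-count is
implemented and the alternative is noted here.

Densities are `count / region_area_mm2` exactly, with the region area taken
from the supplied region mask (or the full field) via `pixel_size_um²`.
On-nucleus mean intensities (e.g. C3 on GFAP nuclei) are arithmetic means of
the channel over each glial nucleus pixel set; a field with zero glial
nuclei reports a missing value, never zero. Technical replicates (1–4 per
animal) are averaged arithmetically per animal before statistics — the
two-stage stand-in for the animal-level random intercept (§4).

## 3. PET quantification

SUV(x) = C(x) / (dose / weight), with activity concentration in kBq/ml,
dose in kBq, weight in g, and the standard 1 ml ≡ 1 g density convention.
Decay correction is assumed applied upstream: a single reconstructed 30-min
frame is quantified, and VOIs are inputs (atlas registration is out of
scope).

The reference is the mean SUV of the **lowest quartile** of cerebellar
voxels, operationalized as the ⌈n/4⌉ smallest under a stable ascending sort
— unambiguous on small masks, and by construction insensitive to inflation
of high-uptake (skull-adjacent) voxels. SUVR_Q1 = mean VOI SUV / reference,
so it is exactly invariant under global rescaling of the volume. A zero
reference (uniformly zero cerebellum) is an error: the ratio is undefined.

Note that with voxel noise the Q1 reference sits slightly below the planted
cerebellar mean (it averages the lower tail), biasing noisy-phantom SUVR
upward by a few percent; at zero noise planted ratios are recovered exactly.

## 4. Cohort statistics

Outcomes are modelled on the natural-log scale. The transform is
ln(value + shift) with shift = 10 **only** for the C3 mean-intensity outcome
and 0 otherwise. With shift 0, zeros are handled by policy: `error`, or the
default `half_min`, which substitutes half the smallest positive value and
logs the substitution loudly.

The original analysis fit mixed models with animal random intercepts and
AIC-guided interaction selection in SAS. Here that is replaced by a
**two-stage estimator**: average technical replicates per animal, then a
two-sample contrast of log-scale group means with the pooled standard error

    SE = s_p √(1/n₁ + 1/n₂),  s_p² pooled over both groups.

With balanced replicates this reproduces the random-intercept model's fixed
-effect point estimate; full REML adds nothing at these group sizes and
would pin the package to a specific solver. GMR = exp(difference), 95 % CI
= exp(difference ± c·SE), two-sided Wald p from the same reference
distribution — so the CI excludes 1 exactly when p < α (duality holds cell
by cell by construction).

The critical value c defaults to the **Student-t quantile on n₁+n₂−2 df**.
Under the generator's log-normal model the t-interval has exact 95 %
coverage at any group size, whereas the normal 1.96 convention covers only
≈ 93 % at n = 8/group; the normal option is available via `use_t=False` for
parity with the large-sample convention. A group with fewer than two animals
yields a missing result carrying a reason, never an estimate.

**FDR.** Benjamini–Hochberg q-values follow the step-up definition
literally: q₍ᵢ₎ = min over j ≥ i of min(1, m·p₍ⱼ₎/j), implemented with the
same arithmetic (`m·p/j`) so a brute-force enumeration of the definition
matches bit-for-bit. The correction family is all region × timepoint cells
within one sex × outcome, matching the per-sex modelling; the family
definition is config-exposed because it is not uniquely determined. A
`collapse: by_cell | by_region` switch reproduces the overall-by-region
display used when a timepoint interaction is absent, without guessing any
model-selection path.

**Inclusion filter.** An exposed animal enters the cohort iff the arithmetic
mean of its modified-Racine scores over (0, 40] min is ≥ 2.5 (closed bound:
a mean of exactly 2.5 is included).

## 5. Synthetic generators: what they emulate

**Fields.** Non-overlapping nuclear discs (rejection sampling, ≤ 10·n
attempts, then a `PlacementError`) on a 512 × 512 px field at 0.325 µm/px —
a typical 20× widefield calibration; the acquisition magnification is known
but the original pixel pitch is not, so the default is documented and
configurable, not inferred. Nucleus radius defaults to 10 px (6.5 µm
diameter) so default nuclei pass the default area filter. The glial marker
covers exactly ⌈target · area⌉ pixels of each glial nucleus (a contiguous
cap, so the planted overlap fraction is known and ≥ the target), plus a
3-px perinuclear ring and 2–4 linear processes that are explicitly confined
to extranuclear pixels — they mimic cytoplasmic IBA1/GFAP morphology without
perturbing any nucleus's overlap fraction. Counts follow
n_glial = round(glial_fraction · n), n_phenotype = round(phenotype_fraction
· n_glial), so phenotype-positive ⊆ glial ⊆ all always holds. Intensities
are background 0.1 / foreground 1.0 with additive Gaussian noise clipped at
zero; **SNR is defined as (foreground − background)/noise_sd**, so
noise_sd = 0.18 gives the SNR ≈ 5 regime used in the recovery benchmarks.
Not emulated: tissue texture, point-spread function, Poisson photon
statistics, illumination gradients, overlapping nuclei. Passing tests
therefore demonstrate correctness of the thresholding/colocalization logic
and its noise robustness in this regime — not segmentation performance on
real tissue.

**PET phantoms.** Disjoint spheres on a deterministic grid inside a
64 × 64 × 48 volume at 0.78 × 0.78 × 0.80 mm voxels (the reconstruction
geometry of the modelled scanners), one sphere per named region plus a
cerebellum at the reference uptake; default dose 37 MBq / 250 g puts the
reference at SUV 1. No scanner physics, attenuation or partial-volume
effects.

**Cohorts.** log value = ln(baseline) + 1[exposed]·ln(true GMR) + aᵢ + εᵢⱼ,
with one animal effect aᵢ ~ N(0, sd_log_animal²) shared across all of that
animal's cells and independent replicate noise εᵢⱼ ~ N(0,
sd_log_replicate²). Defaults n = 8/group, sd_log_animal = 0.3,
sd_log_replicate = 0.15, 2–4 replicates — group sizes and variance scales in
the range typical of the modelled study design. Because the animal effect is
shared across cells, p-values within a family are positively correlated, as
in the longitudinal design; BH remains valid under this dependence.

**Racine series.** Deterministic score patterns cycled over a fixed
observation interval (default 5 min over 4 h), with optional ±1 excursions
at a configured probability.

## 6. Numerical choices and degenerate inputs

- Thresholding ties (value == T) are background (strict `>`); probability
  zero on continuous images.
- Variance under the windowed mean is clipped at 0 before the square root.
- `q1_reference` breaks ties by sort stability; `n = 1` masks use the single
  voxel.
- SE = 0 (noise-free groups): p is 0 for a nonzero difference, 1 otherwise;
  the CI degenerates to the point estimate.
- Empty fields, all-zero images, empty phenotype masks and zero-count
  densities all return defined values (empty masks, zero counts); empty VOI
  masks, zero references, missing cerebellum, nonpositive log arguments and
  over-crowded placements raise errors naming the offence.
- Pipeline seeds are spawned per stage from one root `SeedSequence`, so
  stages are independently reproducible and a fixed seed reruns the whole
  study byte-identically (the manifest records per-file SHA-256).

## 7. Problem sizes

The shipped benchmarks use 512² fields (20 at SNR 5), 1000 simulated
cohorts for estimator calibration, 500 null grids of 30 cells for the FDR
check, 100 random 64² images for the thresholding oracle, and 1000 random
p-vectors for the FDR oracle — sizes chosen so the whole suite runs in a few
minutes on one CPU while keeping Monte-Carlo error well inside the asserted
bands.

## 8. Known limitations

- Microglia vs infiltrating macrophages cannot be distinguished by IBA1
  colocalization; microglia and astrocytes are never co-visualized (separate
  stain protocols).
- Binary pro-/anti-inflammatory phenotyping is a deliberate simplification
  of a phenotypic continuum.
- The two-stage contrast assumes (near-)balanced replicates; strongly
  unbalanced designs would re-weight animals relative to a true mixed model.
- Synthetic-data realism limits are listed in §5; no claim is made about
  segmentation accuracy on real tissue.
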