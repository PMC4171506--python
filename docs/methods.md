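# Methods

This note records the models, algorithms, parameter choices and known
limitations of `dystroquant`, in the order the pipeline runs.

## Image model and calibration

Input is one imaged field of a muscle cross-section: two registered 2-D
intensity grids (dystrophin and spectrin) on the 12-bit acquisition
scale, 0–4095 arbitrary units (au). Values are interpreted as-is; 8- and
16-bit files are accepted but never rescaled, because absolute au values
are only comparable within one experiment's acquisition settings anyway.
A calibration-bead reference intensity can be carried as metadata but is
not applied to the data. Confocal vendor metadata is not parsed: the
µm/pixel calibration is always user-supplied (config or function
argument). Coordinates are 0-based row/column pixel indices; areas are
converted to µm² via `pixel_size**2` only at output time.

## Segmentation (spectrin channel only)

The sarcolemma is spectrin-positive in every fiber, so segmentation never
looks at the dystrophin channel — essential, since DMD fibers may have no
dystrophin signal at all.

1. **Smoothing.** Gaussian filter at `smoothing_sigma_um` (default 1 µm).
2. **Membrane band.** Threshold of the smoothed channel. Default method
   is Otsu's criterion computed on the exact unique-value histogram
   rather than a binned one: binned Otsu can misplace the cut inside a
   populated bin when the histogram has few distinct levels, which
   matters for crisp synthetic images. A percentile-anchored threshold
   (`lo + f·(hi − lo)`) is available as an alternative. Both are
   relative to the image's own intensity distribution, so the band — and
   hence the whole segmentation — is invariant to global detector gain
   (asserted by test).
3. **Fiber interiors.** 4-connected components of the band complement,
   kept if they (a) exceed `seed_min_area_um2` (default 100 µm²), (b) are
   below `max_fiber_area_um2` (default 20 000 µm², which rejects the
   extracellular background sea and fibrotic/empty areas), (c) do not
   occupy more than half of the image border, and (d) have at least
   `enclosure_min_fraction` (default 0.5) of their outer contour on the
   membrane band — an interior must be ringed by membrane to be a fiber.
4. **Membrane assignment / touching-membrane split.** Every band pixel is
   assigned to the fiber whose interior is nearest by Euclidean distance
   transform, capped at `membrane_max_thickness_um` (default 3 µm)
   converted to pixels. A wall shared by two fibers is thereby split down
   its midline, each side going to its own fiber; no membrane pixel is
   ever assigned twice, and ties in the distance transform resolve
   deterministically. The Euclidean distance is used as a deterministic
   stand-in for geodesic distance; for the thin, convex membrane bands of
   muscle mosaics the two coincide except at rare deep concavities.
   Membrane crumbs left 4-disconnected from their interior are dropped to
   keep every labeled region 4-connected.
5. **QC flags** (precedence order): `border` (region touches the image
   edge — the fiber is clipped), `too_small` (area below
   `min_fiber_area_um2`, default 200 µm²), `no_membrane`, and
   `incomplete_membrane` (membrane backs less than
   `membrane_min_perimeter_fraction` = 0.6 of the cytoplasm contour).
   Flagged fibers are kept in the output but excluded from
   quantification. The perimeter-coverage fraction is this package's own
   operationalisation of "sufficiently intact"; there is no community
   standard value.

Connectivity conventions are fixed: 4-connectivity for regions,
8-connectivity for contours. The whole stage is deterministic for a fixed
input and config (asserted bitwise).

## Per-fiber quantification

Intensity statistics over the membrane pixel set use counting
definitions, not interpolation: the Q-level quantile is the
`ceil(q·n)`-th smallest pixel, and the Q90-mean is the arithmetic mean of
the top `ceil(0.1·n)` pixels. This makes results bit-exactly reproducible
and matches the "cut-off between the lowest 90% and the brightest 10% of
pixels" definition used in practice. These statistics are shift- and
scale-equivariant and agree exactly with a brute-force sort oracle
(property-tested over random mask sizes 1–1000).

Morphometry: CSA = (membrane + cytoplasm pixel count)·pixel_size²;
mean membrane thickness = membrane area / inner-contour length, with the
inner contour measured on the cytoplasm mask (`skimage.measure.perimeter`).
The area/perimeter estimator was chosen over a medial-axis transform for
determinism and speed; on an ideal annulus it recovers the wall width
within discretisation error (~5% at 3-px walls). Degenerate fibers with
no cytoplasm are measured from the membrane alone and flagged.

Spectrin is quantified as the per-fiber membrane mean only — it serves as
a membrane identifier and staining control, never for normalising the
dystrophin signal. Cytoplasmic dystrophin is deliberately not measured;
the cytoplasm mask exists only to define geometry.

## Population statistics

The biopsy average is **fiber-weighted**: every QC-passing fiber counts
once, so sections contribute in proportion to their fiber counts.
Per-section means are retained because precision statistics are defined
across sections. The "maximum" of a biopsy is reported both as the
maximum over fibers of per-fiber means and of per-fiber maxima, which
are distinct quantities. Summaries are also computed with revertant-class
fibers excluded (threshold in config), since a treatment comparison may
want to separate restored trace expression from pre-existing revertants.

The cumulative S-curve is the bin-free empirical CDF of per-fiber mean
intensities, in percent of fibers. Curve B is called right-shifted
relative to A when B's quantile function is ≥ A's at every probed level
(stochastic dominance at default levels 0.1–0.9). Histograms default to
Freedman–Diaconis bins.

Fiber classes use half-open intervals on the per-fiber mean:
negative < `trace_floor_au` (default 200 au) ≤ trace <
`revertant_threshold_au` (default 800 au) ≤ revertant. The defaults
reflect intensity ranges typical of DMD biopsies at high laser settings
(trace 200–800 au, revertants 800–2500 au); they are configuration, not
biology — they only make sense at a matching acquisition setting.

## Precision and comparison statistics

CV% = sample SD (n−1) / mean × 100. The sample-SD convention is decisive:
with two replicates it reproduces the bundled reference inter-assay
values (e.g. means 929 and 768 au → 13%; 306/427/354 → 17%), whereas the
population SD does not. Table-style outputs round half-away-from-zero to
integer percent; machine-readable outputs keep full precision. For two
values the closed form CV% = |a−b|/(a+b)·√2·100 serves as a cross-check
oracle in the tests.

Ranking: rank 1 = highest mean; ties break by sample label
(deterministic) and are flagged; concordance is identity of sample order
across experiments.

**Hierarchical visit test.** Observations are per-image means of
per-fiber dystrophin means — the covariance structure of the assay lives
at the image and section levels, not at the fiber level. The model on
log-transformed values is

    log y = µ + visit + section(visit) + ε_image ,

with sections as random intercepts; because each image contributes one
value, the image level is the residual stratum. Variance components and
the visit contrast come from a REML fit (statsmodels MixedLM). Inference
on the contrast uses the between-section stratum: the classical
nested-ANOVA t on per-section means with df = S − 2, which equals the
GLS/REML solution for balanced designs, is exact under normality, and
avoids both the large-sample z approximation and boundary problems when
the estimated section variance hits zero (Satterthwaite-style
denominator df are not available in statsmodels). Simulated type-I error
at α = 0.05 is 0.04–0.05 across seeds (1000-replicate runs in the test
suite). A section-level permutation test (exact enumeration up to 20 000
reassignments, Monte Carlo beyond) is provided as a distribution-free
alternative; image-level exchange is offered only for degenerate
single-section designs and is anti-conservative, as its docstring warns.
Slide-level variance (sections sit on slides) is not modeled separately:
with sections nested in visits the slide term is not identifiable from
the designs supported here.

The pre/post percent difference is computed on biopsy averages;
`compare_visits` bundles it with the S-curve shift assessment and the
hierarchical test into one report.

## Synthetic data generator

The generator defines the study conditions for all tests.

- **Geometry.** Packed mosaics come from a Voronoi tessellation of
  uniform seed points with 3 Lloyd relaxation iterations (pixel-level
  centroid updates), producing convex, muscle-like polygons. Fiber CSA is
  controlled through field area / n_fibers; its spread is emergent from
  the tessellation (CV ≈ 20–25%), not an independent dial. A `sparse`
  layout places isolated disk fibers for analytic tests. Default field:
  512×512 px at 0.88 µm/px (≈ 450×450 µm), giving 80 fibers of ≈ 2.5×10³
  µm² for the dystrophic presets and 46 fibers of ≈ 4.4×10³ µm² for the
  healthy preset — realistic fiber sizes and the ~80 fibers per image
  typical of 25× confocal fields.
- **Membrane.** Each fiber owns a band within `membrane_thickness_um`
  (default 1.3 µm) of its cell boundary, so a shared wall is twice that
  thick; the image border is not a boundary, leaving border-clipped
  fibers with open membranes as in real sections.
- **Intensities.** Per-fiber spectrin means are normal
  (default 1800 ± 150 au); per-fiber dystrophin means are lognormal by
  default (non-negative and right-skewed, as real per-fiber histograms
  are; the true distribution family is unknown — presets match reported
  ranges, not shapes). Presets: `healthy` median 822 au, σ_log 0.25
  (central 95% ≈ 500–1350 au); `bmd` median 350 au; `dmd_trace` median
  400 au, σ_log 0.35 (≈ 200–800 au) with 3% revertants drawn uniformly
  from 800–2500 au; `dmd_null` background-level signal, emulating an
  epitope-deleted biopsy. Cytoplasm and background sit at 50/80/20 au.
- **Rendering order**: paint → Gaussian blur (default σ = 1 px) →
  noise (Gaussian σ = 40 au; optional Poisson) → clip to [0, 4095] →
  round. The order matters: with blur and noise off, rendered membrane
  means equal the drawn true means exactly (up to 12-bit quantization if
  enabled), which the tests exploit.
- **Hierarchical studies.** `generate_study` samples
  log-mean = log(baseline) + visit effect + N(0, σ²_section) +
  N(0, σ²_image), then per-fiber lognormal means; the per-image value is
  the mean of its fiber draws. Large simulation studies (e.g. the
  1000-replicate calibration) run at this value level without rendering
  pixels; `render=True` renders each image for small end-to-end runs.

What the generator does **not** emulate: fibrosis and adipose regions,
freezing artefacts, uneven illumination, fiber-type intensity structure,
spatially correlated noise, or isotype-control backgrounds beyond a flat
offset. Passing tests therefore demonstrate correctness of the
measurement machinery under clean-to-moderately-noisy conditions, not
robustness to every histology artefact; on real sections the QC flags
and operator review carry that load.

## Numerical and design notes

- Problem sizes in the shipped tests/acceptance script: 20 packed
  512×512 sections for segmentation recall; 1000 random masks for the
  quantile oracle; 1000 null and 200 effect replicates (value-level, 8
  sections × 5 images × 40 fibers) for test calibration; 3-image arms of
  48-fiber 320×320 sections for the rendered +30% comparison.
- Blur mixes cytoplasm signal into the membrane band, attenuating
  measured membrane means by roughly 10–20% at default blur; this is an
  optical property of the measurement, affects both arms of a paired
  comparison nearly equally (a true +30% shift is measured as ≈ +29%),
  and is why unbiased-recovery tests use noise without blur.
- The rendered +30% comparison uses a paired construction (post-arm true
  fiber means exactly 1.3× the pre-arm means, same geometry): with
  independently drawn arms, generator sampling noise alone (SD ≈ 4
  percentage points at ~300 fibers/arm) would dominate what is being
  measured, the pipeline's fidelity.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; derived seeds use `SeedSequence` and stay
  below 2³¹. Fixed input + config ⇒ bitwise-identical outputs.
- Degenerate inputs: flat spectrin → zero fibers (not an error);
  empty membrane masks are errors at quantification (callers must filter
  on QC); single-section designs are rejected with a pointer to the
  image-level permutation alternative.

## Known limitations

- Absolute au values are only comparable within one experiment; no
  percent-of-healthy normalisation is offered, since extrapolation
  across acquisition settings and antibodies is unreliable.
- The membrane-thickness estimator is an area/perimeter approximation;
  it biases slightly high for very irregular bands.
- Segmentation accuracy is validated on synthetic mosaics only; real
  sections with extensive fibrosis will need the QC thresholds tuned.
- The mixed model supports exactly two visits and requires ≥2 sections
  per visit and ≥2 images per section.
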