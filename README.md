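# dystroquant

Per-fiber sarcolemmal dystrophin quantification from two-channel
immunofluorescence images of muscle biopsy cross-sections.

## The problem

Duchenne muscular dystrophy (DMD) is caused by loss of dystrophin at the
muscle fiber membrane (sarcolemma). Therapies that aim to restore
dystrophin — exon skipping, stop-codon read-through, gene therapy — need a
sensitive, reproducible readout of dystrophin levels in muscle biopsies.
That readout is complicated by biology: nearly all fibers in a DMD biopsy
express very low "trace" dystrophin, a few "revertant" fibers express
near-normal levels, and intensities vary severalfold between fibers even
in healthy muscle. A biopsy is therefore best described not by one number
but by the *distribution* of membrane dystrophin intensity over its whole
fiber population.

`dystroquant` implements a semi-automated analysis of muscle cross-sections
co-stained for dystrophin and spectrin. Spectrin marks the sarcolemma of
every fiber regardless of disease status, so the spectrin channel drives
segmentation: each fiber is identified, its membrane band separated from
its cytoplasm (splitting the touching membranes of adjacent fibers), and
dystrophin intensity is measured inside each fiber's spectrin-defined
membrane mask on the 12-bit acquisition scale (0–4095 arbitrary units, au).

## What it computes

For each fiber *i* with membrane pixel intensities
$x_{i(1)} \le \dots \le x_{i(n)}$:

- **mean membrane intensity** $\bar{x}_i$, minimum, maximum;
- **nearest-rank quantiles** — the Q-level value is the cut-off between the
  lowest fraction of pixels and the rest, $x_{i(\lceil qn\rceil)}$;
- **Q90-mean** — the mean of the brightest $\lceil 0.1\,n \rceil$ pixels,
  which tracks the bright membrane signal an observer sees by eye;
- morphometry: cross-sectional area (µm²) and mean membrane thickness.

At the biopsy level: the fiber-weighted population average, per-section
means, histograms and the cumulative S-curve (empirical CDF of per-fiber
means — a treatment-induced increase shifts the S-curve to the right),
and a negative / trace / revertant classification (defaults 200 and 800 au).

Assay statistics:

- **precision**: $\mathrm{CV\%} = s/\bar{y} \times 100$ with the sample
  (n−1) standard deviation — intra-assay over replicate sections,
  inter-assay over per-experiment means — plus rank-order concordance of
  samples across experiments;
- **pre/post comparison**: percent difference
  $(y_{\text{post}}-y_{\text{pre}})/y_{\text{pre}} \times 100$, S-curve
  shift assessment, and a hierarchical significance test on
  log-transformed per-image means with visit as the fixed effect and
  sections-within-visit as random effects (REML variance components;
  between-section t inference; section-level permutation test as a
  distribution-free alternative).

Because patient biopsies have no public accessions, the package ships a
synthetic-section generator (Lloyd-relaxed Voronoi fiber mosaics with
membrane bands, intensity presets for healthy/BMD/DMD-trace populations,
blur/noise/quantization, full per-fiber ground truth) so that every stage
is testable end to end.

## Worked example

```python
from dystroquant import (AnalysisConfig, classify_fibers, quantify_image,
                         segment_image, summarize_biopsy)
from dystroquant.simulate import preset_params, generate_section
import pandas as pd

params = preset_params("dmd_trace", seed=1)     # ~80 packed fibers / image
image, truth = generate_section(params)
config = AnalysisConfig()

fibers = segment_image(image, config)            # segment + split + QC
metrics = quantify_image(image, [f for f in fibers if f.qc_pass], config)
frame = pd.DataFrame([m.to_row() for m in metrics])
frame["biopsy_id"] = "DMD-sim"
summary = summarize_biopsy(frame, revertant_threshold_au=800.0)

print(f"fibers segmented: {len(fibers)}, passing QC: {len(metrics)}")
print(f"avg dystrophin membrane mean: {summary.avg_dys_mean:.1f} au")
print(f"avg Q90-mean: {summary.avg_q90_mean:.1f} au")
print(f"mean CSA: {summary.csa_mean_um2:.0f} +/- {summary.csa_sd_um2:.0f} um^2")
```

prints

```
fibers segmented: 80, passing QC: 51
avg dystrophin membrane mean: 372.7 au
avg Q90-mean: 612.9 au
mean CSA: 2417 +/- 566 um^2
```

All 80 generated fibers are identified; the 51 passing QC are the intact
interior fibers (border-clipped fibers are flagged, not measured). The
population average of 373 au sits in the trace range typical of a DMD
biopsy imaged at high laser settings, the Q90-mean is higher by
construction, and the mean fiber cross-section of ~2400 µm² matches the
generator's dystrophic-fiber geometry. Classifying the same fibers finds
2/51 revertants (3.9%), consistent with the preset's 3% revertant rate.

Precision statistics work directly on replicate means:

```python
from dystroquant import cv_percent
r = cv_percent([306, 427, 354], kind="inter")   # one biopsy, 3 experiments
print(f"CV% = {r.cv_percent:.1f} -> {r.cv_percent_rounded}%")
# CV% = 16.8 -> 17%
```

A command line mirrors the library: `dystroquant simulate`,
`dystroquant quantify`, `dystroquant compare` (see `--help`); every run
writes a JSON manifest with config, seeds and per-stage fiber counts.

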