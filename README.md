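# mitophen

Quantification of mitotic phenotypes in chondrocytes expressing
skeletal-dysplasia-associated KIF22 variants.

KIF22 (Kid) is a chromokinesin that generates polar ejection forces (PEF) —
pushing forces on chromosome arms, away from spindle poles — during
mitosis. Variants in KIF22 cause spondyloepimetaphyseal dysplasia with
joint laxity type 2 (SEMDJL2); mechanistically they either fail to switch
PEF off at anaphase onset (dominant variants) or partially lose and
dysregulate motor activity (the recessive R49Q class). Four image-based
assays capture these phenotypes, and this package implements all of them as
a tested, reusable pipeline:

- **Anaphase tracking** — per movie frame, the chromosome-label intensity is
  profiled along the line through both spindle poles, split at the pole
  midpoint, and the distance between the two half-profile maxima is the
  chromosome-mass separation *d*; the per-division maxima of *d* and of the
  pole separation *p* are the endpoints.
- **PEF assay** — on monastrol-induced monopolar spindles, the distance from
  the pole pair to the maximum of the DNA channel's radial intensity
  profile (annular-bin means inside a 14 µm ROI) proxies relative PEF.
- **Nuclear morphometry** — solidity (mask area / convex-hull area) of
  segmented interphase nuclei; nuclei below the 5th percentile of the
  control population (threshold 0.966) are classified abnormal.
- **Expression quantification** — background-subtracted KIF22 intensity
  within a per-cell tubulin-derived spindle mask, normalized to the control
  condition; yields knockdown efficiency and overexpression fold.

Because the study's raw images are not deposited, the package also ships a
synthetic-microscopy generator (`mitophen.synthetic_data`) whose named
condition presets (wt, p144t, e222q, r149q, r49q, GFP-only, each ± KIF22
knockdown) encode the reported per-condition means as ground truth, under a
Gaussian-PSF + Poisson–Gaussian noise model. Every quantification stage is
validated by recovering those encoded values. See `docs/methods.md` for
the models and parameter choices.

## Worked example

Simulate 20 WT-preset anaphase movies, track them, and summarize:

```python
import numpy as np
from mitophen import synthetic_data as syn
from mitophen.anaphase_quant import track_movie

preset = syn.get_preset("wt")          # encodes 14.8 um chromosome / 21.3 um pole plateaus
maxima = []
for seed in range(20):
    movie, truth = syn.generate_anaphase_movie(preset, seed=seed)
    series = track_movie(movie)
    maxima.append(series.max_chrom_separation_um)
print(f"mean max chromosome separation: {np.mean(maxima):.2f} "
      f"+/- {np.std(maxima, ddof=1)/np.sqrt(len(maxima)):.2f} um")
```

```
mean max chromosome separation: 14.43 +/- 0.27 um
```

The tracked mean recovers the preset's encoded 14.8 µm plateau to well
within three reported SEM (±1.11 µm); the residual offset is the sampling
noise of 20 lognormally jittered cells. The same round trip through the
command line:

```sh
mitophen simulate --preset wt --kind anaphase --n 20 --seed 0 --out scratch/wt
mitophen quantify-anaphase --in scratch/wt --out scratch/wt.csv
mitophen report --config run.yaml     # full simulate->quantify->compare pipeline
```

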