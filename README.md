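# ramanbone

Analysis toolkit for Raman microspectroscopy of bone in a murine model of
breast-cancer bone metastasis.  Osteolytic metastases dissolve bio-hydroxyapatite
mineral and degrade the collagen matrix; both leave quantitative fingerprints in
the bone's Raman spectrum.  This package implements the full desk side of such a
study: spectral preprocessing, band-level composition metrics, region-stratified
group statistics, and a PCA → RBF-SVM decision algorithm that predicts how long
a bone has carried tumor from a single spectrum.  A synthetic-study generator
reproduces the sampling design (femurs at 7 sites × 5 replicates = 35 spectra,
vertebral columns at 12 vertebrae × 5 replicates = 60 spectra, at weeks 0, 2, 4
and 5 after tumor inoculation), so every stage is testable end-to-end without
any external data.

## The measurements

Six bands in the fingerprint region are quantified (windows in cm⁻¹):
phosphate ν₁ at ~958 (938–978), phenylalanine ~1004 (994–1014), carbonate ν₁
~1070 (1050–1090), amide III ~1250 (1220–1280), CH₂ wag ~1450 (1420–1480) and
amide I in the 1630–1656 region (window 1608–1704).  Four per-spectrum metrics
summarize bone quality:

| metric | definition | meaning |
|---|---|---|
| mineral-to-matrix | phosphate ν₁ / amide I height | collagen mineralization |
| phosphate-to-carbonate | phosphate ν₁ / carbonate height | inverse marker of carbonate substitution |
| carbonate-to-matrix | carbonate / amide I height | remodeling, fracture-risk associated |
| crystallinity | 1 / FWHM(phosphate ν₁) | apatite crystal order |

Raw spectra pass through five corrections in order: cosmic-ray removal →
aluminum-substrate background subtraction → white-light response division →
automated fluorescence-baseline removal (iterative constrained polynomial) →
normalization to the phosphate ν₁ apex.

The decision algorithm projects normalized spectra onto principal components
(components retained to ≥ 95% cumulative variance, capped at 20), feeds the
scores to an RBF-kernel soft-margin SVM with C and γ chosen on power-of-two
grids, and validates with a leave-one-spectrum-out protocol in which PCA and
the SVM are refit for every fold.  A permuted-label negative control reruns the
whole protocol with week labels randomly reassigned, establishing the chance
floor.

## Worked example

```python
import ramanbone as rb
from ramanbone import bands, mlpipe, preprocess, synth

cfg = rb.default_config()                      # 3 mice per week
study, profile, truth = synth.simulate_study(cfg, seed=0)
print(len(study))                              # 1140 spectra

femur = study.select((study.meta["bone"] == "femur").to_numpy())
normalized, log = preprocess.preprocess_pipeline(femur, profile)

table = bands.metrics_table(normalized)
print(table.groupby(["region", "week"])["mineral_to_matrix"].mean().round(3))

clf = mlpipe.ClassifierConfig(selection="global", seed=0)
result = mlpipe.loocv_classify(normalized, cfg=clf)
print(result.region_average.round(1))
```

Output:

```
1140
region               week
diaphysis            0       2.355
                     2       2.408
                     4       2.465
                     5       2.565
distal_metaphysis    0       2.347
                     2       2.531
                     4       2.935
                     5       3.374
proximal_metaphysis  0       2.397
                     2       2.539
                     4       2.952
                     5       3.357
Name: mineral_to_matrix, dtype: float64
distal_metaphysis      100.0
diaphysis               50.0
proximal_metaphysis     95.0
dtype: float64
```

Mineral-to-matrix rises steeply through the weeks in both metaphyses (where
metastases colonize the vascularized remodeling niche) and barely moves in the
cortical diaphysis.  The classifier separates the four week classes almost
perfectly in the metaphyses, while the nearly unchanged diaphysis is the least
classifiable region — the same qualitative pattern the composition metrics
show.  The permuted-label control for the full study tops out at 27% across
20 iterations (`scripts/acceptance.py --seed 1`), i.e. at 4-class chance.

A CLI mirrors the library: `ramanbone simulate | preprocess | metrics |
classify | report` (see `--help` on each).

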