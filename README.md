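# gliaquant

Scriptable standardization, segmentation and 3D morphometry of radial-glia
fluorescence z-stacks.

The package turns a folder of calibrated TIFF stacks into comparable,
quantified morphology: stacks are rotated and cropped into a common
apicobasal frame from user-drawn line ROIs, optionally deconvolved
(Richardson–Lucy with a theoretical diffraction PSF), binarized with one of
six thresholding strategies or the cytosol/membrane reference pipelines, and
quantified (volume, coverage, surface, EDM thickness, 3D-thinning skeleton
topology, apicobasal texture profiles). A synthetic-phantom generator with
exact ground truth replaces microscopy downloads for testing.

## Modules

| Module | Purpose |
| --- | --- |
| `gliaquant.volume_io` | Calibrated TIFF stacks, ImageJ/JSON ROI archives, MIPs, channel splitting, 8-bit conversion |
| `gliaquant.quality` | ROI statistics, SNR (`mu_s - mu_ns`) and CNR (`(mu_s - mu_ns)/sigma_bg`), z-decay profiles |
| `gliaquant.standardize` | 90° rotations; line-ROI subregion extraction to a fixed width/depth frame |
| `gliaquant.deconvolve` | Paraxial (Born–Wolf) theoretical PSF; Richardson–Lucy (default 1 iteration) |
| `gliaquant.segment` | 3D median + rolling-ball pre-processing; Otsu/Moments/Percentile/Max-Entropy/hysteresis/simple-3D; speckle removal; method comparison |
| `gliaquant.zonation` | 3D → 1D apicobasal mean-intensity profiles, scale normalization, height measures, CSV/heatmap export |
| `gliaquant.quantify` | Volume/coverage/surface, anisotropic EDM thickness, 3D thinning skeleton + graph statistics, texture profiles |
| `gliaquant.phantom` | Radial-glia phantoms with analytic ground truth; quality-metric phantoms; degradation (PSF blur, z-decay, noise) |
| `gliaquant.pipeline` / `gliaquant.cli` | Batch driver with the conventional folder layout (`zDir`, `1CDir`…, `TH`, `ZonationTool`, `QuantEDM`, `QuantSkel`), CoV comparability check |

Note on 3D thinning: the skeletonization uses an in-package
topology-preserving thinning (`gliaquant._thinning`) rather than
`skimage.morphology.skeletonize`, which in the pinned version erases whole
structures for some even-width cross-sections.

## CLI

Every protocol step is a headless subcommand (`gliaquant --help`):

```bash
# synthesize a test batch with ground truth + matching ROI archive
gliaquant phantom --out data/tiff --seed 1 --n 3

# standardize: rotate to the ROI axis, crop to 60 x 10 um with 10 um sigma
gliaquant subregion --input data/tiff --width 60 --depth 10 --sigma 10

# segment and quantify
gliaquant segment --input data/tiff/zDir --profile cytosol
gliaquant quantify --input data/tiff/zDir/TH --sigma 10

# batch comparability (CoV per feature, flags above 20 %)
gliaquant validate --results data/tiff/zDir/TH/QuantificationResults.csv
```

Multi-step runs can be driven from a YAML config
(`gliaquant pipeline --config run.yaml`) with keys `input_dir` and `steps`.

Input expectations: TIFF stacks with resolution tags (ImageJ-style `spacing`
for z); vendor formats must be exported to TIFF first. Line ROIs are read
from `RoiSetLine.zip` (ImageJ ROI archive) or an equivalent `.json`, paired
with the TIFFs in lexicographic filename order.

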