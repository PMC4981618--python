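# wmlseg

Unsupervised detection and segmentation of small focal white-matter lesions
(WML) from co-registered 3D T1w and FLAIR MRI, plus the synthetic phantoms
and evaluation machinery needed to exercise the whole pipeline without any
external data.

## Method

1. **Preprocessing** — Perona–Malik anisotropic diffusion on FLAIR
   (1 iteration, K = 50, high-contrast conduction, 6-neighbour flux form,
   dt = 1/7), followed by a log-domain EM bias-field correction (3-class
   Gaussian mixture alternating with a ridge-regularized order-3 polynomial
   gain model) inside the brain mask.
2. **Tissue model** — a 3-component Gaussian-mixture EM on T1 intensities
   (percentile-initialized k-means start) yields CSF/GM/WM probability
   maps; the brain mask is the 0.5-thresholded maximum-probability map with
   3D hole filling. Externally produced probability maps (e.g. from SPM)
   can be substituted via `--tissue-probs`.
3. **Lesion segmentation** — the main peak μ of the FLAIR GM histogram and
   its FWHM-derived σ define a hyperintensity threshold μ + ασ
   (default α = 2.5). Candidate voxels (inside the brain, outside an
   optional posterior-fossa exclusion mask) are grouped into 26-connected
   components and refined by:
   - minimum size (default 3 mm³, strict less-than removal),
   - WM fraction of the 1-voxel 26-shell neighbourhood ≥ λ (default 0.70),
   - the location exclusion, applied at the candidate stage.
4. **Evaluation** — voxel Dice, lesion-wise TPR/PPV (≥1-voxel overlap
   matching), FN volume rate, the combined score
   `F = 3·DSC·TPR·PPV / (DSC+TPR+PPV)`, burden stratification
   (<5 / 5–25 / >25 lesions), Spearman correlation, Bland–Altman limits,
   and a two-fold cross-validated grid search over
   α ∈ {1.0, …, 3.0} (step 0.1) × λ ∈ {0, …, 1} (step 0.05).
5. **Phantoms** — nested-ellipsoid brain phantoms (CSF rim / GM ribbon /
   WM core) with focal WM lesions, a smooth quasi-Gaussian GM texture
   field, optional multiplicative bias and Gaussian noise, a labelled
   inferior "posterior fossa" slab, and optional non-lesion distractors
   that make the α/λ sweep informative.

## CLI

```bash
# synthesize a phantom case (NIfTI volumes + ground truth + spec echo)
wmlseg phantom --spec spec.yaml --out case/ --seed 11

# segment: writes lesion_mask.nii.gz, lesion_labels.nii.gz, report.json
wmlseg segment --t1 case/t1.nii.gz --flair case/flair.nii.gz \
    --exclusion case/pf_mask.nii.gz --alpha 2.5 --lambda 0.70 \
    --min-volume 3 --out seg/ --seed 13

# compare an automatic mask with ground truth
wmlseg evaluate --auto seg/lesion_mask.nii.gz --gt case/lesion_gt.nii.gz \
    --out report.json

# cross-validated parameter sweep over a YAML list of cases
wmlseg sweep --cases cases.yaml --alpha-min 1 --alpha-max 3 --alpha-step 0.1 \
    --lambda-min 0 --lambda-max 1 --lambda-step 0.05 --folds 2 --seed 7 \
    --out sweep.csv

# FLAIR preprocessing products only
wmlseg preprocess --flair flair.nii.gz --t1 t1.nii.gz --out pre/
```

Each subcommand also accepts `--config run.yaml` supplying defaults for its
options (explicit flags win; unknown keys are rejected). Argument errors
exit with status 2; runtime failures exit with status 1 and name the
failing stage.

## Layout

```
src/wmlseg/
  volume_io.py            NIfTI I/O, Volume/BinaryMask, grid contracts
  preprocessing.py        diffusion, bias field, brain mask
  tissue_model.py         3-class EM tissue probabilities and labels
  lesion_segmentation.py  GM peak, threshold, component filters, pipeline
  evaluation.py           metrics, stratification, grid search
  phantom.py              synthetic case and suite generators
  cli.py                  click entry point (console script: wmlseg)
tests/                    unit + property tests, test_acceptance.py
scripts/acceptance.py     acceptance report generator
```
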