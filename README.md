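# scdmri

Simulation and comparison of diffusion-MRI acquisition protocols for
small-animal spinal cord imaging.

The package simulates synthetic spinal-cord dMRI cohorts under three
acquisition strategies, estimates diffusion-tensor and two-direction
metrics, and computes the statistics used to compare protocols:
signal- and contrast-to-noise ratios, inter-/intra-subject coefficients
of variation, angular deviation from the slice axis, effect sizes, and
nonparametric group tests.

## Modules

| module | role |
| --- | --- |
| `scdmri.schemes` | the three built-in protocols (A: 126 dir / b=700 s/mm²; B: 12 dir / b=1200; C: slice+read axes at 5 b-values), electrostatic direction generation, DTI design matrix, FSL bval/bvec I/O |
| `scdmri.phantom` | procedural cord cross-section (4 WM sectors + 2 GM horns), ground-truth tensors, mono-/bi-exponential signals, Rician noise with NA complex-domain + NR magnitude-domain averaging, cohort generation with biological variation and disease effects |
| `scdmri.dwi_io` | study bundles (NIfTI + bval/bvec + JSON meta), ROI label maps, ROI extraction |
| `scdmri.estimators` | OLS/WLS log-linear tensor fit, eigenvalue metrics (FA/MD/AD/RD), per-direction ADC fit and two-direction metric formulas, angular deviation, frame-projected metrics |
| `scdmri.stats` | SNR, CNR, inter-/intra-subject CV, effect size, exact/approximate two-sided Mann-Whitney U, Spearman correlation |
| `scdmri.pipeline` | experiment orchestration, report tables (means, CVs, best-protocol-per-cell, ES/p comparisons, SNR/CNR), YAML configs |

Units: b-values are stored internally in ms/µm² (1.2 ≙ 1200 s/mm²) and
diffusivities in µm²/ms; files on disk use s/mm².

## CLI

```sh
scdmri run      --config cfg.yaml --seed 1 --out report/     # all stages
scdmri simulate --config cfg.yaml --seed 1 --out sim/        # phantom -> bundles
scdmri fit      --study sim/studies/WT01_week17_B --out maps/WT01_week17_B
scdmri analyze  --maps maps/ --labels sim/labels.nii --out subject_table.tsv
scdmri report   --stats subject_table.tsv --out report/
```

Example config:

```yaml
protocols: [A, B, C]
n_per_group: 7
timepoints: [week10, week17]
seed: 1
fit_method: wls
phantom:
  grid: [64, 64, 8]
  noise_sigma: 20.0
  subject_cv: 0.03
  signal_mode: mono
```

Outputs are tidy TSV tables with a provenance header (config hash +
seed); rerunning the same config and seed reproduces them byte for
byte.

## Acceptance

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

No scalar acceptance targets are defined for this artifact (the
original in vivo data were never released), so the script verifies that
the installed pipeline executes end to end and writes an empty JSON
object.  The substantive acceptance checks are property-based and live
in `tests/test_acceptance.py`: exact noiseless recovery, the
two-direction/tensor degeneracy identity, MD frame invariance, the
Rician FA-bias mechanism, the b-value dependence of fitted
diffusivities, Mann-Whitney oracle equivalence and null calibration,
end-to-end effect-sign recovery, and the intra-subject CV protocol
ordering.
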