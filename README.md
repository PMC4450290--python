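# asymseg

Hybrid brain MR tissue segmentation: an asymmetric-Gaussian modified EM
for initial CSF / gray-matter / white-matter labeling, 3-D gray-level
co-occurrence (Haralick) texture features over ambiguous boundary
voxels, stepwise discriminant feature selection, and one-vs-rest RBF-SVM
relabeling — with a ground-truthed phantom generator so every stage runs
at desk scale without external data.

## Who it is for

Researchers working on intensity-based tissue classification of
skull-stripped, bias-corrected T1-weighted volumes (NIfTI-1 or Analyze
7.5) who need a tested, reproducible implementation of
histogram-splitting EM with per-class asymmetry, volumetric GLCM texture
features, and SVM boundary refinement — or any of those pieces on their
own.

## The model

Tissue intensity distributions on T1 images are skewed (CSF in
particular spreads across the low end of the histogram), so each class
is modelled by an asymmetric Gaussian with distinct flank widths:

    A(z; μ, σ², r) = √(2/π)/(σ(1+r)) · { exp(−(z−μ)²/(2σ²)),     z > μ
                                       { exp(−(z−μ)²/(2r²σ²)),   z ≤ μ

where σ is the right-flank SD and r·σ the left-flank SD (r = 1 is the
symmetric Gaussian).  The histogram is split into three modes at its
interior minima; per mode, μ and σ are fixed and r is found by
minimising the mean absolute difference (1/N)Σ|f_i − g_i| between
observed and model bin counts over a multiplicative 10%-step search.
Voxels get argmax membership labels; those with maximum posterior below
τ = 0.9 form the overlap mask, are described by 130 Haralick texture
features (13 features × mean/std over 13 directions × distances 1–5,
21³ window), reduced by stepwise discriminant analysis, and relabeled by
one-vs-rest soft-margin SVMs (RBF, C = 100).  Agreement is reported as
Jaccard J and Kappa (Dice) k = 2J/(J+1) percentages per tissue.

See `docs/methods.md` for the full procedure, defaults and limitations.

## Worked example

```python
import asymseg as a

# a 64³ three-tissue phantom at 5% Rician noise, with exact ground truth
vol, truth = a.generate_phantom(a.PhantomSpec(seed=7, noise_sigma=0.05))

res = a.run_pipeline(vol, a.PipelineConfig(seed=11), truth=truth)
for p in res.mixture_params:
    print(f"mu={p.mean:6.1f}  sigma_first={p.sigma_first:5.2f}  r={p.ratio:4.2f}")
print("overlap voxels:", res.overlap_count, " relabeled:", res.changed_count)
print("final Kappa %:", {t: round(v, 2) for t, v in res.report.kappa_pct.items()})
```

prints

```
mu=  38.4  sigma_first=11.16  r=1.21
mu= 103.9  sigma_first=11.01  r=1.00
mu= 168.6  sigma_first=11.36  r=0.91
overlap voxels: 356  relabeled: 96
final Kappa %: {'CSF': 99.97, 'GM': 99.93, 'WM': 99.88}
```

The three fitted modes sit at the CSF/GM/WM class means (the 5% noise
broadens each σ from its clean value of 6 and pulls r toward 1); 356
low-confidence voxels were flagged at tissue-boundary intensities and 96
of them reassigned by the SVM stage, which raised every tissue's Kappa
over the EM-only labeling (e.g. WM 99.72 → 99.88).  On a noise-free
phantom the overlap mask is empty and the refinement changes nothing.

The same pipeline is available from a shell:

```bash
asymseg phantom --out vol.nii.gz --truth truth.nii.gz --noise 0.05 --seed 7
asymseg segment vol.nii.gz --truth truth.nii.gz --out-dir seg/
asymseg evaluate seg/final_labels.nii.gz truth.nii.gz
```

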