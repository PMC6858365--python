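# contrastshift

Desk-scale study of a clinically important failure mode in CT organ
segmentation — and of the GAN-based data augmentation that fixes it.

Most labeled abdominal CT datasets are contrast-enhanced: intravenous
iodine raises the attenuation (HU) of perfused organs, most dramatically
the kidney, and adds a characteristic enhancement texture. A 3D U-Net
trained on such data learns to key on those cues and can fail almost
completely on non-contrast scans of the same anatomy — a distribution
shift that real deployments hit constantly, since many patients cannot
receive contrast. Training a CycleGAN on *unpaired* contrast and
non-contrast scans yields a slice-wise translator that renders synthetic
non-contrast versions of the labeled training volumes; mixing those into
training (probability 0.5 per sample) largely restores out-of-
distribution performance without hurting in-distribution accuracy.

This package reproduces that whole mechanism on synthetic 3D phantoms,
on a single CPU, with every stage implemented and tested:

* `contrastshift.phantom` — paired contrast/non-contrast CT-like
  phantoms with organ labels (kidney-like enhancer, bright vessel tube,
  fat slab, acquisition noise);
* `contrastshift.ct_io` — NIfTI I/O, HU clipping to [−200, 300],
  zero-mean/unit-variance normalization, fat-noise estimation, and the
  curation gates (contrast probability > 0.8 / < 0.2, fat-noise SD
  < 15 HU) that assemble translator training pools;
* `contrastshift.augment` — flips, ±30° rotations, elastic b-spline
  deformation, random crop, histogram-equalization augmentation, the
  domain-swap coin, and the 16-variant caching scheme;
* `contrastshift.cyclegan` — `CycleGANTranslator`, an sklearn-style
  estimator (fit on unpaired pools, transform volumes slice-wise) built
  on a small numpy autodiff engine (`contrastshift.nn`);
* `contrastshift.unet` — `UNet3DSegmenter`: residual 3D U-Net with a
  stride-2/kernel-7 entry convolution, group normalization, leaky ReLU,
  no skip at the highest level, trained with the smoothed Dice loss

      Loss = 1 − 2(|X ∩ Y| + s)/(|X| + |Y| + s),   s = 1 train / 0 eval

  and evaluated with Dice score and relative volume error
  |V_expert − V_pred| / V_expert;
* `contrastshift.harness` — 75/5/20 splits, k-fold cross-validation,
  early stopping with best-validation selection, in-/out-of-distribution
  evaluation, Wilcoxon signed-rank comparisons, and `run_experiment`,
  the end-to-end pipeline.

## Worked example

```python
from contrastshift.harness import ExperimentConfig, run_experiment, report_markdown

bundle = run_experiment(ExperimentConfig(seed=0))   # ~7 min on one CPU
print(report_markdown(bundle["summary"]))
for c in bundle["comparisons"]:
    print(c["condition_a"], "vs", c["condition_b"],
          f"n={c['n_pairs']} p={c['p_value']:.3g}")
```

prints (seed 0):

```
| condition | domain | Dice (mean ± SD) | volume error (mean ± SD) |
|---|---|---|---|
| cyclegan | in_distribution | 0.848 ± 0.010 | 0.090 ± 0.024 |
| standard * | in_distribution | 0.881 ± 0.014 | 0.085 ± 0.017 |
| cyclegan * | out_of_distribution | 0.869 ± 0.002 | 0.062 ± 0.002 |
| standard | out_of_distribution | 0.491 ± 0.195 | 0.660 ± 0.172 |
standard vs cyclegan n=40 p=7.88e-08
standard vs cyclegan n=20 p=1.91e-06
```

Read it as the mechanism in miniature: with standard spatial
augmentation only, the kidney model loses ~0.4 Dice when evaluated on
non-contrast phantoms it was never trained on (and its volume estimates
become useless, 66% error); with CycleGAN domain-swap augmentation the
out-of-distribution Dice recovers to ~0.87 while in-distribution
performance stays within a few points. The Wilcoxon lines compare the
two conditions on individually paired cases (40 out-of-distribution
pairs, 20 in-distribution pairs). Absolute values are desk-scale
(32³ phantoms, 2 folds), not clinical numbers; see `docs/methods.md`.

The same pipeline is scriptable from the shell:

```bash
contrastshift run-all --seed 0 --out-dir results/run0
contrastshift simulate --n-cases 5 --grid 48 --out-dir phantoms/
```

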