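# echoenhance

Speckle-degraded cardiac-ultrasound phantom enhancement with a shallow
three-stage convolutional network, plus the image-quality metrics (MSE /
PSNR / SSIM) and rule-based echocardiographic diagnosis logic needed to
exercise the full pipeline on synthetic data only.

## What it does

- **`echoenhance.phantom`** — deterministic four-chamber-style phantom
  images; a seeded degradation chain (Gaussian blur → unit-mean
  multiplicative speckle → additive noise → clip); paired clean/noisy
  datasets with geometry jitter; and synthetic patient cohorts drawn from
  configurable normal distributions truncated to physiologic bounds.
- **`echoenhance.enhancer`** — the three-stage network (feature
  extraction 9×9/16 → nonlinear mapping 5×5/8 → linear reconstruction
  5×5/1), reflect-padded same-size convolutions, ReLU and self-gated swish
  (`x·σ(αx)`, trainable `α`) activations, MSE loss, plain mini-batch SGD,
  and hand-derived backprop verified against finite differences.
- **`echoenhance.semisup`** — the semi-supervised discriminator losses
  (labeled cross-entropy, unlabeled `−t + softplus(t)`, generated
  `softplus(t)` with `t = LSE` over real-class logits; fake-class logit
  pinned to 0) and their weighted total `L_label + v·(L_unlabel + L_fake)/2`,
  plus an optional per-epoch discriminator-tracking hook for training.
- **`echoenhance.metrics`** — MSE, PSNR and SSIM on the integer
  `0..2ⁿ−1` scale; SSIM from global moments by default, with an 8×8
  sliding-window variant.
- **`echoenhance.diagnosis`** — strict-inequality CHF positivity rules
  (LAD > 30 mm; LVDD > 55/50 mm by sex; LVEF < 50 %), AWGS-style sarcopenia
  screening, similarity/proportion concordance arithmetic (half-up rounding
  to one decimal), and pooled t / Pearson chi-square comparisons.
- **`echoenhance.io` / `echoenhance.pipeline` / `echoenhance.cli`** — 8/16-bit
  grayscale PNG/TIFF I/O, cohort and count-table CSVs, a flat validated YAML
  config, per-stage seed derivation, and the end-to-end pipeline.

## CLI

```bash
echoenhance simulate --n-pairs 10 --height 64 --width 64 --seed 1 --out pairs/
echoenhance train --pairs pairs/ --epochs 200 --lr 0.2 --batch 2 --seed 1 --out model.json
echoenhance enhance --model model.json --in pairs/noisy_000.png --out enhanced.png
echoenhance evaluate --ref pairs/clean_000.png --test enhanced.png
echoenhance diagnose --cohort cohort.csv --rule any --out flags.csv
echoenhance concordance --table table.csv --out report.csv
echoenhance run-all --seed 1 --out runs/demo
```

`concordance` expects a CSV with columns `group,chf_count,other_count`;
cohort CSVs use the header
`patient_id,sex,lad_mm,lvdd_mm,lvef_pct,smi_kg_m2,grip_kg,gait_m_s`.
`run-all` accepts a YAML config (`--config`) whose keys and defaults are
`echoenhance.io.RunConfig.defaults()`; unknown keys are rejected.

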