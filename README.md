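# chemfinger

Generative augmentation and PLS-DA grading for chemometric fingerprints.

Quality grading of herbal materials (here: a three-grade H/M/L cohort of
the Tibetan medicinal material Shilajit) is commonly done by pattern
recognition on instrument fingerprints — HPLC chromatograms, FTIR
spectra, or their low-level fusion (raw concatenation). The practical
obstacle is sample scarcity: cohorts of a few dozen batches per grade
leave classifiers such as PLS-DA starved for training data. `chemfinger`
implements the full augmentation-and-grading pipeline for this setting:

1. **Synthetic cohort generator** — grade-structured HPLC chromatograms
   (Gaussian peak trains; the high grade carries the most peaks),
   FTIR spectra (absorption bands whose grade differences are confined to
   the 1,000–1,500 cm⁻¹ fingerprint region), instrument-like noise and
   baseline drift, and low-level data fusion.
2. **Two-stage vector-quantized time-series generator.** Stage 1 maps a
   signal *x* to its STFT *u*, splits it into complementary zero-padded
   low- and high-frequency spectrograms, encodes each branch with a 1-D
   convolutional encoder and replaces every latent by its nearest
   codebook vector *z_q* (Euclidean distance, straight-through
   gradients). The training objective is

       L_VQ = L_codebook + L_recons
       L_codebook = Σ_b ‖sg[E_b(u_b)] − z_q,b‖² + β‖E_b(u_b) − sg[z_q,b]‖²
       L_recons   = Σ_b ‖x_b − x̂_b‖² + ‖u_b − û_b‖²     (b ∈ {LF, HF})

   with `sg` the stop-gradient. Stage 2 freezes the tokenizer and fits a
   bidirectional transformer prior over the discrete tokens by masked-token
   cross-entropy, conditioned on the grade label; sampling proceeds by
   iterative decoding that commits the most confident token predictions
   under a cosine schedule.
3. **Generation quality scoring** — Fréchet distance between Gaussian
   fits of real and generated feature clouds,
   FID = ‖μ_x−μ_g‖² + Tr(Σ_x+Σ_g−2(Σ_xΣ_g)^½), and the inception score
   IS = exp(E_x KL(p(y|x)‖p(y))) ∈ [1, 3], both in the feature space of a
   fully convolutional network trained on the real cohort; PCA/t-SNE
   panels in direct and latent space.
4. **PLS-DA grading** — NIPALS PLS2 on one-hot grade indicators,
   10-fold CV selection of the latent-variable count, explained variance
   per block, and per-grade one-vs-rest SEN/SPE/PRE/ACC/F1 with confusion
   matrices and ROC curves, across six data types (HPLC, FTIR, fused,
   each with and without augmentation).

All neural components run on a small numpy reverse-mode autodiff engine
(`chemfinger.nn`) — the package has no deep-learning framework
dependency and runs on a single CPU at desk scale.

## Worked example

```python
import numpy as np
from chemfinger import (TimeVqvae, Stage1Config, PriorConfig, PLSDA,
                        default_profiles, generate_hplc, train_fcn, FcnConfig,
                        evaluate_generation, values_matrix)

profiles = default_profiles()
real = []
for k, grade in enumerate("HML"):
    real += generate_hplc(profiles[grade], 20, seed=k, length=512)

fitted = TimeVqvae(real,
                   stage1_config=Stage1Config(iterations=300, seed=0),
                   prior_config=PriorConfig(steps=250, seed=0)).fit()
print(fitted.summary())
```

```
Two-stage VQ fingerprint generator
==========================================
samples: 60   signal length: 512
STFT window/hop: 16/8   LF/HF cutoff bin: 5
codebooks: K=64, d=32 per branch   beta=0.25
stage-1 iterations: 300   prior steps: 250
------------------------------------------
final VQ loss:        0.18139
final recons loss:    0.02031
  LF branch:          0.02013
  HF branch:          0.00018
final prior masked CE: 0.17778
```

The reconstruction loss falls by an order of magnitude over training, with
the low-frequency branch (which carries the chromatographic envelope)
dominating the residual; the prior's masked cross-entropy of 0.18 nats
means the transformer predicts held-out tokens nearly deterministically.
Scoring 150 generated samples against the real cohort and grading the
augmented set:

```python
synthetic = fitted.generate_counts({"H": 50, "M": 50, "L": 50}, seed=1)
X, y = values_matrix(real)
Xg, yg = values_matrix(synthetic)
fcn = train_fcn(X, y, FcnConfig(iterations=200, seed=0))
report = evaluate_generation(fcn, X, Xg, "HPLC")
print(f"FID = {report.fid:.4f}   IS = {report.is_mean:.4f} +/- {report.is_std:.4f}")
print(f"conditional fidelity = {np.mean(fcn.predict(Xg) == yg):.3f}")

clf = PLSDA(np.vstack([X, Xg]), np.concatenate([y, yg]), n_lv=6).fit()
print(clf.summary())
```

```
FID = 11.2045   IS = 1.1395 +/- 0.1925
conditional fidelity = 0.980

PLS-DA grade classifier
==========================================
samples: 210   features: 512
latent variables: 6
explained variance (cumulative): X 0.892   Y 0.989
------------------------------------------
training metrics (macro): SEN=1.0000  SPE=1.0000  PRE=1.0000  ACC=1.0000  F1=1.0000
overall training accuracy: 1.0000
```

98 % of the generated chromatograms are assigned their requested grade by
the real-trained FCN, and the PLS-DA model fitted on the augmented set
separates the three grades perfectly on its training block. The full
benchmark over all six data types is one call (or
`chemfinger run-all --profile smoke` from the shell):

```python
from chemfinger import RunConfig, run_all
artifacts = run_all(RunConfig.profile("smoke", seed=0, outdir="runs/smoke"))
```

which writes loss traces, generation-quality reports, projection
coordinates, per-grade metric tables and confusion matrices as CSV plus a
JSON manifest.

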