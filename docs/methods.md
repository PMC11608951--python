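# Methods

## Problem setting

`chemfinger` models the grading of a herbal material from 1-D instrument
fingerprints when real batches are scarce. A cohort is a set of samples,
each a fixed-length signal (HPLC chromatogram on a retention-time axis,
FTIR spectrum on a wavenumber axis, or their raw concatenation) with a
grade label H, M or L. The pipeline asks two questions: can a discrete
generative model learn the per-grade signal distribution from a few dozen
batches, and does augmenting the training set with its samples help a
PLS-DA grade classifier.

## Synthetic cohort generator

Because no public graded cohort of this kind exists, the package carries
a first-class generator with known ground truth.

**Chromatograms** are sums of Gaussian peaks. The default grade profiles
share ten peaks (grade-invariant retention times and heights) and add
grade-specific peaks so the totals are 18 / 14 / 10 for H / M / L —
a peak-richness ordering with the high grade densest. Peak widths default
to 0.35 min on a 0–60 min axis. **Spectra** are sums of Gaussian bands on
a 4,000–400 cm⁻¹ axis; eight shared bands are grade-invariant, and five
discriminating bands sit inside 1,000–1,500 cm⁻¹ with per-grade height
offsets scaled by a single `effect` knob (0 = indistinguishable grades).
Default cohort sizes are 44 / 60 / 33 batches for H / M / L and default
generated-batch counts 298 / 311 / 291.

Per sample, instrument variability enters as (i) log-normal
multiplicative peak-height jitter (spread 0.15 by default), (ii) a random
quadratic baseline scaled by `baseline_drift_amplitude` (default 0.02 in
absorbance units), and (iii) additive white Gaussian noise
(`noise_sd` = 0.01). What this does **not** emulate: retention-time
shifts and peak tailing, correlated (pink) detector noise, atmospheric
CO₂/H₂O interference in spectra, and any real chemistry. Passing tests
therefore show that the pipeline recovers grade structure expressed as
peak/band amplitude patterns under amplitude noise — not that it would
survive retention-drift misalignment, which real chromatograms exhibit.

Full-scale signal lengths are 9,000 (HPLC) and 1,869 (FTIR; fused
10,869). The package's own test and example regime uses 512 and 256
points with the same axes — peak widths then span only a few samples,
which is the harder, information-denser direction — so that the whole
suite runs in minutes on one CPU. The length is a constructor argument
everywhere.

## Stage 1: dual-branch VQ tokenizer

The signal is transformed with a one-sided STFT (periodic Hann window,
hop = window/2, centred zero-padding). Window length defaults to 64
samples for signals of ≥ 1,024 points and 16 otherwise, the smallest
power of two giving a non-trivial frequency axis at desk scale. The
spectrogram is split at `cutoff_bin = ⌈F/2⌉` into complementary
zero-padded low- and high-frequency parts; the split is an exact
partition, so the LF and HF time-domain components sum to the signal.

Each branch stacks real and imaginary parts as channels and passes
through a 3-layer 1-D convolutional encoder (two stride-2 layers, hidden
width 64) to latents of dimension d = 32 on a 4× coarser frame grid.
Latents are vector-quantized against a per-branch codebook of K = 64
entries — nearest Euclidean codeword, ties to the lowest index —
with straight-through gradients, and decoded by a mirrored convolutional
stack (nearest-neighbour 2× upsampling) back to spectrogram channels,
re-masked to the branch's band. Inverse STFT (synthesis-windowed
overlap-add normalised by the window-square envelope; exact for
consistent spectrograms) is implemented as a linear operator inside the
autodiff graph, so the time-domain reconstruction term is trained
directly.

Losses follow the standard VQ recipe: codebook terms pull codewords
toward (stopped) encodings, β-weighted commitment terms (β = 0.25, the
conventional weight) pull encodings toward (stopped) codewords, and the
reconstruction loss penalises squared error in both time and
time-frequency domains per branch. Logged losses use mean-per-element
reduction so magnitudes are comparable across signal lengths; the logged
total equals codebook + reconstruction exactly, and the reconstruction
column equals the sum of its LF and HF columns. Training is Adam
(learning rate 10⁻³, decoupled weight decay 10⁻⁵), batch 16, 1,000
iterations by default (400 in the test regime; the full-scale preset uses
5,000). The codebook is initialised from a 0.1-scaled normal and updated
by gradient (the codebook loss carries explicit codebook terms, so no
exponential-moving-average update is needed). The two branch
encoders/decoders are independent — the low- and high-frequency
statistics differ enough that weight sharing has no obvious benefit.

## Stage 2: masked-token transformer prior

The per-branch token grids are concatenated into one sequence (LF then
HF) with learned position and branch embeddings; a learned grade
embedding is added at every position, making generation class-
conditional. Joint modelling of both branches in one sequence preserves
LF–HF coherence; a sequential LF-then-HF decode is not needed for the
scales used here. The transformer is bidirectional: depth 2, width 64,
4 heads, GELU MLPs — the smallest stack that reliably learns the token
distributions of the desk-scale corpora.

Training masks a random fraction of tokens — the fraction is γ(r) =
cos(πr/2) at a progress r drawn uniformly per sample (a linear schedule
is available) — and minimises cross-entropy of the true tokens at the
masked positions only. The stage-1 tokenizer is frozen throughout;
a parameter hash asserts the contract.

Decoding starts fully masked and runs T = 10 iterations (temperature
1.0, optional linear annealing): every masked position is re-predicted,
a candidate token is sampled, and the most confident candidates are
committed so that the number of committed positions follows the inverse
schedule, ending complete at iteration T. A keep-one-per-step schedule
exists for exact accounting (then T must be at least the sequence
length). Committed positions are never revisited.

## Generation quality

The feature extractor is the canonical time-series FCN — three 1-D conv
blocks with 64/128/64 filters and kernels 8/5/3, global average pooling,
linear head — trained on the real cohort only (never on generated data).
The desk-scale variant strides the first two convolutions (4 and 2) so
the stack runs quickly on a CPU at length 512; with stride 1 the
per-iteration cost is ~8× higher with no measurable change in desk-scale
accuracy. Feature dimension is 64.

FID uses sample means and covariances (`ddof = 1`); the matrix square
root of Σ_x Σ_g is computed as Tr((Σ_x^½ Σ_g Σ_x^½)^½) via two symmetric
eigendecompositions with negative eigenvalues clipped at zero, falling
back to an ε·I (ε = 10⁻⁶) ridge if the result is non-finite. The
inception score uses 10 splits by default (its std column is the spread
across splits) and is computed on generated samples only, scored by the
real-trained FCN. PCA is on mean-centred, unscaled data with the
largest-magnitude-loading-positive sign convention; t-SNE uses
perplexity 15 (clipped to (n−1)/3) and a fixed seed.

## PLS-DA grading

Grades are one-hot encoded in the fixed column order (H, M, L); the
regression is NIPALS PLS2 (scikit-learn's `PLSRegression`, `scale=False`)
on mean-centred blocks, consistent with the no-preprocessing protocol.
Class prediction is arg-max over predicted indicator columns with ties to
the earlier class. The LV count is selected by stratified 10-fold CV over
1..15 candidates using the one-standard-error rule (plain arg-max
available); explained variance per LV uses the orthogonality of NIPALS
X-scores, so cumulative fractions are sums of per-LV terms and are
verified against a residual-based computation.

Per-grade metrics are one-vs-rest; note the per-grade ACC includes true
negatives and therefore differs from the overall multi-class accuracy
(confusion-matrix trace over total) — both are reported. Precision with
no positive predictions is defined as 0 with a warning; a grade absent
from the truth yields missing metrics, excluded from macro averages with
a warning. ROC curves are one-vs-rest on the predicted indicator columns.

Dataset partitioning keeps the real/generated bookkeeping explicit: the
real cohort is split with a largest-remainder stratified rule (35 of
137 by default, reproducing 102/35 train/test), generated samples are
allocated 7:3 the same way (630/270 of 900), and a `mixed_test` flag
chooses between the mixed test pool (732/305 protocol) and real-only
test evaluation. Real-only testing is the stricter reading — a mixed
test set partially scores the generator against itself — so the
package's own end-to-end study uses it, while the mixed protocol remains
available.

## End-to-end study conditions

The augmentation study in the test suite runs five seeds of: 20 real
chromatograms per grade at length 512, moderate class overlap (effect
0.6, noise 0.05, height jitter 0.3), a generator fitted on the real
training split only (400 stage-1 iterations, 300 prior steps), 200
generated samples per grade, PLS-DA with 6 LVs evaluated on the real-only
test split, and conditional fidelity measured by an FCN trained on all
real data. These sizes are the package's chosen desk-scale regime;
full-scale presets exist in `RunConfig.profile("full")`.

## Known limitations

- The autodiff engine is float64 and single-threaded; it is sized for
  desk-scale experiments, not for the full 9,000-point, 5,000-iteration
  regime (which the configuration exposes but which is days of CPU time).
- Codebook usage is not regularised (no EMA, no dead-code resurrection);
  at very small corpora some codewords go unused, which is harmless here.
- The generator is evaluated on synthetic cohorts whose variability is
  amplitude-only; conclusions about real chromatographic drift do not
  follow (see the generator section).
- t-SNE coordinates depend on scikit-learn's implementation details and
  are only reproducible within a fixed library version.
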