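# Methods

## The image encoding

An artificial image object (AIO) is a deterministic, invertible
arrangement of a fixed gene list onto image coordinates.  The gene list
is the intersection of the cohorts' gene symbols, sorted by chromosome
and transcription start site and truncated to the pixel capacity of the
chosen geometry.  Index arithmetic is 0-based, row-major within a
channel and channel-major across channels; this single convention
reproduces both published layouts (16,384 genes as 128×128×1 with the
first 128 genes forming the first row, or as 64×64×4 with 4,096 genes
per channel).  Chromosome order is numeric 1–22, then X, Y, MT, then
other contigs alphabetically; ties in (chromosome, TSS) break by symbol.
Under-full images zero-pad trailing pixels (configurable to an error);
overflow is always an error.

Intensities come from per-gene min–max rescaling of log2(FPKM + 1) to
integers 0–255 with round-half-to-even.  The scaler is fit on the
training cohort; applying it to an external cohort clips out-of-range
values to the byte range.  Constant genes map to 0.  The pseudocount
of 1 makes FPKM 0 → intensity contribution 0 and keeps the transform
exactly invertible; it is configurable.

Per-gene (rather than global) scaling discards each gene's absolute
expression level and keeps only its within-cohort variation — that is
what lets low- and high-expressed genes contribute on equal footing
without feature selection, but it also means a cohort-specific shift in
a gene's mean moves *all* of that gene's pixel intensities, which is why
cross-cohort shift is damaging and worth diagnosing (below).

## Classifiers

The 2D classifier has two branches merged by concatenation before four
fully connected layers (three hidden, one output).  The convolutional
branch is a compact VGG-style stack: six 3×3 convolution stages plus one
1×1 stage.  The embedding branch maps each discrete intensity (0–255)
to a learned vector and average-pools over pixel positions; because of
the average pooling this equals a linear map of the image's normalized
intensity histogram and is computed that way.  What the paper-described
architecture fixes is the layer counts and kernel sizes; everything else
is a `ModelSpec` parameter with package-chosen defaults:

| parameter | default (2D) | default (1D) | note |
|---|---|---|---|
| conv filters | 8, 8, 16, 16, 32, 32 | same | 1×1 stage: 64 |
| pooling | average, 2×2 after every 2nd stage | average, 4 | `pool_type="max"` available |
| batch norm | on (after each conv) | off | |
| conv-branch readout | global average pool | flatten | see below |
| dense widths | 128, 64, 32 | same | + output layer |
| embedding dim | 8 | 8 | `use_embedding=False` to disable |
| dropout (dense) | 0.25 | 0.25 | |
| L2 | 1e-4 | 1e-4 | per kernel |

The readout differs by mode deliberately.  After the 1×1 stage the 2D
branch takes a global spatial average: at the cohort sizes this package
targets (hundreds of samples), a flattened 2048-dimensional feature map
memorizes the training set, while the translation-invariant channel
summary generalizes.  The 1D branch keeps the positional flatten because
genome position is the one axis whose coordinates carry meaning.  These
defaults were chosen for small-cohort generalization on one CPU; filter
counts in the dozens are deliberately modest — the planted-signal
studies below showed no benefit from wider stacks.

Training uses Adam (configurable learning rate and epsilon), a
multiplicative per-epoch learning-rate decay (default 0.97 from 1e-3),
batch size 32, up to 30 epochs with early stopping (patience 8) on a
stratified 10% validation split, restoring the best-epoch weights
(including batch-norm running statistics).  All initialization,
shuffling, dropout and validation splitting flow from explicit seeds;
identical (spec, config, seed) reproduces identical weights bit-for-bit.
A non-finite loss aborts with a pointer to the learning rate.  Binary
calls use a strict p > 0.5 rule; multiclass calls are the argmax with
ties to the lowest class index.

## Evaluation protocol

Binary metrics evaluate the confusion-matrix formulas exactly; a ratio
with a zero denominator is reported as undefined (`None`), never as 0.
AUC is the Mann–Whitney statistic U/(n₁n₀) computed from average ranks,
so ties count one half.  Multiclass reports are one-vs-rest: the
per-class "accuracy" is that class's recall (the fraction of its samples
called correctly), the class AUC uses the class's probability column,
categorical accuracy is the fraction of correct argmax calls, and
weighted averages are Σ (class frequency × class metric) — for binary
tasks the weighted row coincides with the overall metric, and weighted
recall telescopes to categorical accuracy.

Cross-validation is stratified five-fold (fold assignment delegated to
scikit-learn behind the package's `CVPlan`, seed-controlled); held-out
predictions are pooled across folds and the metrics computed once on the
pooled set, with per-fold counts logged.  Repeated runs perturb the
training configuration (seeds by default) and report mean ± sd per
metric.  External testing fits one model on the full labeled training
cohort and scores an independent cohort; the gene orders must match
exactly, and the training-fit scaler is applied to the test cohort by
default (independent rescaling is a caller choice).

Dataset shift is diagnosed as the Pearson correlation of per-gene mean
log2 expression between two cohorts over their shared genes.  Matched
cohorts land near 1; values around 0.8 mark shift severe enough to
degrade transfer.

## The synthetic cohort generator

Real cohorts at this scale are controlled-access downloads, so testing
runs on simulated cohorts built to reproduce the two statistical
features the encoding is designed around: strong gene–gene correlation
and cross-cohort mean shift.

Genes split into contiguous blocks sharing a latent factor.  For sample
latents: a severity s ~ N(0,1) drives the labels — the binary label is
1{s > 0} and the three-level ordinal label thresholds s at (−0.43,
0.43), so labels are exactly recomputable from the stored latents.  The
effect size δ is the loading of s on the factors of the informative
blocks, f_b = (δ·s + η_b)/√(1+δ²); non-informative blocks use pure
noise factors.  Gene-level log2 expression is μ_g + σ_g(α·f_b +
√(1−α²)·ε), giving within-block gene–gene correlation exactly α², and
FPKM = max(2^x − 1, 0), so log2(x+1) preprocessing recovers the Gaussian
scale (exactly, except where the floor at zero bites low-mean genes).
δ = 0 is an exact null.  Defaults (600 samples, 4,096 genes in 64
blocks, α = 0.6, δ = 2, 20% informative blocks, per-gene means uniform
on log2-FPKM 2–9, sds 0.5–2) describe a strongly separable cohort whose
latent-sign Bayes accuracy is ≈ 0.955 — a deliberate regime: a correct
pipeline must score high, a broken one cannot hide.

Replicate cohorts (`simulate_replicate`) reuse the annotation, per-gene
means/sds, block structure and effect, drawing new subjects — emulating
a second dataset from the same assay (consistency r ≈ 0.999 at these
sizes).  Dataset shift adds independent per-gene offsets ν_g ~ N(0,
σ_ν²) on the log2 scale; by the attenuation identity r = sd_μ/√(sd_μ² +
σ_ν²), choosing σ_ν = sd_μ·√(1/r² − 1) lands the diagnostic at a target
r (verified: targets 0.8 and 0.99 measure within ±0.01 at 4,096 genes).
Survival times are exponential with hazard λ·HR^label (defaults λ =
5e-4/day, HR = 2) under independent exponential censoring whose rate is
solved from the requested censoring fraction; observed days are rounded
to integers ≥ 1.

What the generator does **not** emulate: realistic co-expression
networks or breast-cancer subtype structure, count noise, library-size
or batch effects within a cohort, informative censoring, or label error.
Passing tests therefore certify the pipeline's mechanics and its
behavior under the stated statistical structure — not clinical
performance on real cohorts.

## Survival analysis

Kaplan–Meier curves use the product-limit estimator; subjects censored
at an event time remain at risk for that event (the standard tie
convention).  The K-group log-rank test accumulates observed-minus-
expected event counts and the hypergeometric covariance at each distinct
event time, drops one group, and refers the quadratic form (via
pseudo-inverse, guarding all-tied degeneracies) to χ² with K−1 degrees
of freedom; for two groups this is (Σ(O−E))²/ΣV.  Comparing call
sources runs one test per source on disjoint subject sets — overlap is
a design error — and no multiple-comparison correction is applied.

## Numerical and design notes

- All tensors train in float32; metrics and probabilities are computed
  in float64.  Quantization to bytes is round-half-to-even.
- The permuted-label control is judged against the interval from
  0.5 − z₉₉·se to (majority-class rate) + z₉₉·se, since a label-blind
  classifier's accuracy legitimately sits anywhere between a coin flip
  and the majority vote.
- The study sizes used by the test suite and `scripts/acceptance.py`
  (600 × 4,096 cross-validation; 300-sample transfer experiments at ten
  seeds; 100–200 log-rank replicates) were chosen so each experiment
  carries clear statistical signal at desk scale.
- Known limitations: no GPU path; no augmentation or transfer learning
  (out of scope by design); the simulator's shift model perturbs only
  per-gene means, not variances or correlations; Ki67 dichotomization is
  fixed at the clinical 20% staining threshold.
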