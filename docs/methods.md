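# Methods

## Problem setting

Tumor expression cohorts are extreme small-n/high-p data: tens of samples,
10³–10⁴ genes, 2–4 classes. The package's pipeline is: (1) unsupervised gene
ranking and selection, (2) per-gene standardization, (3) stratified
train/test splitting, (4) sample expansion of the training part,
(5) training of a stacked autoencoder or 1-D CNN on the merged
expanded + raw rows, (6) scoring on held-out raw samples.

## Sample expansion

For corruption parameter `a`, one uniformly random permutation of the `m`
gene indices is chunked into consecutive groups of `a`; each of the first
`floor(m/a)` groups defines one corrupted copy of the sample with that
group's values set to exactly 0. Consequences, all property-tested:

- row count is `n × (floor(m/a) + 1)` including the raw rows;
- the corruption groups of one sample are pairwise disjoint, each of size
  exactly `a`; when `a ∤ m` the `m mod a` leftover indices of that
  permutation are never corrupted for that sample;
- every copy inherits the source label.

Corruption is applied **after** row normalization, so a zeroed entry sits at
the gene's training mean — the same convention as masking noise on
standardized inputs in denoising autoencoders. Corruption groups are drawn
once per expansion, not redrawn per epoch; each expanded set is saved with
provenance (source sample, corrupted indices) and round-trips through CSV.

## Gene ranking (Inf-FS)

Genes are vertices of a fully connected graph with edge weights

    A_ij = α · max(σ̂_i, σ̂_j) + (1 − α)(1 − |ρ_ij|),

σ̂ the per-gene SD rescaled by the maximum SD (making the two terms
commensurate), ρ the Spearman correlation, α = 0.5. A gene's score sums
weighted paths of all lengths: with r = r_fraction/ρ(A), r_fraction = 0.9,

    score_i = Σ_j [(I − rA)^{-1} − I]_ij,

the closed form of the geometric series Σ_l (rA)^l, which converges since
r·ρ(A) < 1. A test checks the closed form against the explicitly summed
series (400 terms; the tail decays as 0.9^l, so ~200 terms are needed for
1e-8 agreement). The coefficients above are one published formulation of
the graph-weighting idea; because variants exist, a plain variance ranking
(`--selector variance`) is provided as a transparent fallback. Selection is
unsupervised and applied before splitting; note that it also *orders* genes
by score, which places correlated high-dispersion genes near each other —
the 1-D CNN benefits from this local structure.

## Normalization

Each gene row is mapped to mean 0, SD 1 using the population SD (divide by
n); constant rows map to 0, the limit of the transform's intent. By default
the statistics are fitted on the training columns of each split and applied
to the test columns, avoiding leakage; `--normalize-all` fits on the whole
matrix for users who prefer the simpler convention. Selection precedes
normalization.

## SESAE

Tied-weight autoencoders: encode `y = σ(Wx + b_y)`, decode
`z = σ(Wᵀy + b_z)` — one W per layer, used transposed in the decoder for
dimensional consistency. Pretraining minimizes the batch-mean squared
reconstruction error `½‖x − z‖²` by full-batch gradient descent; MSE is the
appropriate reconstruction loss for real-valued standardized inputs. Layer
2 is pretrained on layer-1 codes; decoders are then discarded and a softmax
head (cross-entropy) is fine-tuned jointly with the encoders. Cross-entropy
is the standard pairing for a classification head and keeps gradients
well-scaled; a sigmoid + squared-error head (`head="squared"`) exists for
strict symmetry with the CNN's loss. Weight init: uniform
±4·√(6/(fan_in+fan_out)) for sigmoid layers, biases 0, seeded. Defaults:
η = 0.1, 100 pretraining + 200 fine-tuning epochs, full batch (training
sets here are ≤ ~10⁴ rows of ≤ 500 values).

## SE1DCNN

Seven layers: input m1 genes → C1 (k1 valid cross-correlations, length w1,
ReLU) → M1 (non-overlapping max pool p1, argmax retained) → C2 (k2 kernels
over all k1 channels — full connection table, the modern default) → M2 →
fully connected (m6 ReLU units) → C sigmoid outputs. Sigmoid outputs pair
with the squared-error loss `½Σ(t − y)²` (one-hot targets, mean over the
batch): the output sensitivity is then `δ = f′(u)∘(y − t)` and all updates
follow the plain delta rule (no momentum or adaptive optimizers). Pooling
routes gradients to the argmax position (first position on ties); a test
verifies the routed deltas conserve mass per window. Cross-correlation (no
kernel flip) is the convolution convention; learned kernels absorb the
difference. The published case-study configurations use w = 21 and p = 4
in both stages (configs/), giving the 500 → 480 → 120 → 100 → 25 length
chain; m6 is not part of those tables and defaults to 100. Defaults:
η = 0.05, 200 epochs, full batch — but see the learnability note below.

Every analytic gradient (autoencoder, classifier head, all eight CNN
tensors) is checked against central finite differences (ε = 1e-5, relative
error < 1e-5) — the single most load-bearing test of the backpropagation
algebra.

## Evaluation protocol

One evaluation = `repeats` (default 10) stratified splits: per class of
size n_c, `ceil(0.2·n_c)` samples train, the rest test. Ceiling rounding is
forced by the expansion row counts this produces (5 training samples from
classes {8, 12}; 13 from {12, 20, 10, 18} or {22, 40}). Accuracies are
reported per repeat and pooled (total correct / total predictions) in
percent with two decimals. A repeated-split design is used rather than
literal k-fold partitioning because a fixed 20%-per-class training fraction
is incompatible with disjoint folds; both the fraction and the repeat count
are configurable. `expand_all` mode instead expands the held-out samples
too and scores the model on their corrupted rows (testing whether corrupted
samples are still recognizable). All randomness (splits, corruption,
weight init) derives from one master seed via spawned seed sequences; runs
are exactly reproducible.

## Synthetic data

Gene g has baseline μ_g ~ N(0, baseline_sd²); sample j's value is
μ_g + shift + N(0, noise_sd²), where shift = effect_size·noise_sd if gene g
is informative for sample j's class (each informative gene is assigned one
class, cycling so every class receives signal). Defaults: effect_size 2.0
(a clearly separable but not degenerate two-group difference), 50
informative genes (≈10% of a 500-gene panel, a realistic DE fraction),
noise_sd = baseline_sd = 1. A log-normal flag exponentiates values for
positive intensity-like scales; the pipeline standardizes per gene, so
location/scale are immaterial. The generator draws i.i.d. noise per gene —
it emulates the *shape* of microarray cohorts, not their correlation
structure (co-expression modules, batch effects, probe saturation are
absent). Passing tests therefore demonstrate correctness of the machinery
and learnability of clean signal, not expected accuracy on real tumors.

## Learnability test conditions

The end-to-end check generates 2000 genes (100 informative, effect 3.0),
selects 500 by Inf-FS, splits classes {8, 12} 20/80 (5 train / 15 test),
expands with a = 2, and compares SE1DCNN against the plain 1DCNN on ten
seeded repeats, plus SESAE against the majority class. Problem and model
sizes (CNN k1 = k2 = 4, m6 = 32, minibatch 32, 10 epochs, η = 0.02; SAE
[50, 50], 30 + 60 epochs) are deliberately modest so the whole suite runs
in about a minute on one CPU. The optimizer settings matter here: with only
5 distinct raw profiles and i.i.d. noise genes, full-batch descent at a
large step memorizes the training set before learning the signal, whereas
small minibatches generalize — on real, correlated data this failure mode
is far weaker. Sample expansion is what rescues the CNN in this regime:
pilot runs of the frozen protocol give pooled test accuracy ≈ 67% for
SE1DCNN vs ≈ 53% for the plain 1DCNN (majority class 60%), with
SE ≥ plain in 8/10 repeats, and SESAE reaches 100%.

## Known limitations

- Accuracies on the three public microarray case studies are not asserted
  anywhere: they require the external datasets and unpublished training
  hyperparameters. The shipped configs transcribe the published layer
  shapes only.
- The Inf-FS edge-weight coefficients are a reconstruction of the cited
  method's published idea, not a transcription from this pipeline's source;
  the variance selector is the escape hatch.
- The sigmoid/squared-error CNN head is faithful to the original design but
  slow to escape saturation; practitioners wanting raw performance would
  swap in softmax/cross-entropy (available for the SAE head).
- Constant genes get dispersion 0 and Spearman ρ = 0 by convention; inputs
  with missing values must be imputed (per-gene median flag) or rejected.
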