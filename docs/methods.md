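# Methods

This note documents the models, conventions and numerical choices behind
branchnet, what the synthetic study system does and does not emulate, and the
known limitations.

## Coordinates and formats

All genomic coordinates inside the package are 0-based, half-open
(BED-native). Readers convert on entry and writers on exit: WIG fixedStep /
variableStep positions are 1-based on disk and shifted by −1 on read;
bedGraph intervals are already half-open and are expanded per base. The BED
score column is ignored; class identity comes from which file an interval was
read from (one BED per class). Conservation lookups never fail — bases absent
from the track score 0.0, the neutral phyloP value.

## Window normalisation

Intervals are extended or trimmed to the configured window length
(default 150 nt, a standard choice for RNA–protein interaction models and
near the practical upper bound for reliable secondary-structure prediction)
around their midpoint: `start' = (start+end)//2 − window//2`,
`end' = start' + window`. Both floors are deliberate so results are
bit-reproducible. A normalised window that would leave `[0, chrom_length)` is
dropped and counted, not clipped: clipping would reintroduce the
variable-length inputs the extend/trim strategy exists to avoid, and padding
could let the network learn the padding artifact instead of the biology.

## Branch encodings

* **Sequence** — one-hot over the fixed column order A, C, G, T; U is read
  as T; N encodes to an all-zero row. The all-zero row coincides with the
  attribution zero baseline, so unknown bases receive exactly zero
  attribution by construction.
* **Structure** — the window's sequence is folded to a dot-bracket string and
  one-hot encoded over the column order `(`, `.`, `)`. Two folding engines
  share the contract (length preserved, brackets balanced): `vienna` shells
  out to RNAfold (minimum free energy), and the built-in engine is a
  base-pair-maximisation dynamic program (AU/GC/GU pairs, minimum hairpin
  loop of 3 unpaired bases; a pair (i, j) requires j − i > 3). Its traceback
  prefers the unpaired case and then the smallest pairing-partner index, so
  the structure is deterministic. The pair-count optimum is verified against
  exhaustive enumeration in the tests. A three-channel bracket one-hot was
  chosen over a two-state paired/unpaired encoding because it preserves pair
  directionality at negligible cost; this was a genuinely open design point.
* **Conservation** — per-base scores used raw, with no normalisation: phyloP
  scores are already centred at 0 and their sign is meaningful (positive =
  conserved, negative = fast-evolving). On '−'-strand intervals the score
  vector is reversed so it stays co-oriented with the reverse-complemented
  sequence.

Strand handling: '−'-strand intervals contribute the reverse complement of
their genomic sequence, and the tests assert the resulting encoding equals
the row-reversed, A↔T/C↔G column-permuted '+' encoding.

## Balancing and splitting

Class reduction downsamples a class uniformly without replacement to an
absolute size n (capped at the class size — never upsampled) or a ratio
r ∈ (0, 1], keeping original sample order. Splits produce four subsets;
train/validation drive optimisation, evaluation is scored immediately after
training, and the black-box subset is never touched until a final audit.
Random splits are stratified per class: validation/evaluation/black-box take
`floor(ratio · n_class)` samples of each class and train takes the
remainder, so every subset's class mix matches the whole within one sample
per class (the default ratios are 70/15/10/5). Whether to stratify was an
open point; stratification was chosen because at the few-hundred-sample
scale of typical experiments an unlucky unstratified split measurably skews
validation metrics. Chromosome splits route every sample by its chromosome
and refuse unassigned chromosomes, making subsets chromosome-disjoint by
construction.

## The network engine

No TensorFlow-class dependency is used; the backend is a small numpy engine
with exact analytic backpropagation, written so that gradients with respect
to the *inputs* — required by Integrated Gradients — are first-class.

Conventions, fixed for reproducibility:

* Convolutions: stride 1, 'same' padding (left pad `(k−1)//2`), ReLU.
* Hidden dense layers: ReLU. The output layer is linear + softmax with one
  unit per class; training minimises categorical cross-entropy.
* Batch normalisation (when flagged) sits between the affine map and its
  activation; dropout (inverted, seeded) after the activation.
* Recurrent layers (GRU or LSTM; LSTM forget-gate bias initialised to 1)
  return the full sequence except the last recurrent layer of a section,
  which returns its final step. The bidirectional wrapper concatenates the
  forward cell's last step with the backward cell's output at the original
  first time point.
* No pooling layers are inserted: with 150-nt inputs and the small filter
  counts used here, resolution loss buys no measurable speed.
* Weights are Glorot-uniform initialised from a single seeded generator
  consumed in a fixed branch order, so two builds from the same (spec, seed)
  agree parameter-by-parameter, and a full training run is reproducible from
  (data, spec, training config, seed).

Optimizers: SGD with Nesterov momentum fixed at 0.9, RMSprop (ρ=0.9), Adam
(β₁=0.9, β₂=0.999), all at the user's learning rate. With SGD two schedules
are available; their exact parameterisation is a package choice, recorded
here and in the run config:

* `scheduler`: step decay in thirds of the run,
  `lr(e) = lr₀ · 0.1^⌊e / ⌈E/3⌉⌋`.
* `one_cycle`: over the global step fraction f, a linear ramp lr₀/10 → lr₀
  for f ∈ [0, 0.45], linear decay back to lr₀/10 for f ∈ (0.45, 0.9], and a
  linear anneal to lr₀/1000 over the final 10%.

Early stopping monitors the validation loss (the trained objective, rather
than accuracy): if it fails to improve on the running best by more than
`min_delta` for `patience` consecutive epochs (defaults 0.01 and 10),
training stops and the best epoch's weights are restored.

## Evaluation

Multi-class ROC and precision–recall are computed one-vs-rest per class,
using that class's softmax probability as the score, plus a micro-average
over the pooled (label, score) pairs of all classes. The curve code wraps
scikit-learn's threshold sweep (one point per distinct score, descending);
areas are trapezoidal. The tests verify `auc(roc_curve(·))` equals the
pairwise Mann–Whitney statistic with ties half-credited, to 1e-9.

One subtlety worth recording: for two classes, the per-class AUROCs are
always equal (complementary scores flip both labels and scores), but the
pooled micro-average is *not* in general equal to them — pooling adds
cross-sample comparisons between a sample's probability and another
sample's complementary probability, which measure calibration against the
0.5 threshold rather than ranking. The two coincide exactly when the scorer
is 0.5-threshold-consistent, which is what the test asserts.

Predictions are never thresholded into a single class label; the export
carries all K probabilities (6 decimals) with the argmax highlighted, ties
going to the lowest class index.

## Integrated Gradients

Attribution of input element i toward class c is

    (x_i − x'_i) · (1/m) Σ_{k=1..m} ∂F_c(x' + α_k (x − x')) / ∂x_i ,

with zero baseline x' in every branch (zero is also the neutral conservation
score), a path shared by all branches, default m = 50, and F_c the
*pre-softmax logit*: the softmax saturates, so its gradient vanishes exactly
where the model is most confident, while the logit stays informative.

The path positions are midpoints, α_k = (k − ½)/m. This is a deliberate
numerical choice: a one-sided Riemann sum carries a systematic
(h(1) − h(0))/2m endpoint term (h the path derivative of F), which for these
ReLU networks was measured to decay only as O(1/m) and to dominate the
completeness residual — the midpoint rule cancels it, leaving only the
fluctuation from ReLU kinks crossing quadrature cells, orders of magnitude
smaller at the same cost. The residual of any quadrature is noisy per sample
(it depends on how kinks align with the grid), so refinement claims should
be read on residuals averaged over samples.

Every call computes the completeness residual
`|Σ attributions − (F(x) − F(x'))|` and warns when it exceeds
`max(tol · |F(x) − F(x')|, 1e-4)` (tol default 1e-3); the residual is also
stored on the result so users always see the approximation quality. A
caution on the relative reading: the softmax identifies only logit
*differences*, so a trained network may park one class's logit near its
baseline value — the residual relative to that logit's span is then
meaningless, and the absolute floor governs.

Per-position scores are channel sums of the L×C attribution matrix; display
normalisation divides by the maximum absolute value (sign preserved:
positive renders red, negative blue). The report renders the top-10
predictions per class (ties to the lower sample index) as per-position
heatmaps, alongside raw per-channel TSVs.

## The synthetic study system

The fixtures module generates the study conditions all tests and the
acceptance script run under: chr1..chrN of i.i.d. uniform A/C/G/T bases
(default 4 × 100 kb); candidate windows on a fixed grid with spacing equal
to the window length (which makes non-overlap and the capacity check exact);
1,000 windows per class by default; the 7-mer TGCATGC written into the
reference at each positive window's centre; negative windows chosen to
contain no occurrence of the motif (or its reverse complement) even by
chance. The conservation track is Gaussian noise (σ = 0.5) at every base
plus a +2.0 elevation over positive-class motif bases — roughly the contrast
between neutral background and a strongly conserved element in vertebrate
phyloP tracks. An optional flag plants a fraction of windows on the '−'
strand (motif reverse-complemented) to exercise strand handling, and the
`motif_in_negatives` variant plants the motif in *both* classes so that the
conservation track carries the only class signal — the probe used to
demonstrate the value of the conservation branch.

What the fixture does **not** emulate: realistic CLIP-seq peak shapes,
motif positional jitter or degeneracy (the motif is exact and always
centred), realistic phyloP score distributions (real tracks are skewed and
autocorrelated), structure-driven class signal, and genomic sequence
composition (no repeats, no GC structure). Passing tests therefore
demonstrate the *machinery* — encodings, optimisation, metrics, attribution
— under a recoverable planted signal, not performance on real data.

## Problem sizes and defaults used in the shipped analyses

The test suite and `scripts/acceptance.py` use: 1,000 + 1,000 windows of
150 nt (the fixture defaults); a sequence branch of one conv layer
(16 filters, kernel 8) and a 16-unit dense common layer; a conservation
branch, where used, of one conv layer (8 filters, kernel 8); Adam at 1e-3,
batch 32, up to 30 epochs with early stopping (patience 10, min-delta 0.01).
These sizes train in seconds on one CPU while leaving the planted signal
comfortably recoverable (evaluation AUROC ≈ 1.0 for the sequence model;
≈ 0.5 without the conservation branch on the `motif_in_negatives` variant
and ≈ 1.0 with it). Oracle checks run at their natural sizes: 100 random
instances (n ≤ 50) for the ROC/Mann–Whitney identity and 200 random
sequences (length ≤ 12) for the folding enumeration.

## Known limitations

* Spliced (transcriptome) coordinate mapping is out of scope; intervals are
  taken on the reference as given.
* The built-in folder maximises pair count, not free energy; for
  structure-sensitive applications use the `vienna` engine.
* The engine is CPU-only and optimised for the small models this workflow
  targets; it is not a general-purpose deep-learning framework.
* bigWig conservation input is supported only when pyBigWig is installed;
  the tested baseline is the text dialects (WIG fixedStep/variableStep,
  bedGraph).
* Session-ledger concurrency is guarded by a lock file: a second concurrent
  writer fails loudly rather than merging.
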