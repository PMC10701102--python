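# Methods

## The problem

Genomic prediction (genomic selection) estimates a quantitative trait from
genome-wide SNP markers so that breeding candidates can be ranked without
waiting for phenotypes. The statistical difficulty is that marker count far
exceeds sample count, informative loci can be arbitrarily far apart on the
chromosome, and trait distributions are thin-tailed: most individuals sit
near the trait mean, so a model trained with a uniform loss underserves the
extreme individuals a breeder cares about most.

This package implements a sequence model for that problem: the SNP vector
of each individual is treated as a long ordered sequence with physical
coordinates, and attention over *lags* (rather than position pairs) is used
to aggregate information across the genome at O(L log L) cost.

## Network architecture

Input: an n x C x L array, with L the number of markers and C the
encoding channels — one channel of 0/1/2 dosage, or three one-hot
channels, optionally concatenated with three GWAS-weighted one-hot
channels (see below).

**Embedding.** A same-padded 1-D convolution (kernel `embed_kernel`,
default 3) maps the C input channels to `d_model` features per marker.
Sinusoidal positional features are added elementwise:

    pe_t[2k]   = sin(omega_k t),  pe_t[2k+1] = cos(omega_k t),
    omega_k    = 1 / 10000^(2k / d_model),

with t the physical base-pair coordinate of the marker (or the marker
index when `index_positions` is set or no map exists). Positions up to
10^8 bp are used verbatim; the encoding is evaluated in double precision,
where sin/cos of arguments of order 10^8 still carry ~1e-8 relative phase
error — far below the feature scale, so raw coordinates are safe.

**Autocorrelation attention.** For query/key sequences Q, K (both equal to
the block input here), per-lag scores are the circular cross-correlation

    AR(tau) = sum_s Q[(s + tau) mod L] * K[s],

computed via real FFT as irfft(rfft(Q) * conj(rfft(K))) and averaged over
feature channels. The k = max(1, floor(c * ln L)) highest-scoring lags are
selected per sample (ties toward the smaller lag), their scores pass
through a softmax, and the output is the weighted sum of circularly
rolled value sequences: sum_j w_j * roll(V, tau_j). The natural logarithm
is used in k, following the convention of decomposition transformers; c
defaults to 2.

**Encoder block.** One block consumes exactly: one attention layer, two
series-decomposition layers, one pointwise (kernel-1) convolution, one
LayerNorm, two GELU activations and two dropout layers, wired as

    a  = dropout(gelu(attention(x, x, x)))
    s1 = residual(decomp(x + a))
    b  = dropout(gelu(conv1x1(s1)))
    s2 = residual(decomp(s1 + b))
    out = layer_norm(s2)        # learned gain and bias

Series decomposition subtracts a replicate-padded moving average (odd
window, default 25 markers): trend = AvgPool(Padding(X)), residual =
X - trend, with residual + trend = X exactly. GELU is the exact erf form;
the tanh approximation is provided separately for reference.

**Regression head.** The L x d_model features are flattened and mapped by
a single linear layer to one real value per individual.

## Focal MAE loss and optimization

    loss = (1/M) * sum_i (tanh(beta * |Y_i - Y'_i|))^gamma * |Y_i - Y'_i|

with beta = 0.5 and gamma = 1 by default. The tanh modulation down-weights
individuals whose error is already small — the abundant middle of a
Gaussian-shaped trait — and leaves large-error (rare, extreme) individuals
at nearly full weight; gamma = 0 recovers plain MAE exactly.

Optimization is Adam with initial learning rate 1e-4, weight decay 1e-5
(classic L2-in-gradient convention), batch size 32, and a per-epoch
exponential decay lr(e) = lr0 * lr_gamma^e. The decay rate is a free
choice here: with the small fixed lr0, a rate of 0.99/epoch freezes the
model within a few hundred epochs before convergence on small datasets,
so the default is lr_gamma = 0.999 and 100 epochs. Dropout defaults to
0.1. Parameters are fan-in-scaled Gaussian, seeded; training is
bit-reproducible given the seed.

The network runs in float64 by default, which keeps the op-level contracts
exact; `precision="float32"` halves memory traffic and is what the
cross-validated experiments use (measured to leave prediction quality
unchanged at three decimals on the reference conditions).

The engine behind these layers is a small reverse-mode autodiff over
numpy arrays (`gpformer.nn.autograd`), validated against central finite
differences. Top-k lag selection is treated as piecewise-constant (no
gradient through the argsort), the standard straight-through treatment of
hard selection.

## GWAS-guided encoding (knowledge-guided weighting)

A single-marker general linear model scan regresses the trait on each
marker's dosage and reports the slope F statistic with (1, n-2) degrees of
freedom and its p-value; monomorphic markers get non-numeric statistics.
External TASSEL-style statistics tables are accepted interchangeably.
Per-marker attention weights are

    w = -log10(max(P, 1e-20)) + F     (numeric P),     w = 1 otherwise.

The base 10 follows the GWAS "negative log P" convention (the formula's
log base is otherwise unspecified); the floor prevents infinite weights at
numerically-zero p-values. F is added on its raw scale, unnormalized —
implemented literally; note that F is unbounded, so for very strong
associations the F term dominates the log-p term. The weighted one-hot
encoding multiplies each marker's hot channel by w (missing stays
(0,0,0)), and the three weighted channels are concatenated with the base
channels ahead of the embedding convolution, so a w = 0 marker still
reaches the model through its unweighted base channel.

Inside cross-validation the scan runs on the training folds only; weights
computed on all samples would leak held-out phenotypes into the encoding.
A `full_data_weights` switch disables the guard for comparison with the
literal protocol of weighting on the whole dataset.

## Evaluation

5-fold cross-validation with a seeded uniform random partition; each fold
is held out once. Per fold: MAE, Pearson correlation (PCC), and the
consistent index

    CI = PCC / (MAE / mean(|y|) + 1),

which discounts trend accuracy by normalized numerical error; CI = PCC at
zero error, |CI| <= |PCC| always, larger is better. Metrics are computed
on the raw trait scale; by default training itself uses a z-scored target
(statistics from the training folds, predictions transformed back before
scoring) so that the fixed learning rate and focal beta are
scale-independent. Zero-variance inputs raise rather than return NaN.

## Synthetic data

The simulator provides the ground-truth datasets used by every test:

- Genotypes: per-marker allele frequency uniform in `maf_range`
  (default 0.1-0.5), Hardy-Weinberg genotype draws; local LD from a
  first-order copying process (each sample copies the previous marker's
  genotype with probability `ld_rho`, default 0.3). This produces tunable
  adjacent-marker correlation but is *not* a coalescent model: no
  long-range haplotype structure, recombination hotspots, or demography.
- Positions: sorted distinct uniform integers on [1, 1e8], exercising
  large-coordinate positional encodings.
- Traits: y = sum_j beta_j x_j + sum gamma_ab x_a x_b + eps with effects
  standard normal (or |beta| = 1 in the sparse-large-effect preset used
  for GWAS-power experiments), and eps scaled so the realized
  var(genetic)/var(y) equals the requested h2.
- One root seed; each stage draws from its own derived substream.
- When a missing rate is configured, `simulate_dataset` computes the trait
  from the complete genotypes first and masks calls afterwards — a trait
  exists regardless of which calls the assay drops — while the masked
  matrix stays bit-identical to the direct genotype generator at the same
  seed.

Reference study conditions (the simulator defaults): 400 samples, 500
markers, 20 additive QTL, h2 = 0.8. Passing results on these data show
the pipeline recovers planted additive signal and that GWAS weighting
helps when marker effects are sparse and large; they do not certify
performance on real crop panels, whose LD structure, allele-frequency
spectra and trait architectures are richer than this generator.

## Experiment sizes used by tests and the acceptance script

The cross-validated experiments use a compact configuration — d_model = 8,
one encoder block, c = 1, float32, 50 training epochs (25 on the smaller
sparse-trait comparison) — chosen once as the smallest configuration that
cleanly separates signal from a permuted-label control on the reference
conditions. The capacity check (16 samples, 32 markers, 500 epochs,
d_model = 16) verifies the network can memorize a tiny fixture, loss
falling below 10% of its initial value.

## Known limitations

- Mode imputation stands in for nearest-neighbour imputation; adequate at
  the low missing rates left after QC, crude above that.
- The internal GWAS provider is the plain GLM scan only — no kinship or
  structure correction; externally computed mixed-model statistics can be
  supplied instead.
- Single trait, additive + pairwise-epistatic architectures only; no
  dominance, no multi-trait correlations.
- The attention mechanism shares selected delays across feature channels;
  multi-head variants are not implemented.
- Sequence length is fixed at model construction (the flatten head is
  position-specific), so train and test data must share one marker panel.
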