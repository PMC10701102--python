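# gpformer

Genomic prediction from genome-wide SNP markers with a lag-attention
sequence model, GWAS-guided marker weighting, and a focal absolute-error
training objective.

## Who this is for

Breeders and quantitative geneticists who want to rank selection
candidates by predicted phenotype from a dense marker panel, and method
developers who need a self-contained, fully seeded genotype-to-metric
pipeline (simulation included) to experiment against.

## The model

Each individual's SNP vector (dosage 0/1/2 or one-hot, L markers with
physical coordinates) is embedded by a 1-D convolution plus sinusoidal
positional features pe_t built from the base-pair coordinate t with
frequencies ω_k = 1/10000^(2k/d_model). The encoder scores *lags* by the
FFT circular cross-correlation of query and key,

    AR(τ) = F⁻¹( F(Q) · F*(K) ),

keeps the top k = ⌊c·ln L⌋ delays, and aggregates softmax-weighted
circularly rolled copies of the value sequence — attention over the whole
genome at O(L log L). Each block also subtracts a moving-average trend
(series decomposition), applies a pointwise convolution, GELU, dropout
and LayerNorm; a flatten + linear head outputs the predicted trait.

Training minimizes the focal MAE

    loss = (1/M) Σᵢ (tanh(β·|Yᵢ−Y'ᵢ|))^γ · |Yᵢ−Y'ᵢ|,   β = 0.5, γ = 1,

with Adam (lr 1e-4, weight decay 1e-5, batch 32) and exponential
learning-rate decay. Prediction quality is reported as MAE, Pearson
correlation (PCC), and the consistent index

    CI = PCC / (MAE / mean(|y|) + 1),

a single number combining trend and numerical accuracy (CI = PCC at zero
error; larger is better).

Optionally, a knowledge-guided encoding turns association evidence into an
attention prior: a single-marker GLM scan (or an external TASSEL-style
stats table) gives each marker w = −log₁₀(P) + F (1 when untested), the
one-hot channels are scaled by w, and the weighted channels are
concatenated to the unweighted input. Inside cross-validation the scan is
restricted to training folds, so the encoding never sees held-out
phenotypes.

Everything runs on numpy with a small built-in reverse-mode autodiff
engine — no GPU or deep-learning framework required.

## Worked example

```python
import gpformer as gp

# 400 individuals, 500 markers, 20 additive QTL, heritability 0.8
cfg = gp.SimConfig(seed=1)
g = gp.simulate_genotypes(cfg)
y, truth = gp.simulate_phenotype(g, cfg)

report = gp.kfold_cv(
    g, y,
    gp.ModelConfig(d_model=8, c_factor=1.0, precision="float32"),
    gp.TrainConfig(epochs=50, seed=1),
)
print(report.to_frame().to_string(index=False))
```

prints (about three minutes on one CPU core):

```
fold      MAE      PCC       CI
   0 2.513188 0.350450 0.176845
   1 2.468322 0.469654 0.242589
   2 2.482534 0.464520 0.243959
   3 2.758420 0.296042 0.143911
   4 2.204447 0.330459 0.171671
mean 2.485382 0.382225 0.195795
```

A mean PCC near 0.38 at h² = 0.8 means the model recovers a solid share
of the simulated genetic signal from 320 training individuals per fold
(the square root of h² bounds attainable PCC at ≈0.89); CI discounts that
correlation by the normalized MAE. A label-permuted control on the same
data stays near zero. The same pipeline is available from the shell:

```sh
gpf simulate --config sim.yaml --out data/
gpf qc data/genotypes.csv --maf-min 0.05 --miss-max 0.1 --out data/qc.csv
gpf gwas data/qc.csv data/phenotypes.tsv --out data/stats.tsv
gpf cv data/qc.csv data/phenotypes.tsv --k 5 --use-kgm --out results/
```

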