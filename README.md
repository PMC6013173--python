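# boearch

Modelling the **breadth of expression (BoE)** of human transcripts from the
**transcription-factor composition of their proximal promoters**.

Housekeeping transcripts are expressed almost everywhere; tissue-specific
transcripts in only a few cell types. This package asks how much of that
difference is encoded in the promoter itself: the multiset of TF binding
sites (ChIP-seq peaks) falling within ±500 bp of the transcription start
site. It is written for computational biologists working with
ENCODE-style merged peak calls and FANTOM5-style CAGE expression tables,
and for anyone who wants a fully tested, simulation-backed version of this
kind of promoter-architecture analysis.

## The model

For transcript *i*, BoE is recoded as a binomial response: the number of
samples *k<sub>i</sub>* (out of *n* = 1660 expression libraries) in which
the transcript exceeds 10 TPM. With *x<sub>ij</sub>* the number of
strong binding sites (quality score > 500) of TF *j* in the promoter
window of transcript *i*, the core model is a quasibinomial GLM with
logit link:

```
k_i ~ Binomial(n, p_i),   logit(p_i) = θ0 + Σ_j θ_j x_ij,   Var ∝ φ
```

Around this sit the rest of the family: lasso / ridge / elastic-net paths
with cross-validated λ, a Bayesian GLM with N(0, 10) priors, a
pairwise-interaction extension, a deviance-partitioning regression tree,
a per-TF regulatory-logic classifier (activating / inhibitory /
saturating, from mean BoE stratified by site count with Wilcoxon support),
k-means transcript clustering in the (architecture size, BoE) plane, a
random-forest benchmark with out-of-bag permutation importance, and a
permutation null for TF–TF Spearman correlations with VIF-based
collinearity pruning. A synthetic-data generator reproduces the
statistical structure of the real inputs (≈95 % sparse count matrix,
≈27 % empty architectures, near-duplicate TF columns) with known ground
truth, so every estimator is tested for recovery, not just for running.

## Worked example

```python
import boearch
from boearch.synthetic import SimulationConfig, default_tf_effects, simulate_dataset

cfg = SimulationConfig(n_transcripts=3000, n_tfs=10, n_samples=1660,
                       sparsity=0.8, empty_fraction=0.25, seed=3)
cfg.tf_effects = default_tf_effects(cfg.tf_labels, seed=3, prop_saturating=0)
truth = simulate_dataset(cfg)

fit = boearch.fit_quasibinomial(truth.count_matrix, truth.response)
print(f"phi = {fit.dispersion:.2f}")
print(f"intercept {fit.intercept:+.2f} -> basal BoE "
      f"{boearch.inverse_logit(fit.intercept):.2f}")
```

prints

```
phi = 0.98
intercept -2.00 -> basal BoE 0.12
```

φ ≈ 1 says the binomial error model fits (no overdispersion beyond what
was simulated); the intercept recovers the planted −2, i.e. transcripts
with *empty* promoter architectures are expressed in about 12 % of
samples — the basal level attributable to factors outside the assayed TF
panel. The scripts in `examples/` walk through each capability
(integration from files, correlation/VIF analysis, the model family, tree
and logic classification, clustering and the dual-promoter enrichment
test) and print the numbers they compute with a line on what they mean.

A thin CLI mirrors the library for shell pipelines:

```bash
boearch simulate --config sim.cfg --seed 1 --out inputs/
boearch build --peaks peaks.bed --tss tss.tsv --expr expr.tsv --out build/
boearch run --config sim.cfg --seed 1 --out artifacts/
```

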