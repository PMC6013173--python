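"""Regression tree and per-TF regulatory-logic classification.

Fits the deviance-partitioning tree of BoE on presence/absence TF
predictors (every split lands at 0.5) and classifies each TF as
activating, inhibitory or saturating from the per-site-count strata.
"""

from boearch.logic import classify_matrix
from boearch.synthetic import SimulationConfig, TfEffect, simulate_dataset
from boearch.tree import fit_tree, render_tree

cfg = SimulationConfig(n_transcripts=8000, n_tfs=6, n_samples=400,
                       sparsity=0.6, empty_fraction=0.1, seed=4)
cfg.tf_effects = {
    "TF001": TfEffect("activating", 0.5),
    "TF002": TfEffect("activating", 0.3),
    "TF003": TfEffect("inhibitory", -0.6),
    "TF004": TfEffect("saturating", 0.8, -1.8),
    "TF005": TfEffect("activating", 0.15),
    "TF006": TfEffect("activating", 0.1),
}
truth = simulate_dataset(cfg)
P, boe = truth.count_matrix, truth.response.boe

tree = fit_tree((P > 0).astype(int), boe, max_depth=2)
print(render_tree(tree))

calls = classify_matrix(P, boe)
cols = ["mean_0", "mean_1", "mean_2", "mean_3", "effect"]
print(calls[cols].round(2).to_string())
# The tree picks the strongest activator first; the strata table shows
# mean BoE rising with activating site counts, falling for the repressor,
# and rising-then-dropping for the saturating TF.
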