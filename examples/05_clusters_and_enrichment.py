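"""Transcript clusters in the (architecture size, BoE) plane, plus the
dual-polymerase promoter enrichment test.

k-means with k = 3 separates tissue-specific, housekeeping and atypical
transcripts; the Fisher test reproduces the Pol II enrichment of dual
Pol II-Pol III promoters from its 2x2 counts.
"""

import pandas as pd

from boearch.cluster import cluster_summary, cluster_transcripts
from boearch.comparison import Contingency2x2, fisher_enrichment
from boearch.integration import architecture_size
from boearch.synthetic import default_config, simulate_dataset

truth = simulate_dataset(default_config(n_transcripts=8000, n_tfs=40, seed=5))
P, boe = truth.count_matrix, truth.response.boe

size = architecture_size(P, mode="raw")
res = cluster_transcripts(size.to_numpy(), boe, seed=5)
summary = cluster_summary(res, boe, {"size": size.to_numpy()})
print(summary[["n", "boe_mean", "size_mean"]].round(2).to_string())

counts = Contingency2x2(32, 2, 16_913, 13_846)
enrich = fisher_enrichment(counts)
print(f"\ndual Pol II-Pol III promoters: odds ratio "
      f"{enrich.odds_ratio:.1f}, Fisher exact p = {enrich.p_value:.1e}")
mc = fisher_enrichment(counts, mc_replicates=2000, seed=5)
print(f"Monte Carlo p over 2000 fixed-margin tables: {mc.p_value:.1e}")
# Housekeeping transcripts combine the largest architectures with the
# broadest expression; the 2x2 test shows dual promoters are ~13x
# enriched in Pol II peaks.
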