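"""Per-TF regulatory logic: activating, inhibitory or saturating.

Transcripts are stratified by the exact number of binding sites of one TF
(0, 1, 2, 3; counts above three pooled into the 3 stratum) and the mean
BoE per stratum is examined.  A monotone increase is activating, a
monotone decrease inhibitory; a rise from 0 to 1 site followed by a
statistically significant drop (two-sample Wilcoxon rank-sum) at two
sites is saturating.  A mean dip that fails the Wilcoxon test does not
override an activating call.  Strata with three or fewer transcripts are
too small to enter the classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

MIN_STRATUM = 3  # strata need more than three transcripts to count
MAX_COUNT = 3


@dataclass
class LogicStrata:
    """Per-site-count strata of one TF column."""

    means: dict[int, float]
    sizes: dict[int, int]
    values: dict[int, np.ndarray]

    def eligible(self) -> list[int]:
        return [c for c in sorted(self.sizes) if self.sizes[c] > MIN_STRATUM]


@dataclass
class LogicCall:
    """Classification of one TF with its supporting test p-values."""

    cls: str  # activating | inhibitory | saturating | unclassified
    wilcoxon_p: dict[tuple[int, int], float] = field(default_factory=dict)
    reason: str = ""


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided two-sample Wilcoxon rank-sum p-value with continuity
    correction; exact by enumeration for small tie-free samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def stratify(column: np.ndarray, boe: np.ndarray) -> LogicStrata:
    """Group per-transcript BoE by the TF's site count (0-3, >3 pooled)."""
    counts = np.minimum(np.asarray(column, dtype=np.int64), MAX_COUNT)
    boe = np.asarray(boe, dtype=float)
    if counts.shape != boe.shape:
        raise ValueError("column and response must align")
    means, sizes, values = {}, {}, {}
    for c in range(MAX_COUNT + 1):
        sel = boe[counts == c]
        if len(sel):
            means[c] = float(sel.mean())
            sizes[c] = int(len(sel))
            values[c] = sel
    return LogicStrata(means, sizes, values)


def classify(strata: LogicStrata, alpha: float = 0.05) -> LogicCall:
    """Call the regulatory logic from eligible strata (size > 3)."""
    elig = strata.eligible()
    if len(elig) < 2:
        return LogicCall("unclassified", reason="fewer than two eligible strata")
    means = [strata.means[c] for c in elig]
    diffs = np.diff(means)

    if np.all(diffs >= 0):
        return LogicCall("activating")
    if np.all(diffs <= 0) and means[1] < means[0]:
        return LogicCall("inhibitory")

    pvals: dict[tuple[int, int], float] = {}
    if means[1] > means[0]:
        # rise then dip: saturating only if some dip is significant
        for i in range(1, len(elig)):
            lo, hi = elig[i - 1], elig[i]
            if strata.means[hi] < strata.means[lo]:
                p = wilcoxon_rank_sum(strata.values[hi], strata.values[lo])
                pvals[(lo, hi)] = p
                if p < alpha:
                    return LogicCall("saturating", pvals)
        return LogicCall("activating", pvals)
    return LogicCall("unclassified", pvals, reason="non-monotone without initial rise")


def classify_matrix(P, boe: np.ndarray, alpha: float = 0.05):
    """Stratify and classify every TF column; returns a tidy DataFrame in
    the TF / mean(n) per stratum / effect shape."""
    import pandas as pd

    rows = []
    for label in P.columns:
        strata = stratify(P[label].to_numpy(), boe)
        call = classify(strata, alpha)
        row = {"tf": label, "effect": call.cls}
        for c in range(MAX_COUNT + 1):
            if c in strata.means:
                row[f"mean_{c}"] = strata.means[c]
                row[f"n_{c}"] = strata.sizes[c]
            else:
                row[f"mean_{c}"] = np.nan
                row[f"n_{c}"] = 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("tf")
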