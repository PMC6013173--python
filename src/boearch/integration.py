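"""Data integration: expression -> BoE, TSS + peaks -> count matrix.

Breadth of expression (BoE) for a transcript is the number of samples in
which it exceeds the TPM cutoff (strictly), over the number of samples.
Promoter architectures are multisets of TF binding sites: QS-filtered peaks
whose midpoint falls inside the symmetric promoter window around the TSS.
Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import (
    BoEResponse,
    CountMatrix,
    GenomicInterval,
    PeakRecord,
    TssRecord,
)

logger = logging.getLogger(__name__)

DEFAULT_TPM_CUTOFF = 10.0
DEFAULT_QS_CUTOFF = 500
DEFAULT_HALF_WIDTH = 500


def compute_boe(expr: pd.DataFrame, tpm_cutoff: float = DEFAULT_TPM_CUTOFF
                ) -> BoEResponse:
    """Count, per transcript, the samples with TPM strictly above the cutoff.

    A cell exactly at the cutoff counts as not expressed.
    """
    if tpm_cutoff <= 0:
        raise ValueError("tpm_cutoff must be positive")
    if expr.empty:
        raise ValueError("empty expression table")
    successes = (expr.to_numpy() > tpm_cutoff).sum(axis=1)
    return BoEResponse(list(expr.index.astype(str)), successes, expr.shape[1])


def collapse_redundant(tss: list[TssRecord]) -> list[TssRecord]:
    """One transcript per (chrom, strand, tss): transcripts sharing a TSS
    share a promoter and would be redundant rows.  The representative is the
    lexicographically smallest transcript id; output is sorted by genomic
    position then id, hence deterministic."""
    best: dict[tuple[str, str, int], TssRecord] = {}
    for rec in tss:
        key = (rec.chrom, rec.strand, rec.tss)
        cur = best.get(key)
        if cur is None or rec.transcript_id < cur.transcript_id:
            best[key] = rec
    return sorted(best.values(),
                  key=lambda r: (r.chrom, r.tss, r.strand, r.transcript_id))


def promoter_window(t: TssRecord, half_width: int = DEFAULT_HALF_WIDTH
                    ) -> GenomicInterval:
    """Symmetric half-open window [tss - w, tss + w), clipped at zero.
    Strand does not alter the window."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    return GenomicInterval(t.chrom, max(0, t.tss - half_width), t.tss + half_width)


def filter_peaks_by_qs(peaks: list[PeakRecord], qs_cutoff: int = DEFAULT_QS_CUTOFF
                       ) -> list[PeakRecord]:
    """Keep peaks with quality score strictly above the cutoff."""
    return [p for p in peaks if p.qs > qs_cutoff]


def build_count_matrix(
    peaks: list[PeakRecord],
    windows: list[GenomicInterval],
    transcripts: list[str],
) -> CountMatrix:
    """x_ij = number of peaks of TF j whose midpoint lies in window i.

    Multiplicities are preserved (architectures are multisets).  A peak
    whose midpoint falls in several overlapping windows counts in each.
    Peaks on chromosomes absent from the annotation are ignored and counted
    in a log message.
    """
    if len(windows) != len(transcripts):
        raise ValueError("windows and transcripts must align")
    tf_labels = sorted({p.tf_label for p in peaks})
    tf_index = {lab: j for j, lab in enumerate(tf_labels)}
    counts = np.zeros((len(windows), len(tf_labels)), dtype=np.int64)

    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, w in enumerate(windows):
        trees[w.chrom][w.start:w.end] = i

    skipped = 0
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            skipped += 1
            continue
        mid = p.midpoint
        for iv in tree[mid]:
            counts[iv.data, tf_index[p.tf_label]] += 1
    if skipped:
        logger.info("build_count_matrix: %d peaks on chromosomes absent "
                    "from the annotation were ignored", skipped)
    return pd.DataFrame(counts, index=list(transcripts), columns=tf_labels)


def architecture_size(
    P: CountMatrix,
    mode: str = "raw",
    exclude_pol2: bool = False,
    pol2_labels: list[str] | None = None,
) -> pd.Series:
    """Promoter architecture size per transcript.

    ``raw`` is the multiset cardinality (sum of counts); ``unique`` the
    number of distinct TFs with at least one site.  With ``exclude_pol2``
    the designated polymerase columns are dropped before summing.
    """
    if mode not in ("raw", "unique"):
        raise ValueError("mode must be 'raw' or 'unique'")
    Q = P
    if exclude_pol2:
        if not pol2_labels:
            raise ValueError("exclude_pol2 requires pol2_labels")
        unknown = set(pol2_labels) - set(P.columns)
        if unknown:
            raise ValueError(f"unknown Pol II labels: {sorted(unknown)}")
        Q = P.drop(columns=list(pol2_labels))
    if mode == "raw":
        out = Q.sum(axis=1)
    else:
        out = (Q > 0).sum(axis=1)
    return out.astype(np.int64)


def exclude_covariates(P: CountMatrix, labels: list[str]) -> CountMatrix:
    """Drop designated columns (e.g. the polymerase-II covariates, which are
    consequences rather than causes of expression)."""
    unknown = set(labels) - set(P.columns)
    if unknown:
        raise ValueError(f"unknown columns: {sorted(unknown)}")
    return P.drop(columns=list(labels))


def build_from_files(
    peaks_path,
    tss_path,
    expr_path,
    qs_cutoff: int = DEFAULT_QS_CUTOFF,
    tpm_cutoff: float = DEFAULT_TPM_CUTOFF,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> tuple[CountMatrix, BoEResponse]:
    """File-level convenience: peaks + TSS + expression -> (P, BoE).

    Transcripts are the non-redundant TSS records that also appear in the
    expression table; rows of both outputs align.
    """
    from . import io

    peaks = filter_peaks_by_qs(io.read_peaks(peaks_path), qs_cutoff)
    tss = collapse_redundant(io.read_tss(tss_path))
    expr = io.read_expression(expr_path)

    tss = [t for t in tss if t.transcript_id in set(expr.index.astype(str))]
    ids = [t.transcript_id for t in tss]
    windows = [promoter_window(t, half_width) for t in tss]
    P = build_count_matrix(peaks, windows, ids)
    response = compute_boe(expr.loc[ids], tpm_cutoff)
    return P, response
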