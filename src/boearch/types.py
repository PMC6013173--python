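"""Shared containers for the promoter-architecture / BoE pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BoEResponse:
    """Per-transcript breadth of expression as a binomial response.

    ``successes[i]`` is the number of samples in which transcript *i* was
    expressed above the TPM cutoff; ``trials`` is the number of samples
    (libraries), constant across transcripts. BoE = successes / trials.
    """

    transcript_ids: list[str]
    successes: np.ndarray
    trials: int

    def __post_init__(self) -> None:
        self.successes = np.asarray(self.successes, dtype=np.int64)
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if np.any(self.successes < 0) or np.any(self.successes > self.trials):
            raise ValueError("successes must lie in [0, trials]")
        if len(self.transcript_ids) != self.successes.shape[0]:
            raise ValueError("ids and successes lengths differ")

    @property
    def boe(self) -> np.ndarray:
        """Proportion of samples expressing each transcript, in [0, 1]."""
        return self.successes / self.trials

    def __len__(self) -> int:
        return self.successes.shape[0]

    def subset(self, index: np.ndarray) -> "BoEResponse":
        ids = [self.transcript_ids[i] for i in np.atleast_1d(index)]
        return BoEResponse(ids, self.successes[index], self.trials)


# A CountMatrix is a pandas DataFrame with transcript ids as the index, TF
# labels as columns and non-negative integer site counts as values.  A type
# alias keeps the interchange format explicit without wrapping pandas.
CountMatrix = pd.DataFrame


def validate_count_matrix(P: CountMatrix) -> None:
    """Raise if P is not a well-formed transcripts x TFs count matrix."""
    if P.index.has_duplicates or P.columns.has_duplicates:
        raise ValueError("row/column labels must be unique")
    values = P.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
    if (values < 0).any():
        raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class PeakRecord:
    """One merged ChIP-seq peak: BED-like half-open interval plus a quality
    score in [0, 1000]."""

    chrom: str
    start: int
    end: int
    tf_label: str
    qs: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start must be < end ({self.start} >= {self.end})")
        if not 0 <= self.qs <= 1000:
            raise ValueError("qs must be within [0, 1000]")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class TssRecord:
    """A transcript keyed by its transcription start site."""

    transcript_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty interval")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end
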