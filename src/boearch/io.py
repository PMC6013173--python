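"""Readers and writers for the pipeline's plain-text interchange formats.

Peak files are 5-column BED-like TSVs (chrom, start, end, TF label, quality
score), no header.  TSS annotations are 4-column TSVs with a header
(transcript_id, chrom, strand, tss).  Expression tables are TSVs whose
header row holds sample ids and whose first column holds transcript ids.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import BoEResponse, CountMatrix, PeakRecord, TssRecord


def read_peaks(path: str | Path) -> list[PeakRecord]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "tf_label", "qs"],
        dtype={"chrom": str, "tf_label": str},
    )
    return [
        PeakRecord(r.chrom, int(r.start), int(r.end), r.tf_label, int(r.qs))
        for r in df.itertuples(index=False)
    ]


def write_peaks(peaks: list[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.tf_label}\t{p.qs}\n")


def read_tss(path: str | Path) -> list[TssRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"transcript_id": str, "chrom": str})
    required = {"transcript_id", "chrom", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS file missing columns: {sorted(missing)}")
    return [
        TssRecord(r.transcript_id, r.chrom, r.strand, int(r.tss))
        for r in df.itertuples(index=False)
    ]


def write_tss(records: list[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tchrom\tstrand\ttss\n")
        for t in records:
            fh.write(f"{t.transcript_id}\t{t.chrom}\t{t.strand}\t{t.tss}\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if expr.empty:
        raise ValueError("empty expression table")
    if (expr.to_numpy() < 0).any():
        raise ValueError("negative TPM values")
    return expr


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="transcript_id",
                float_format="%.4f")


def read_count_matrix(path: str | Path) -> CountMatrix:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_count_matrix(P: CountMatrix, path: str | Path) -> None:
    P.to_csv(path, sep="\t", index_label="transcript_id")


def read_response(path: str | Path) -> BoEResponse:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    trials = int(df["trials"].iloc[0])
    return BoEResponse(list(df.index.astype(str)),
                       df["successes"].to_numpy(), trials)


def write_response(response: BoEResponse, path: str | Path) -> None:
    pd.DataFrame(
        {"successes": response.successes,
         "trials": response.trials,
         "boe": response.boe},
        index=pd.Index(response.transcript_ids, name="transcript_id"),
    ).to_csv(path, sep="\t", float_format="%.6f")


def write_matrix_with_response(
    P: CountMatrix, response: BoEResponse, path: str | Path
) -> None:
    """Single TSV holding the model matrix plus the BoE columns, the shape
    used for downstream model fitting."""
    joined = P.copy()
    joined["successes"] = response.successes
    joined["trials"] = response.trials
    joined["boe"] = response.boe
    joined.to_csv(path, sep="\t", index_label="transcript_id",
                  float_format="%.6f")


def read_matrix_with_response(path: str | Path) -> tuple[CountMatrix, BoEResponse]:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    trials = int(df["trials"].iloc[0])
    response = BoEResponse(list(df.index.astype(str)),
                           df["successes"].to_numpy(), trials)
    P = df.drop(columns=["successes", "trials", "boe"])
    return P.astype(np.int64), response
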