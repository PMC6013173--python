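"""Synthetic promoter architectures and binomial BoE responses.

The generator reproduces the statistical structure the downstream analysis
assumes: a very sparse transcripts x TFs count matrix (about 95 % zero
cells), a sizeable share of promoters with no strong binding site at all
(about 27 % all-zero rows), pairs of TF columns with near-perfect rank
correlation (antibodies targeting the same protein), and a breadth of
expression response that is binomial over n = 1660 samples with a
logit-linear predictor.  Each TF acts through one of three regulatory
logics: activating (log-odds increase per site), inhibitory (decrease per
site), or saturating (increase for the first site, penalty for additional
sites).  Ground truth is retained so that model-recovery can be scored.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BoEResponse, CountMatrix

LOGIC_CLASSES = ("activating", "inhibitory", "saturating")

# Geometric success probability for non-zero site counts.  Mass 0.6 / 0.24 /
# 0.096 on 1 / 2 / 3 sites keeps counts above three rare, matching the 0-3
# stratification range used by the regulatory-logic analysis.
_COUNT_GEOM_P = 0.6


@dataclass(frozen=True)
class TfEffect:
    """Planted regulatory logic of one TF.

    ``theta`` is the per-site log-odds effect (for saturating TFs the effect
    of the first site); ``saturation_penalty`` is the log-odds contribution
    of each site beyond the first and is only used for saturating TFs.
    """

    cls: str
    theta: float
    saturation_penalty: float = 0.0

    def __post_init__(self) -> None:
        if self.cls not in LOGIC_CLASSES:
            raise ValueError(f"unknown effect class {self.cls!r}")

    def linear_contribution(self, counts: np.ndarray) -> np.ndarray:
        if self.cls == "saturating":
            return self.theta * np.minimum(counts, 1) + (
                self.saturation_penalty * np.maximum(counts - 1, 0)
            )
        return self.theta * counts


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_transcripts: int
    n_tfs: int
    n_samples: int = 1660
    sparsity: float = 0.95
    empty_fraction: float = 0.27
    intercept: float = -2.0
    tf_effects: dict[str, TfEffect] = field(default_factory=dict)
    correlated_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1 or self.n_tfs < 1 or self.n_samples < 1:
            raise ValueError("dimensions must be positive")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must be in [0, 1)")
        if not 0 <= self.empty_fraction < 1:
            raise ValueError("empty_fraction must be in [0, 1)")
        if self.empty_fraction > self.sparsity:
            raise ValueError(
                "infeasible config: empty_fraction cannot exceed the overall "
                "sparsity target"
            )
        labels = set(self.tf_labels)
        for a, b, rho in self.correlated_pairs:
            if a == b:
                raise ValueError(f"correlated pair references one TF ({a})")
            if a not in labels or b not in labels:
                raise ValueError(f"correlated pair ({a}, {b}) references unknown TF")
            if not -1 <= rho <= 1:
                raise ValueError("target rho must be in [-1, 1]")
        unknown = set(self.tf_effects) - labels
        if unknown:
            raise ValueError(f"tf_effects reference unknown TFs: {sorted(unknown)}")
        _solve_sparsity(self.sparsity, self.empty_fraction, self.n_tfs)

    @property
    def tf_labels(self) -> list[str]:
        width = max(3, len(str(self.n_tfs)))
        return [f"TF{j + 1:0{width}d}" for j in range(self.n_tfs)]

    @property
    def transcript_ids(self) -> list[str]:
        width = max(5, len(str(self.n_transcripts)))
        return [f"NM_{i + 1:0{width}d}" for i in range(self.n_transcripts)]

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Child generator for one pipeline stage, derived from the master
        seed so stages are individually reproducible."""
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return np.random.default_rng(ss)


@dataclass
class SimulationTruth:
    """Planted parameters plus realized data, for recovery scoring."""

    config: SimulationConfig
    coefficients: pd.Series  # per-TF theta on the logit scale
    logic_classes: pd.Series  # per-TF class name
    count_matrix: CountMatrix
    successes: np.ndarray

    @property
    def response(self) -> BoEResponse:
        return BoEResponse(
            list(self.count_matrix.index), self.successes, self.config.n_samples
        )


def default_tf_effects(
    labels: list[str],
    seed: int = 0,
    prop_inhibitory: float = 0.05,
    prop_saturating: float = 0.05,
) -> dict[str, TfEffect]:
    """Assign regulatory logics in realistic proportions.

    The split (90 % activating, 5 % inhibitory, 5 % saturating) mirrors the
    dominance of activating TFs among classified factors; magnitudes sit in
    the range typical of per-site log-odds effects on breadth of expression
    (about 0.1-0.4 activating, -0.6 to -0.2 inhibitory).
    """
    rng = np.random.default_rng(seed)
    n = len(labels)
    n_inh = max(1, round(prop_inhibitory * n)) if n >= 3 and prop_inhibitory > 0 else 0
    n_sat = max(1, round(prop_saturating * n)) if n >= 3 and prop_saturating > 0 else 0
    classes = ["activating"] * (n - n_inh - n_sat)
    classes += ["inhibitory"] * n_inh + ["saturating"] * n_sat
    rng.shuffle(classes)
    effects = {}
    for label, cls in zip(labels, classes):
        if cls == "activating":
            effects[label] = TfEffect(cls, rng.uniform(0.1, 0.4))
        elif cls == "inhibitory":
            effects[label] = TfEffect(cls, rng.uniform(-0.6, -0.2))
        else:
            effects[label] = TfEffect(
                cls, rng.uniform(0.4, 0.7), rng.uniform(-2.0, -1.0)
            )
    return effects


def default_config(
    n_transcripts: int = 20_000, n_tfs: int = 148, seed: int = 0
) -> SimulationConfig:
    """The standard study conditions: 1660 samples, 95 % sparsity, 27 %
    empty architectures, intercept -2 and two highly correlated TF pairs."""
    cfg = SimulationConfig(n_transcripts=n_transcripts, n_tfs=n_tfs, seed=seed)
    labels = cfg.tf_labels
    cfg.tf_effects = default_tf_effects(labels, seed=seed)
    if n_tfs >= 4:
        cfg.correlated_pairs = [
            (labels[0], labels[1], 0.99),
            (labels[2], labels[3], 0.90),
        ]
        # correlated partners share the primary member's effect class
        cfg.tf_effects[labels[1]] = cfg.tf_effects[labels[0]]
        cfg.tf_effects[labels[3]] = cfg.tf_effects[labels[2]]
    cfg.__post_init__()
    return cfg


def _solve_sparsity(S: float, E: float, N: int) -> float:
    """Per-cell sparsity s for the occupied rows.

    A fraction E of rows is empty by design; the remaining rows are iid
    Bernoulli cells conditioned on holding at least one site, so the empty
    fraction is exactly E and the overall zero-cell fraction is

        E + (1 - E) * (s - s^N) / (1 - s^N) = S.

    The conditioned zero fraction is capped at (N-1)/N, so combinations
    demanding more are infeasible under independent cells.
    """
    from scipy.optimize import brentq

    target = (S - E) / (1 - E)
    if target <= 0:
        return 0.0
    if N == 1 or target >= (N - 1) / N - 1e-12:
        raise ValueError(
            "infeasible sparsity/empty_fraction combination: occupied rows "
            f"cannot carry a zero-cell fraction of {target:.3f} with {N} TFs"
        )

    def h(s: float) -> float:
        sN = s**N
        return (s - sN) / (1 - sN) - target

    return brentq(h, 1e-12, 1 - 1e-9, xtol=1e-13)


def simulate_architectures(config: SimulationConfig) -> CountMatrix:
    """Draw a transcripts x TFs matrix of promoter binding-site counts.

    A fixed fraction of rows is forced empty; within the remaining rows
    cells are occupied independently at the rate that yields the overall
    sparsity target, with geometric counts on occupied cells.  Correlated
    pairs are induced by a cell-copy mixture: the second column of a pair
    copies the first column's cell with probability equal to the target
    Spearman rho, else keeps an independent same-marginal draw.
    """
    rng = config.stage_rng("architectures")
    M, N = config.n_transcripts, config.n_tfs
    cell_sparsity = _solve_sparsity(config.sparsity, config.empty_fraction, N)

    counts = np.zeros((M, N), dtype=np.int64)
    n_empty = int(round(config.empty_fraction * M))
    empty_rows = rng.choice(M, size=n_empty, replace=False)
    occupied = np.ones(M, dtype=bool)
    occupied[empty_rows] = False

    labels = config.tf_labels
    col = {lab: j for j, lab in enumerate(labels)}
    pairs = [(col[a], col[b], rho) for a, b, rho in config.correlated_pairs]

    def draw_block(rows: int) -> np.ndarray:
        present = rng.random((rows, N)) >= cell_sparsity
        vals = rng.geometric(_COUNT_GEOM_P, size=(rows, N))
        block = np.where(present, vals, 0)
        for ja, jb, rho in pairs:
            copy = rng.random(rows) < rho
            block[copy, jb] = block[copy, ja]
        return block

    n_occ = int(occupied.sum())
    block = draw_block(n_occ)
    if cell_sparsity > 0:
        # occupied rows are conditioned on holding at least one site
        redo = np.nonzero(~block.any(axis=1))[0]
        while len(redo):
            block[redo] = draw_block(len(redo))
            redo = redo[~block[redo].any(axis=1)]
    counts[occupied] = block

    return pd.DataFrame(counts, index=config.transcript_ids, columns=labels)


def linear_predictor(P: CountMatrix, config: SimulationConfig) -> np.ndarray:
    """eta_i = theta0 + sum_j f_j(x_ij) under the planted effects."""
    eta = np.full(len(P), config.intercept, dtype=float)
    for label, effect in config.tf_effects.items():
        if label not in P.columns:
            raise ValueError(f"effect column {label} missing from matrix")
        eta += effect.linear_contribution(P[label].to_numpy())
    return eta


def simulate_boe(P: CountMatrix, config: SimulationConfig) -> BoEResponse:
    """Draw successes_i ~ Binomial(n_samples, inv-logit(eta_i))."""
    extra = set(config.tf_effects) - set(P.columns)
    if extra:
        raise ValueError(f"effects reference columns absent from P: {sorted(extra)}")
    rng = config.stage_rng("response")
    eta = linear_predictor(P, config)
    prob = 1.0 / (1.0 + np.exp(-eta))
    successes = rng.binomial(config.n_samples, prob)
    return BoEResponse(list(P.index), successes, config.n_samples)


def simulate_dataset(config: SimulationConfig) -> SimulationTruth:
    """Architectures + response + ground truth in one call."""
    P = simulate_architectures(config)
    response = simulate_boe(P, config)
    coeffs = pd.Series(
        {lab: config.tf_effects[lab].theta if lab in config.tf_effects else 0.0
         for lab in P.columns},
        name="theta",
    )
    classes = pd.Series(
        {lab: config.tf_effects[lab].cls if lab in config.tf_effects else "activating"
         for lab in P.columns},
        name="logic",
    )
    return SimulationTruth(config, coeffs, classes, P, response.successes)


def simulate_expression(
    boe_target: BoEResponse, tpm_cutoff: float = 10.0, seed: int = 0
) -> pd.DataFrame:
    """TPM table whose thresholding reproduces ``boe_target`` exactly.

    "On" cells are log-normal around 100 TPM, shifted strictly above the
    cutoff; "off" cells are log-normal around 1 TPM, redrawn uniformly below
    the cutoff where the tail would cross it.  compute_boe with the same
    cutoff therefore round-trips the target exactly.
    """
    if tpm_cutoff <= 0:
        raise ValueError("tpm_cutoff must be positive")
    rng = np.random.default_rng(seed)
    M, n = len(boe_target), boe_target.trials
    k = boe_target.successes

    off = np.exp(rng.normal(0.0, 1.0, size=(M, n)))
    bad = off >= tpm_cutoff
    off[bad] = rng.uniform(0.0, tpm_cutoff, size=int(bad.sum()))

    on = tpm_cutoff + np.exp(rng.normal(np.log(90.0), 0.8, size=(M, n)))

    # per-row random choice of which k_i samples are "on"
    order = rng.random((M, n)).argsort(axis=1).argsort(axis=1)
    on_mask = order < k[:, None]
    tpm = np.where(on_mask, on, off)

    samples = [f"S{j + 1:04d}" for j in range(n)]
    return pd.DataFrame(tpm, index=boe_target.transcript_ids, columns=samples)


def write_input_files(
    truth: SimulationTruth,
    outdir: str | Path,
    tpm_cutoff: float = 10.0,
    qs_cutoff: int = 500,
    decoy_rate: float = 0.1,
    window_half_width: int = 500,
) -> dict[str, Path]:
    """Materialize peak/TSS/expression files that rebuild this dataset.

    Transcripts are laid out on one chromosome with disjoint promoter
    windows; each planted site becomes a peak with QS above the cutoff whose
    midpoint falls inside the owning window, plus a fraction of low-QS decoy
    peaks that the QS filter must remove.
    """
    from .io import write_expression, write_peaks, write_tss
    from .types import PeakRecord, TssRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    rng = cfg.stage_rng("files")

    spacing = 4 * window_half_width
    tss_records = [
        TssRecord(tid, "chr1", "+", 2 * window_half_width + i * spacing)
        for i, tid in enumerate(truth.count_matrix.index)
    ]
    peaks = []
    counts = truth.count_matrix.to_numpy()
    labels = list(truth.count_matrix.columns)
    for i, rec in enumerate(tss_records):
        for j, lab in enumerate(labels):
            for _ in range(counts[i, j]):
                mid = rec.tss + int(rng.integers(-window_half_width + 1,
                                                 window_half_width - 1))
                half_len = int(rng.integers(50, 200))
                qs = int(rng.integers(qs_cutoff + 1, 1001))
                peaks.append(PeakRecord("chr1", max(0, mid - half_len),
                                        mid + half_len, lab, qs))
    n_decoys = int(decoy_rate * len(peaks))
    genome_end = tss_records[-1].tss + spacing
    for _ in range(n_decoys):
        mid = int(rng.integers(100, genome_end))
        lab = labels[int(rng.integers(len(labels)))]
        half_len = int(rng.integers(50, 200))
        qs = int(rng.integers(0, qs_cutoff + 1))  # fails the strict filter
        peaks.append(PeakRecord("chr1", max(0, mid - half_len),
                                mid + half_len, lab, qs))
    rng.shuffle(peaks)

    expr = simulate_expression(truth.response, tpm_cutoff,
                               seed=int(rng.integers(2**31)))
    paths = {
        "peaks": outdir / "peaks.bed",
        "tss": outdir / "tss.tsv",
        "expression": outdir / "expression.tsv",
    }
    write_peaks(peaks, paths["peaks"])
    write_tss(tss_records, paths["tss"])
    write_expression(expr, paths["expression"])
    return paths


def parse_config_file(path: str | Path) -> SimulationConfig:
    """Read a key/value config.

    Scalar keys: n_transcripts, n_tfs, n_samples, sparsity, empty_fraction,
    intercept, seed.  ``effect.<TF> = <class> <theta> [<penalty>]`` plants a
    per-TF effect; ``pair = <TF> <TF> <rho>`` adds a correlated pair.
    """
    scalars: dict[str, str] = {}
    effects: dict[str, TfEffect] = {}
    pairs: list[tuple[str, str, float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key.startswith("effect."):
            parts = value.split()
            pen = float(parts[2]) if len(parts) > 2 else 0.0
            effects[key[len("effect."):]] = TfEffect(parts[0], float(parts[1]), pen)
        elif key == "pair":
            a, b, rho = value.split()
            pairs.append((a, b, float(rho)))
        else:
            scalars[key] = value
    cfg = SimulationConfig(
        n_transcripts=int(scalars["n_transcripts"]),
        n_tfs=int(scalars["n_tfs"]),
        n_samples=int(scalars.get("n_samples", 1660)),
        sparsity=float(scalars.get("sparsity", 0.95)),
        empty_fraction=float(scalars.get("empty_fraction", 0.27)),
        intercept=float(scalars.get("intercept", -2.0)),
        tf_effects=effects,
        correlated_pairs=pairs,
        seed=int(scalars.get("seed", 0)),
    )
    return cfg
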