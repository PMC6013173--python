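"""End-to-end orchestration: integration -> correlations -> models -> report.

Every stage writes plain TSV/text artifacts into one output directory,
each with a provenance header line (config hash, seed, stage) so a run
can be audited and reproduced.  One master seed is fanned out to
per-stage child seeds.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .cluster import cluster_summary, cluster_transcripts
from .comparison import (
    coefficient_correlations,
    summarize_coefficients,
)
from .correlation import (
    flag_significant,
    pairwise_tf_correlations,
    permutation_null,
    prune_collinear,
)
from .glm import fit_penalized, fit_quasibinomial
from .integration import architecture_size, build_from_files
from .logic import classify_matrix
from .synthetic import SimulationConfig, simulate_dataset, write_input_files
from .tree import fit_tree, render_tree
from .types import BoEResponse, CountMatrix


@dataclass
class PipelineConfig:
    """Inputs, cutoffs and seeds for one pipeline run."""

    out_dir: Path
    peaks: Path | None = None
    tss: Path | None = None
    expression: Path | None = None
    simulate: SimulationConfig | None = None
    tpm_cutoff: float = 10.0
    qs_cutoff: int = 500
    half_width: int = 500
    vif_cutoff: float = 10.0
    p_cutoff: float = 0.05
    models: tuple[str, ...] = ("glm", "lasso", "ridge", "enet")
    n_perm: int = 10
    n_lambda: int = 30
    cv_folds: int = 10
    exclude: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for cut in (self.tpm_cutoff, self.qs_cutoff, self.half_width,
                    self.vif_cutoff, self.p_cutoff):
            if cut <= 0:
                raise ValueError("all cutoffs must be positive")
        if self.simulate is None and not (self.peaks and self.tss
                                          and self.expression):
            raise ValueError("need input files or a simulation config")

    def stage_seed(self, stage: str) -> int:
        return int(
            np.random.SeedSequence(
                [self.seed, zlib.crc32(stage.encode())]
            ).generate_state(1)[0] % (2**31)
        )

    def config_hash(self) -> str:
        # analysis parameters only: paths do not affect the computation
        skip = {"out_dir", "peaks", "tss", "expression"}
        payload = repr(sorted(
            (k, v) for k, v in self.__dict__.items() if k not in skip))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: PipelineConfig, stage: str) -> str:
    return (f"# boearch stage={stage} seed={config.seed} "
            f"config={config.config_hash()}\n")


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig,
               stage: str, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config, stage))
        df.to_csv(fh, sep="\t", **kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the artifact directory."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if config.simulate is not None:
            truth = simulate_dataset(config.simulate)
            paths = write_input_files(truth, out / "inputs",
                                      tpm_cutoff=config.tpm_cutoff,
                                      qs_cutoff=config.qs_cutoff,
                                      window_half_width=config.half_width)
            truth_df = pd.DataFrame({"theta": truth.coefficients,
                                     "logic": truth.logic_classes})
            _write_tsv(truth_df, out / "simulation_truth.tsv", config, stage)
            peaks, tss, expr = paths["peaks"], paths["tss"], paths["expression"]
        else:
            peaks, tss, expr = config.peaks, config.tss, config.expression

        stage = "integration"
        P, response = build_from_files(
            peaks, tss, expr,
            qs_cutoff=config.qs_cutoff,
            tpm_cutoff=config.tpm_cutoff,
            half_width=config.half_width,
        )
        if config.exclude:
            keep = [c for c in P.columns if c not in set(config.exclude)]
            P = P[keep]
        with open(out / "matrix.tsv", "w") as fh:
            fh.write(_provenance(config, stage))
            io.write_matrix_with_response(P, response, fh)

        stage = "correlation"
        corr = pairwise_tf_correlations(P)
        null = permutation_null(P, n_perm=config.n_perm,
                                seed=config.stage_seed(stage))
        corr = flag_significant(corr, null)
        _write_tsv(corr.table, out / "correlations.tsv", config, stage,
                   index=False)
        (out / "thresholds.json").write_text(json.dumps(
            {"lower": null.lower, "upper": null.upper,
             "n_permutations": null.n_permutations,
             "seed": null.seed, "config": config.config_hash()}, indent=2))
        P_model, vif_report = prune_collinear(P, cutoff=config.vif_cutoff)
        _write_tsv(vif_report.initial.to_frame(), out / "vif.tsv", config, stage)

        stage = "models"
        fits: dict[str, object] = {}
        for model in config.models:
            seed = config.stage_seed(f"model:{model}")
            if model == "glm":
                fits[model] = fit_quasibinomial(P_model, response)
            elif model in ("lasso", "ridge", "enet"):
                alpha = {"lasso": 1.0, "ridge": 0.0, "enet": 0.5}[model]
                fits[model] = fit_penalized(
                    P_model, response, alpha=alpha,
                    n_lambda=config.n_lambda, cv_folds=config.cv_folds,
                    seed=seed)
            elif model == "bayes":
                from .bayes import fit_bayesian
                fits[model] = fit_bayesian(P_model, response, seed=seed)
            else:
                raise ValueError(f"unknown model {model!r}")
            coef = fits[model].params.to_frame("estimate")
            if hasattr(fits[model], "bse"):
                coef["se"] = fits[model].bse
                coef["p_value"] = fits[model].pvalues
            _write_tsv(coef, out / f"coefficients_{model}.tsv", config, stage)

        stage = "tree"
        tree = fit_tree(P_model, response.boe)
        (out / "tree.txt").write_text(_provenance(config, stage)
                                      + render_tree(tree))

        stage = "logic"
        logic = classify_matrix(P_model, response.boe, alpha=config.p_cutoff)
        _write_tsv(logic, out / "logic.tsv", config, stage)

        stage = "clustering"
        size = architecture_size(P, mode="raw")
        clusters = cluster_transcripts(size.to_numpy(), response.boe,
                                       seed=config.stage_seed(stage))
        _write_tsv(pd.DataFrame({"cluster": clusters.labels},
                                index=P.index),
                   out / "clusters.tsv", config, stage,
                   index_label="transcript_id")
        summary = cluster_summary(
            clusters, response.boe,
            {"size_raw": size.to_numpy(),
             "size_unique": architecture_size(P, mode="unique").to_numpy()})
        _write_tsv(summary, out / "cluster_summary.tsv", config, stage)

        stage = "comparison"
        summaries = pd.DataFrame([
            {"model": name, **vars(summarize_coefficients(f, name)),
             "span": summarize_coefficients(f, name).span}
            for name, f in fits.items()]).drop(columns=["model_id"])
        _write_tsv(summaries, out / "model_summary.tsv", config, stage,
                   index=False)
        if len(fits) >= 2:
            _write_tsv(coefficient_correlations(fits),
                       out / "coefficient_correlations.tsv", config, stage)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage tag
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    return out


_REPORT_SECTIONS = {
    "Model matrix": "matrix.tsv",
    "TF correlations": "correlations.tsv",
    "Permutation thresholds": "thresholds.json",
    "Collinearity (VIF)": "vif.tsv",
    "Model summaries": "model_summary.tsv",
    "Model agreement": "coefficient_correlations.tsv",
    "Regression tree": "tree.txt",
    "Regulatory logic": "logic.tsv",
    "Transcript clusters": "cluster_summary.tsv",
}


def generate_report(artifact_dir: str | Path) -> str:
    """Human-readable collation of one run's artifacts; missing files are
    listed rather than fatal."""
    artifact_dir = Path(artifact_dir)
    lines = [f"boearch report for {artifact_dir}", "=" * 40]
    missing = []
    for title, fname in _REPORT_SECTIONS.items():
        path = artifact_dir / fname
        if not path.exists():
            missing.append(fname)
            continue
        lines += ["", title, "-" * len(title)]
        text = path.read_text().strip().splitlines()
        lines += text[:15]
        if len(text) > 15:
            lines.append(f"... ({len(text) - 15} more lines)")
    if missing:
        lines += ["", "Missing artifacts", "-" * 17, *missing]
    return "\n".join(lines) + "\n"
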