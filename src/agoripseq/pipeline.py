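"""End-to-end orchestration: counts -> normalization -> GLM -> targets.

:class:`AgoRipTargetPipeline` is the estimator facade (fit on a
libraries x genes matrix plus sample sheet; fitted attributes expose
normalization factors, contrast results and target calls).
:func:`run_pipeline` drives it from a :class:`~agoripseq.config.PipelineConfig`,
writing TSV outputs and a JSON manifest; on failure partial outputs are
removed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import __version__, io
from .config import PipelineConfig
from .glm import NegativeBinomialLRT
from .normalize import TMMNormalizer, cpm, filter_low_expression, tmm_factors
from .simulate import SimConfig, simulate_ripseq
from .targets import AGO_IGG, AGO_TL, LYSATE, call_potential_targets, prioritize_targets
from .tissue import overlap_tissue

logger = logging.getLogger("agoripseq")

__all__ = ["AgoRipTargetPipeline", "run_pipeline"]


class AgoRipTargetPipeline(BaseEstimator):
    """Full miR target identification from factorial RIP-Seq counts.

    Chains TMM normalization, the low-expression filter, the negative
    binomial GLM with the three background-correcting contrasts, the
    sign-based potential-target rule and the fold/expression
    prioritization filter.

    Parameters mirror the pipeline configuration; all defaults are the
    analysis defaults (4-fold Ago enrichment, 1.5-fold lysate repression,
    8 cpm in every library, no FDR cutoff).

    Attributes
    ----------
    normalizer_ : fitted :class:`~agoripseq.normalize.TMMNormalizer`
    gene_mask_ : boolean Series of genes passing the expression filter
    model_ : fitted :class:`~agoripseq.glm.NegativeBinomialLRT`
    results_ : dict of contrast name -> result DataFrame
    target_calls_ : per-gene call table with flags and fold changes
    summary_ : per-stage gene counts
    """

    def __init__(
        self,
        trim_m: float = 0.30,
        trim_a: float = 0.05,
        ref_library=None,
        min_avg_cpm: float = 1.0,
        dispersion="shrunk",
        prior_weight: float = 10.0,
        min_ago_fold: float = 4.0,
        min_lysate_fold: float = 1.5,
        min_cpm: float = 8.0,
        fdr_cutoff=None,
        ago_rule: str = "both",
    ):
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.ref_library = ref_library
        self.min_avg_cpm = min_avg_cpm
        self.dispersion = dispersion
        self.prior_weight = prior_weight
        self.min_ago_fold = min_ago_fold
        self.min_lysate_fold = min_lysate_fold
        self.min_cpm = min_cpm
        self.fdr_cutoff = fdr_cutoff
        self.ago_rule = ago_rule

    def fit(self, X, design):
        """Run the analysis.

        ``X`` is a libraries x genes matrix (DataFrame indexed by
        library_id, or array aligned with ``design``); ``design`` is the
        sample sheet DataFrame.
        """
        if isinstance(X, pd.DataFrame):
            counts = X.T  # genes x libraries
        else:
            X = np.asarray(X)
            counts = pd.DataFrame(
                X.T,
                index=[f"gene_{i:05d}" for i in range(X.shape[1])],
                columns=design["library_id"].tolist(),
            )
        counts = io.join_counts_design(counts, design)

        t0 = time.perf_counter()
        norm = TMMNormalizer(
            trim_m=self.trim_m, trim_a=self.trim_a, ref_library=self.ref_library
        ).fit(counts.T)
        factors = norm.factors_frame()
        logger.info("TMM normalization done in %.2fs", time.perf_counter() - t0)

        mask = filter_low_expression(counts, factors, self.min_avg_cpm)
        kept = counts.loc[mask]
        logger.info("expression filter kept %d / %d genes", int(mask.sum()), len(mask))

        t0 = time.perf_counter()
        model = NegativeBinomialLRT(
            dispersion=self.dispersion, prior_weight=self.prior_weight
        )
        offsets = np.log(norm.effective_library_sizes_)
        model.fit(kept.T, design, offsets=offsets, gene_ids=kept.index.to_numpy())
        logger.info("NB GLM + LRT done in %.2fs", time.perf_counter() - t0)

        cpm_matrix = cpm(kept, factors)
        calls = call_potential_targets(model.results_, fdr_cutoff=self.fdr_cutoff)
        calls = prioritize_targets(
            calls,
            cpm_matrix,
            min_ago_fold=self.min_ago_fold,
            min_lysate_fold=self.min_lysate_fold,
            min_cpm=self.min_cpm,
            ago_rule=self.ago_rule,
        )

        self.normalizer_ = norm
        self.norm_factors_ = factors
        self.gene_mask_ = mask
        self.model_ = model
        self.results_ = model.results_
        self.cpm_ = cpm_matrix
        self.target_calls_ = calls
        self.summary_ = {
            "n_genes_input": int(len(mask)),
            "n_genes_post_filter": int(mask.sum()),
            "n_potential_targets": int(calls["is_potential_target"].sum()),
            "n_prioritized_targets": int(calls["is_prioritized"].sum()),
        }
        s = self.summary_
        if not (
            s["n_prioritized_targets"]
            <= s["n_potential_targets"]
            <= s["n_genes_post_filter"]
            <= s["n_genes_input"]
        ):
            raise AssertionError(f"inconsistent stage gene counts: {s}")
        return self

    def predict(self, X=None) -> np.ndarray:
        """Boolean prioritized-target flag per analysed gene."""
        if not hasattr(self, "target_calls_"):
            raise ValueError("pipeline is not fitted")
        return self.target_calls_["is_prioritized"].to_numpy()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline from a configuration; write outputs + manifest.

    Inputs are either read from ``config.counts`` / ``config.sample_sheet``
    or, when a simulation block is present and no counts path is given,
    generated by :func:`agoripseq.simulate.simulate_ripseq` with the
    configured seed.  Returns the result bundle as a dict.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str):
        path = out_dir / name
        io.write_table(df, path)
        written.append(path)
        return path

    try:
        truth = None
        if config.counts is not None:
            counts = io.read_counts(config.counts)
            design = io.read_sample_sheet(config.sample_sheet)
        elif config.simulation is not None:
            sim = SimConfig(seed=config.seed, **config.simulation.model_dump())
            counts, design, truth = simulate_ripseq(sim)
            io.write_counts(counts, out_dir / "simulated_counts.tsv")
            written.append(out_dir / "simulated_counts.tsv")
            _write(design, "sample_sheet.tsv")
            _write(truth, "sim_truth.tsv")
        else:
            raise ValueError("config must provide counts+sample_sheet or a simulation block")

        counts = io.join_counts_design(counts, design)
        pipe = AgoRipTargetPipeline(
            trim_m=config.normalization.trim_m,
            trim_a=config.normalization.trim_a,
            ref_library=config.normalization.ref_library,
            min_avg_cpm=config.normalization.min_avg_cpm,
            dispersion=config.model.dispersion,
            prior_weight=config.model.prior_weight,
            min_ago_fold=config.calling.min_ago_fold,
            min_lysate_fold=config.calling.min_lysate_fold,
            min_cpm=config.calling.min_cpm,
            fdr_cutoff=config.calling.fdr_cutoff,
            ago_rule=config.calling.ago_rule,
        )
        pipe.fit(counts.T, design)

        _write(pipe.norm_factors_, "norm_factors.tsv")
        for name, res in pipe.results_.items():
            safe = name.replace("/", "_")
            _write(res, f"contrast_{safe}.tsv")
        _write(pipe.target_calls_, "target_calls.tsv")

        overlap = None
        if config.tissue_table is not None:
            tissue = io.read_table(config.tissue_table)
            prioritized = pipe.target_calls_.loc[
                pipe.target_calls_["is_prioritized"], "gene_id"
            ].tolist()
            if prioritized:
                res = overlap_tissue(
                    prioritized,
                    tissue,
                    universe_size=pipe.summary_["n_genes_input"],
                    down_fold_cutoff=config.integration.down_fold_cutoff,
                    p_cutoff=config.integration.p_cutoff,
                )
                overlap = res.__dict__
                _write(pd.DataFrame([overlap]), "tissue_overlap.tsv")
            else:
                logger.warning("no prioritized targets; skipping tissue overlap")

        manifest = {
            "package_version": __version__,
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "gene_counts": pipe.summary_,
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        written.append(out_dir / "manifest.json")

        return {
            "pipeline": pipe,
            "norm_factors": pipe.norm_factors_,
            "results": pipe.results_,
            "target_calls": pipe.target_calls_,
            "truth": truth,
            "overlap": overlap,
            "manifest": manifest,
        }
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
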