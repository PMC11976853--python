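"""End-to-end orchestration of the transfer-and-rescore pipeline.

Stage order (checkpoint files in parentheses):

1. featurize the unfiltered search PSMs and train the cross-validated
   rescorer (``01_first_round.tsv``, ``weights_stage1.tsv``);
2. filter at the input PSM FDR — these are the transfer seeds
   (``02_accepted_input.tsv``);
3. cluster all spectra and transfer identifications within clusters
   (``03_clusters.tsv``, ``04_transferred.tsv``);
4. featurize the transferred candidates (reusing the stage-1 RT
   calibration);
5. merge: transferred candidates replace first-round PSMs only for
   spectra that failed the first-round FDR (``05_merged.tsv``);
6. rescore the merged table with the stage-1 weights as a static model —
   no retraining (``06_final_rescored.tsv``, ``weights_static.tsv``);
7. best PSM per spectrum, PSM- and peptide-level q-values
   (``07_psms.tsv``, ``08_peptides.tsv``);
8. picked protein-group FDR (``09_protein_groups.tsv``).

A rerun with an identical config and seed writes byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering as _clustering
from .clustering import annotate_clusters, build_rarity_model, complete_linkage, write_clusters
from .features import PropertyProvider, align_rt, featurize
from .proteins import ProteinGroup, best_psm_per_spectrum, merge_candidates, picked_protein_fdr
from .rescoring import (
    RescoreModel,
    apply_static,
    attach_pep,
    merge_models,
    peptide_qvalues,
    train_rescorer,
)
from .spectra import PSMTable, Spectrum, filter_predictable, write_psm_table
from .transfer import TransferConfig, run_transfer

logger = logging.getLogger("psmtransfer")


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters; defaults mirror the recommended settings
    (stringency 10, maximum PEP 5%, keep_all ambiguity policy, 1% FDR)."""

    bin_width: float = _clustering.DEFAULT_BIN_WIDTH
    top_k: int = _clustering.DEFAULT_TOP_K
    stringency: int = _clustering.DEFAULT_STRINGENCY
    precursor_tol: float = _clustering.DEFAULT_PRECURSOR_TOL
    transfer: TransferConfig = field(default_factory=TransferConfig)
    transfer_enabled: bool = True
    fragment_tol: float = 0.02
    train_fdr: float = 0.01
    n_iterations: int = 10
    n_folds: int = 3
    seed: int = 0
    psm_fdr: float = 0.01
    peptide_fdr: float = 0.01
    protein_fdr: float = 0.01

    def __post_init__(self) -> None:
        for name in ("train_fdr", "psm_fdr", "peptide_fdr", "protein_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        transfer = TransferConfig(**raw.pop("transfer", {}))
        return cls(transfer=transfer, **raw)


@dataclass
class PipelineResult:
    first_round: PSMTable
    transferred: PSMTable
    merged: PSMTable
    final: PSMTable
    psm_level: PSMTable
    peptide_level: PSMTable
    protein_groups: list[ProteinGroup]
    static_model: RescoreModel
    clusters: list


def _write_weights(model: RescoreModel, path: Path) -> None:
    raw = model.raw_space()
    df = pd.DataFrame(
        {"feature": list(raw.weights) + ["__intercept__"],
         "weight": list(raw.weights.values()) + [raw.intercept]}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _checkpoint(table: PSMTable, path: Path | None) -> None:
    if path is not None:
        write_psm_table(table, path)


def _write_groups(groups: list[ProteinGroup], path: Path) -> None:
    recs = [
        {
            "group_id": g.group_id,
            "accessions": ";".join(g.member_accessions),
            "n_peptides": len(g.peptides),
            "best_score": g.best_score,
            "decoy": int(g.is_decoy_group),
            "q_value": g.q_value,
        }
        for g in groups
    ]
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(spectra: list[Spectrum], psms: PSMTable, provider: PropertyProvider,
                 config: PipelineConfig = PipelineConfig(),
                 output_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage on in-memory inputs; optionally write checkpoints."""
    out = None
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)

    def ckpt(name: str) -> Path | None:
        return out / name if out is not None else None

    # stage 1: featurize + cross-validated rescoring of the search PSMs
    search = filter_predictable(psms)
    feats1 = featurize(search, spectra, provider, config.fragment_tol)
    models, scored1 = train_rescorer(
        feats1, train_fdr=config.train_fdr, n_iterations=config.n_iterations,
        n_folds=config.n_folds, seed=config.seed,
    )
    static_model = merge_models(models)
    scored1 = attach_pep(scored1)
    logger.info("stage 1: %d search PSMs rescored", len(scored1))
    _checkpoint(scored1, ckpt("01_first_round.tsv"))
    if out is not None:
        _write_weights(static_model, out / "weights_stage1.tsv")

    if config.transfer_enabled:
        # stage 2: input-FDR filter -> transfer seeds
        accepted = PSMTable(
            [p for p in scored1 if p.q_value is not None
             and p.q_value <= config.transfer.input_fdr],
            {"input_fdr": config.transfer.input_fdr},
        )
        logger.info("stage 2: %d PSMs accepted at input FDR %.3g",
                    len(accepted), config.transfer.input_fdr)
        _checkpoint(accepted, ckpt("02_accepted_input.tsv"))

        # stage 3: clustering + transfer
        rarity = build_rarity_model(spectra, config.bin_width, config.top_k)
        clusters = complete_linkage(spectra, rarity, config.stringency,
                                    config.precursor_tol)
        clusters = annotate_clusters(clusters, accepted)
        transferred = run_transfer(clusters, accepted, config.transfer)
        logger.info("stage 3: %d clusters (%s), %d transferred PSMs",
                    len(clusters), transferred.provenance.get("cluster_states"),
                    len(transferred))
        if out is not None:
            write_clusters(clusters, spectra, out / "03_clusters.tsv")
        _checkpoint(transferred, ckpt("04_transferred.tsv"))

        # stage 4: featurize transfers with the stage-1 RT calibration
        rt_maps = align_rt(feats1, spectra, provider)
        feats_t = featurize(transferred, spectra, provider, config.fragment_tol,
                            rt_maps=rt_maps)

        # stage 5: replacement-rule merge
        merged = merge_candidates(scored1, feats_t, config.psm_fdr)
    else:
        clusters = []
        transferred = PSMTable([], {"n_transferred": 0})
        merged = merge_candidates(scored1, transferred, config.psm_fdr)
    logger.info("stage 5: %d merged candidates", len(merged))
    _checkpoint(merged, ckpt("05_merged.tsv"))

    # stage 6: static rescoring — the stage-1 weights, no retraining
    final = apply_static(static_model, merged)
    final = attach_pep(final)
    _checkpoint(final, ckpt("06_final_rescored.tsv"))
    if out is not None:
        _write_weights(static_model, out / "weights_static.tsv")

    # stage 7: best PSM per spectrum; PSM- and peptide-level q-values
    psm_level = best_psm_per_spectrum(final)
    peptide_level = peptide_qvalues(psm_level)
    logger.info("stage 7: %d spectra, %d peptides",
                len(psm_level), len(peptide_level))
    _checkpoint(psm_level, ckpt("07_psms.tsv"))
    _checkpoint(peptide_level, ckpt("08_peptides.tsv"))

    # stage 8: picked protein-group FDR on the accepted PSMs
    accepted_final = PSMTable(
        [p for p in psm_level if p.q_value is not None and p.q_value <= config.psm_fdr]
    )
    groups = picked_protein_fdr(accepted_final, config.protein_fdr)
    logger.info("stage 8: %d protein groups", len(groups))
    if out is not None:
        _write_groups(groups, out / "09_protein_groups.tsv")

    return PipelineResult(
        first_round=scored1,
        transferred=transferred,
        merged=merged,
        final=final,
        psm_level=psm_level,
        peptide_level=peptide_level,
        protein_groups=groups,
        static_model=static_model,
        clusters=clusters,
    )
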