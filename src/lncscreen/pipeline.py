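"""End-to-end orchestration: filter -> classify -> DE -> pair -> screen.

The pipeline consumes a :class:`~lncscreen.simulate.Bundle` (annotation,
coding evidence, counts; optionally sequences, precomputed energies, miRNA
hairpins, a qPCR table and a term map), applies every stage with the
thresholds in :class:`PipelineConfig`, and returns all stage tables plus a
report of the partition counts (classification split, per-genotype DE
counts, cis positional partition, tolerance categories).  All stages are
deterministic: identical config + inputs reproduce identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping

import pandas as pd

from . import identify, pairing, precursor, screen
from .expression import UNCHANGED, compute_fpkm, differential_expression
from .identify import CodingEvidence
from .simulate import Bundle

log = logging.getLogger("lncscreen")


@dataclass
class PipelineConfig:
    """Global thresholds; the defaults are the screen's operating point."""

    min_length: int = 200  # nt; candidates shorter than this are dropped
    vote_min: int = 3  # coding-potential votes needed for a consensus
    corr_min: float = 0.6  # both Pearson and Spearman must exceed this
    corr_absolute: bool = False
    cis_window: int = 10_000  # bp span-to-span window for cis assignment
    energy_max: float = -60.0  # kcal/mol gate for trans pairs
    fdr_max: float = 0.05
    lfc_min: float = 1.0  # |log2fc| for up/down states
    fdr_gate_for_states: bool = False  # states from fold change alone by default
    zero_score_is_coding: bool = False
    min_identity: float = 0.9  # precursor scan
    min_coverage: float = 0.9
    max_trans_candidates: int | None = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_length < 1 or self.vote_min not in range(0, 6):
            raise ValueError("min_length >= 1 and vote_min in 0..5 required")
        if not (-1 <= self.corr_min) or self.cis_window < 0:
            raise ValueError("corr_min >= -1 and cis_window >= 0 required")
        if not (0 <= self.fdr_max <= 1) or self.lfc_min < 0:
            raise ValueError("fdr_max in [0,1] and lfc_min >= 0 required")


@dataclass
class PipelineResult:
    classification: pd.DataFrame
    discard_log: pd.DataFrame
    de_tables: dict[str, pd.DataFrame]  # genotype -> DE table
    pairs: pd.DataFrame
    pair_skips: list[tuple[str, str, str]]
    tolerance_calls: list[screen.ToleranceCall]
    tolerance_summary: pd.DataFrame
    key_pairs: pd.DataFrame
    precursor_hits: pd.DataFrame
    qpcr: pd.DataFrame
    enrichment: pd.DataFrame
    report: dict = field(default_factory=dict)


def _check_inputs(bundle: Bundle) -> None:
    missing = []
    if not bundle.transcripts:
        missing.append("annotation (transcripts)")
    if bundle.evidence is None or bundle.evidence.empty:
        missing.append("coding evidence")
    if bundle.counts is None or bundle.counts.empty:
        missing.append("counts")
    if missing:
        raise ValueError(f"missing mandatory input(s): {', '.join(missing)}")


def run_pipeline(config: PipelineConfig, bundle: Bundle,
                 term_map: Mapping[str, list[str]] | None = None) -> PipelineResult:
    """Execute every stage in order and assemble the report."""
    _check_inputs(bundle)
    log.info("thresholds: %s", asdict(config))

    # --- filter + consensus classification ---------------------------------
    candidates, discard_log = identify.filter_candidates(
        bundle.transcripts, known_ids=bundle.known_ids, min_length=config.min_length
    )
    cand_ids = {t.transcript_id for t in candidates}
    evidence = [
        CodingEvidence(
            transcript_id=str(r.transcript_id),
            cpc_score=float(r.cpc), cnci_score=float(r.cnci), lgc_score=float(r.lgc),
            pfam_hit=bool(int(r.pfam)), swissprot_hit=bool(int(r.swissprot)),
        )
        for r in bundle.evidence.itertuples(index=False)
        if str(r.transcript_id) in cand_ids
    ]
    classification = identify.classify_all(
        evidence, vote_min=config.vote_min, zero_is_coding=config.zero_score_is_coding
    )
    lnc_ids = set(classification.loc[classification["call"] == "novel_lncRNA", "transcript_id"])
    novel_mrna_ids = set(classification.loc[classification["call"] == "novel_mRNA", "transcript_id"])
    by_id = {t.transcript_id: t for t in bundle.transcripts}
    known_set = set(bundle.known_ids) | {
        t.transcript_id for t in bundle.transcripts if t.origin == "known_mRNA"
    }
    mrna_ids = novel_mrna_ids | (known_set & set(by_id))
    log.info(
        "classification: %d lncRNA, %d novel mRNA, %d ambiguous, %d known mRNA",
        len(lnc_ids), len(novel_mrna_ids),
        int((classification["call"] == "ambiguous").sum()), len(known_set & set(by_id)),
    )

    # --- expression + per-genotype DE --------------------------------------
    counts = bundle.expression()
    lengths = bundle.lengths()
    fpkm = compute_fpkm(counts, lengths)
    de_tables = {
        g: differential_expression(
            counts, lengths, g,
            lfc_min=config.lfc_min, fdr_max=config.fdr_max,
            fdr_gate=config.fdr_gate_for_states,
        )
        for g in ("tolerant", "sensitive")
    }

    # --- target pairing ----------------------------------------------------
    de_mrnas = {
        fid
        for df in de_tables.values()
        for fid, st in zip(df["feature_id"], df["state"])
        if st != UNCHANGED and fid in mrna_ids
    }
    lncs = [by_id[i] for i in sorted(lnc_ids) if i in by_id]
    genes = [by_id[i] for i in sorted(mrna_ids)]
    energy_table = None
    if bundle.energies is not None and not bundle.energies.empty:
        energy_table = {
            (r.lncrna_id, r.target_id): float(r.energy)
            for r in bundle.energies.itertuples(index=False)
        }
    pairs, pair_skips = pairing.assign_targets(
        lncs, genes, fpkm,
        sequences=bundle.sequences or None,
        energy_table=energy_table,
        corr_min=config.corr_min, corr_absolute=config.corr_absolute,
        cis_window=config.cis_window, energy_max=config.energy_max,
        max_trans_candidates=config.max_trans_candidates,
        trans_universe=de_mrnas,
    )
    pair_table = pairing.pairs_to_frame(pairs)
    partition = pairing.cis_partition(pairs)

    # --- tolerance screen + key pairs --------------------------------------
    calls, summary = screen.screen_features(de_tables["tolerant"], de_tables["sensitive"])
    fold_changes = pd.concat(
        [df[["feature_id", "genotype", "log2fc"]] for df in de_tables.values()],
        ignore_index=True,
    )
    key_pairs = screen.select_key_pairs(pairs, calls, fold_changes)

    # --- optional stages ---------------------------------------------------
    prec_hits = pd.DataFrame()
    if bundle.hairpins and bundle.sequences:
        lnc_seqs = {i: bundle.sequences[i] for i in sorted(lnc_ids) if i in bundle.sequences}
        if lnc_seqs:
            prec_hits = precursor.hits_to_frame(
                precursor.precursor_scan(
                    lnc_seqs, bundle.hairpins,
                    min_identity=config.min_identity, min_coverage=config.min_coverage,
                )
            )
    qpcr_out = pd.DataFrame()
    qpcr_r2 = None
    if bundle.qpcr is not None and not bundle.qpcr.empty:
        rel = screen.relative_expression_ddct(bundle.qpcr)
        qlfc = screen.qpcr_log2_fold_changes(rel)
        seq_lfc = dict(
            zip(de_tables["tolerant"]["feature_id"], de_tables["tolerant"]["log2fc"])
        )
        merged = qlfc.assign(log2fc_seq=[seq_lfc.get(g) for g in qlfc["gene"]]).dropna()
        qpcr_out = merged
        if len(merged) >= 3:
            qpcr_r2 = screen.concordance_r2(
                merged["log2fc_seq"].to_numpy(), merged["log2fc_qpcr"].to_numpy()
            )
    enrichment = pd.DataFrame()
    if term_map:
        linked_lncs = {
            c.feature_id for c in calls
            if c.category != screen.NOT_LINKED and c.feature_id in lnc_ids
        }
        target_genes = {p.target_id for p in pairs if p.lncrna_id in linked_lncs}
        universe = set(mrna_ids)
        enrichment = screen.overrepresentation(target_genes & universe, term_map, universe)

    report = {
        "n_transcripts": len(bundle.transcripts),
        "n_candidates": len(candidates),
        "n_discarded": len(discard_log),
        "n_lncrna": len(lnc_ids),
        "n_novel_mrna": len(novel_mrna_ids),
        "n_ambiguous": int((classification["call"] == "ambiguous").sum()),
        "de_counts": {
            g: df["state"].value_counts().to_dict() for g, df in de_tables.items()
        },
        "n_pairs": len(pairs),
        "n_cis": partition["cis_total"],
        "n_trans": sum(1 for p in pairs if p.mode == "trans"),
        "cis_partition": partition,
        "tolerance_summary": dict(zip(summary["category"], summary["n"])),
        "n_key_pairs": len(key_pairs),
        "n_key_lncrnas": key_pairs["lncrna_id"].nunique() if len(key_pairs) else 0,
        "n_precursor_hits": len(prec_hits),
        "qpcr_r2": qpcr_r2,
        "thresholds": asdict(config),
    }
    return PipelineResult(
        classification=classification,
        discard_log=discard_log,
        de_tables=de_tables,
        pairs=pair_table,
        pair_skips=pair_skips,
        tolerance_calls=calls,
        tolerance_summary=summary,
        key_pairs=key_pairs,
        precursor_hits=prec_hits,
        qpcr=qpcr_out,
        enrichment=enrichment,
        report=report,
    )
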