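"""Scan lncRNAs for embedded miRNA hairpin sequences (sRNA precursor flags).

A lncRNA that carries a near-exact copy of a known miRNA hairpin may act as
a precursor for that miRNA.  Each hairpin is locally aligned against each
lncRNA (Smith-Waterman scoring: match +1, mismatch -2, gap -3) on both
strands; a hit is reported when the identity over the aligned region and
the fraction of the hairpin covered by the alignment both reach their
thresholds (defaults 0.9 / 0.9).  Only the best hit per (lncRNA, hairpin)
pair is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

_VALID = set("ACGUT")


@dataclass(frozen=True)
class PrecursorHit:
    lncrna_id: str
    mirna_id: str
    identity: float
    hairpin_coverage: float
    lnc_start: int  # 1-based closed interval on the lncRNA
    lnc_end: int
    strand: str  # "+" if the hairpin matches the lncRNA as given, "-" if its reverse complement does


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -3
    return aligner


def _norm(seq: str, name: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"{name}: invalid nucleotide characters {sorted(bad)}")
    return s


def _best_local(aligner: PairwiseAligner, lnc: str, hp: str):
    """(identity, coverage, lnc_start, lnc_end) of the best local alignment."""
    alns = aligner.align(lnc, hp)
    if len(alns) == 0 or alns.score <= 0:
        return 0.0, 0.0, 0, 0
    aln = alns[0]
    ta, qa = aln.aligned  # blocks on target (lnc) and query (hairpin)
    matches = 0
    aligned_cols = 0
    covered = 0
    for (ts, te), (qs, qe) in zip(ta, qa):
        aligned_cols += te - ts
        covered += qe - qs
        matches += sum(1 for i in range(te - ts) if lnc[ts + i] == hp[qs + i])
    # gap columns inside the local alignment count against identity
    span_t = ta[-1][1] - ta[0][0]
    span_q = qa[-1][1] - qa[0][0]
    total_cols = aligned_cols + (span_t - aligned_cols) + (span_q - covered)
    identity = matches / total_cols if total_cols else 0.0
    coverage = covered / len(hp)
    return identity, coverage, int(ta[0][0]) + 1, int(ta[-1][1])


def precursor_scan(
    lnc_seqs: Mapping[str, str],
    hairpin_seqs: Mapping[str, str],
    min_identity: float = 0.9,
    min_coverage: float = 0.9,
    both_strands: bool = True,
) -> list[PrecursorHit]:
    """Report the best qualifying hairpin hit per (lncRNA, hairpin) pair."""
    for thr, name in ((min_identity, "min_identity"), (min_coverage, "min_coverage")):
        if not 0 < thr <= 1:
            raise ValueError(f"{name} must be in (0, 1]")
    if not lnc_seqs or not hairpin_seqs:
        raise ValueError("sequence collections must be nonempty")
    aligner = _make_aligner()
    hits: list[PrecursorHit] = []
    for lnc_id, lnc_raw in lnc_seqs.items():
        lnc = _norm(lnc_raw, lnc_id)
        for hp_id, hp_raw in hairpin_seqs.items():
            hp = _norm(hp_raw, hp_id)
            candidates = [(hp, "+")]
            if both_strands:
                candidates.append((str(Seq(hp).reverse_complement()), "-"))
            best: PrecursorHit | None = None
            for hp_seq, strand in candidates:
                ident, cov, s, e = _best_local(aligner, lnc, hp_seq)
                if ident >= min_identity and cov >= min_coverage:
                    hit = PrecursorHit(lnc_id, hp_id, ident, cov, s, e, strand)
                    if best is None or (hit.identity, hit.hairpin_coverage) > (
                        best.identity, best.hairpin_coverage
                    ):
                        best = hit
            if best is not None:
                hits.append(best)
    return hits


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {id: sequence} (order-preserving)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def hits_to_frame(hits: Iterable[PrecursorHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": h.lncrna_id,
                "mirna_id": h.mirna_id,
                "identity": h.identity,
                "hairpin_coverage": h.hairpin_coverage,
                "lnc_start": h.lnc_start,
                "lnc_end": h.lnc_end,
                "strand": h.strand,
            }
            for h in hits
        ],
        columns=[
            "lncrna_id", "mirna_id", "identity", "hairpin_coverage",
            "lnc_start", "lnc_end", "strand",
        ],
    )
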