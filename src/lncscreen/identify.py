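"""Candidate filtering and consensus coding-potential classification.

Novel transcripts are first filtered by length (default: keep >= 200 nt) and
against a set of known-mRNA identifiers.  Each survivor then receives five
binary coding verdicts: three numeric coding-potential scores (CPC-, CNCI-
and LGC-style; score > 0 votes coding, < 0 noncoding) and two protein
database hit flags (Pfam, SwissProt; a hit votes coding).  The consensus
call is a majority over these five verdicts with one asymmetry: a transcript
is called a novel mRNA only when at least three verdicts vote coding AND at
least one protein-database hit supports it; it is a novel lncRNA when at
least three verdicts vote noncoding; anything else is ambiguous and excluded
from both downstream sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .annotation import TranscriptModel

#: reason codes used in the discard log
TOO_SHORT = "too_short"
KNOWN_MRNA = "known_mRNA"


@dataclass(frozen=True)
class CodingEvidence:
    """The five per-transcript coding verdicts (three scores, two DB flags)."""

    transcript_id: str
    cpc_score: float
    cnci_score: float
    lgc_score: float
    pfam_hit: bool
    swissprot_hit: bool

    def votes(self, zero_is_coding: bool = False) -> int:
        """Number of the five verdicts voting *coding* (0-5).

        A score of exactly 0 votes noncoding by default; ``zero_is_coding``
        flips that convention.
        """
        def score_votes(s: float) -> bool:
            return s > 0 or (zero_is_coding and s == 0)

        return (
            int(score_votes(self.cpc_score))
            + int(score_votes(self.cnci_score))
            + int(score_votes(self.lgc_score))
            + int(self.pfam_hit)
            + int(self.swissprot_hit)
        )


@dataclass(frozen=True)
class ClassCall:
    transcript_id: str
    coding_votes: int
    call: str  # novel_mRNA | novel_lncRNA | ambiguous


def filter_candidates(
    transcripts: Iterable[TranscriptModel],
    known_ids: Iterable[str] = (),
    min_length: int = 200,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Drop short transcripts and known mRNAs; log every discard.

    Returns the retained candidates (length >= ``min_length`` and id not in
    ``known_ids``) and a discard log with columns ``transcript_id`` and
    ``reason`` (``known_mRNA`` takes precedence over ``too_short`` when both
    apply, matching the order the filters are usually described in).
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    known = set(known_ids)
    kept: list[TranscriptModel] = []
    discards: list[tuple[str, str]] = []
    for t in transcripts:
        if t.transcript_id in known or t.origin == "known_mRNA":
            discards.append((t.transcript_id, KNOWN_MRNA))
        elif t.length < min_length:
            discards.append((t.transcript_id, TOO_SHORT))
        else:
            kept.append(t)
    log = pd.DataFrame(discards, columns=["transcript_id", "reason"])
    return kept, log


def consensus_classify(
    ev: CodingEvidence, vote_min: int = 3, zero_is_coding: bool = False
) -> ClassCall:
    """Five-way majority vote with the protein-database conjunction for mRNAs.

    novel_mRNA  iff coding_votes >= vote_min and (pfam_hit or swissprot_hit);
    novel_lncRNA iff (5 - coding_votes) >= vote_min; otherwise ambiguous.
    With vote_min = 3 the two conditions are mutually exclusive, so every
    transcript gets exactly one call.
    """
    votes = ev.votes(zero_is_coding=zero_is_coding)
    if votes >= vote_min and (ev.pfam_hit or ev.swissprot_hit):
        call = "novel_mRNA"
    elif (5 - votes) >= vote_min:
        call = "novel_lncRNA"
    else:
        call = "ambiguous"
    return ClassCall(transcript_id=ev.transcript_id, coding_votes=votes, call=call)


def classify_all(
    evidence: Iterable[CodingEvidence], vote_min: int = 3, zero_is_coding: bool = False
) -> pd.DataFrame:
    """Classify a collection of evidences into a tidy table."""
    rows = [
        consensus_classify(ev, vote_min=vote_min, zero_is_coding=zero_is_coding)
        for ev in evidence
    ]
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in rows],
            "coding_votes": [r.coding_votes for r in rows],
            "call": [r.call for r in rows],
        }
    )


def read_evidence(path) -> list[CodingEvidence]:
    """Read a tab-separated evidence table.

    Expected header: ``transcript_id cpc cnci lgc pfam swissprot`` with the
    flags encoded 0/1.  Records with a missing score are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["transcript_id", "cpc", "cnci", "lgc", "pfam", "swissprot"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"evidence table {path}: missing columns {missing}")
    if df[["cpc", "cnci", "lgc"]].isna().any().any():
        bad = df.loc[df[["cpc", "cnci", "lgc"]].isna().any(axis=1), "transcript_id"]
        raise ValueError(f"evidence table {path}: missing scores for {list(bad)}")
    return [
        CodingEvidence(
            transcript_id=str(r.transcript_id),
            cpc_score=float(r.cpc),
            cnci_score=float(r.cnci),
            lgc_score=float(r.lgc),
            pfam_hit=bool(int(r.pfam)),
            swissprot_hit=bool(int(r.swissprot)),
        )
        for r in df.itertuples(index=False)
    ]


def evidence_from_mapping(m: Mapping[str, tuple[float, float, float, bool, bool]]) -> list[CodingEvidence]:
    return [
        CodingEvidence(tid, c, n, l, bool(p), bool(s)) for tid, (c, n, l, p, s) in m.items()
    ]
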