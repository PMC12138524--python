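"""lncRNA-mRNA target pairing: correlation gate, cis window, trans energy.

A candidate lncRNA-mRNA pair must first pass an expression-correlation gate:
both Pearson and Spearman coefficients, computed on log2(FPKM + 1) across
all samples, must strictly exceed a threshold (default 0.6).  Surviving
pairs on the same chromosome that overlap or lie within the cis window
(default 10 kb span-to-span) become *cis* pairs with a positional subtype;
all other survivors become *trans* pairs iff their predicted RNA-RNA
hybridisation free energy is at or below a threshold (default -60 kcal/mol).
A pair is never both: cis takes precedence.

Energies can come from a precomputed table (e.g. an external hybridisation
tool's output) or from the built-in stand-in :func:`duplex_energy`, which
minimises, over all ungapped antisense offsets, the summed Watson-Crick
nearest-neighbor stack free energies (Turner 2004 37 degC parameters) of
complementary runs of at least 4 bp.  The stand-in ignores loop penalties
and wobble pairs; it is a deliberately simple, monotone proxy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import (
    CisSubtype,
    GeometryError,
    Relation,
    TranscriptModel,
    classify_cis_subtype,
    locus_geometry,
)
from .expression import ExpressionMatrix

# Turner 2004 Watson-Crick/Watson-Crick nearest-neighbor stack free energies
# (kcal/mol at 37 degC), keyed by the 5'->3' dinucleotide on one strand with
# both bases Watson-Crick paired.  The 10 unique published values expand to
# all 16 dimers by reverse-complement symmetry.
NN_STACK: dict[str, float] = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

CONSTANT_VECTOR = "constant_vector"
BELOW_THRESHOLD = "below_threshold"


@dataclass(frozen=True)
class CorrelationResult:
    pearson: float
    spearman: float
    passed: bool
    reason: str | None = None


@dataclass(frozen=True)
class TargetPair:
    """One gated lncRNA-mRNA regulatory pair."""

    lncrna_id: str
    target_id: str
    mode: str  # "cis" | "trans"
    cis_subtype: CisSubtype | None
    pearson: float
    spearman: float
    energy_kcal_mol: float | None = None
    gap_bp: int | None = None


def correlation_gate(
    x: Sequence[float],
    y: Sequence[float],
    threshold: float = 0.6,
    absolute: bool = False,
    log_transform: bool = True,
) -> CorrelationResult:
    """Compute Pearson and Spearman on log2(x+1), log2(y+1); gate on both.

    The pair passes iff both coefficients strictly exceed ``threshold``
    (their absolute values, with ``absolute``).  A constant vector makes the
    correlation undefined: the gate fails with reason ``constant_vector``.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1 or xv.size < 3:
        raise ValueError("expression vectors must be equal-length 1-D with n >= 3")
    if log_transform:
        xv = np.log2(xv + 1.0)
        yv = np.log2(yv + 1.0)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return CorrelationResult(np.nan, np.nan, False, CONSTANT_VECTOR)
    pear = float(stats.pearsonr(xv, yv).statistic)
    spear = float(stats.spearmanr(xv, yv).statistic)
    pv, sv = (abs(pear), abs(spear)) if absolute else (pear, spear)
    passed = pv > threshold and sv > threshold
    return CorrelationResult(pear, spear, passed, None if passed else BELOW_THRESHOLD)


def _validate_rna(seq: str, name: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"{name}: invalid RNA characters {sorted(bad)}")
    return s


def duplex_energy(seq_a: str, seq_b: str, min_run: int = 4) -> float:
    """Ungapped antisense hybridisation energy stand-in (kcal/mol, <= 0).

    Slides ``seq_b`` reversed along ``seq_a`` (antisense orientation), finds
    Watson-Crick complementary runs of at least ``min_run`` bases over all
    offsets, scores each run as the sum of its adjacent-pair nearest-neighbor
    stack energies, and returns the energy of the most stable single run
    (one contiguous helix; separate short runs are not summed, since without
    loop penalties their sum would grow without bound with sequence length).
    Returns 0.0 when no qualifying run exists anywhere.
    """
    a = _validate_rna(seq_a, "seq_a")
    b = _validate_rna(seq_b, "seq_b")
    if len(a) < 10 or len(b) < 10:
        raise ValueError("sequences must be at least 10 nt")
    # Antisense pairing: a[i] pairs b[j] with the strands antiparallel, so for
    # a fixed offset the paired position walks backwards along b.  Work with b
    # reversed and complemented: a pairing is then simple base equality, and
    # every offset is one diagonal of the la x lb match matrix.
    code = {"A": 0, "C": 1, "G": 2, "U": 3}
    av = np.array([code[c] for c in a], dtype=np.int8)
    bv = np.array([code[_COMPLEMENT[c]] for c in b[::-1]], dtype=np.int8)
    # stack energy of the a-dinucleotide whose 5' base sits at position k
    stack = np.array([NN_STACK[a[k : k + 2]] for k in range(len(a) - 1)])
    la, lb = len(av), len(bv)
    # Row-wise DP over the la x lb match matrix (each diagonal is one offset):
    # along each diagonal track the current run's length and accumulated stack
    # energy; keep the best (most negative) energy over all runs >= min_run.
    best = 0.0
    run_len = np.zeros(lb, dtype=np.int32)
    run_energy = np.zeros(lb)
    for i in range(la):
        m = av[i] == bv
        prev_len = np.empty_like(run_len)
        prev_len[0] = 0
        prev_len[1:] = run_len[:-1]
        prev_energy = np.empty_like(run_energy)
        prev_energy[0] = 0.0
        prev_energy[1:] = run_energy[:-1]
        run_len = np.where(m, prev_len + 1, 0)
        if i > 0:
            run_energy = np.where(m, prev_energy + np.where(prev_len > 0, stack[i - 1], 0.0), 0.0)
        else:
            run_energy = np.zeros(lb)
        live = run_len >= min_run
        if live.any():
            best = min(best, float(run_energy[live].min()))
    return best


def assign_targets(
    lncs: Iterable[TranscriptModel],
    genes: Iterable[TranscriptModel],
    expression: ExpressionMatrix,
    sequences: Mapping[str, str] | None = None,
    energy_table: Mapping[tuple[str, str], float] | None = None,
    corr_min: float = 0.6,
    corr_absolute: bool = False,
    cis_window: int = 10_000,
    energy_max: float = -60.0,
    max_trans_candidates: int | None = None,
    trans_universe: set[str] | None = None,
) -> tuple[list[TargetPair], list[tuple[str, str, str]]]:
    """Build the gated cis/trans pair set.

    For every lncRNA x gene candidate with expression for both members:
    the correlation gate is applied first; gated same-chromosome pairs
    overlapping or within ``cis_window`` bp become cis (with positional
    subtype); remaining gated pairs become trans iff their energy (from
    ``energy_table``, else :func:`duplex_energy` on ``sequences``) is at or
    below ``energy_max``.  ``trans_universe``, when given, restricts trans
    evaluation to the named targets (typically the differentially expressed
    mRNAs) — the quadratic trans search is the expensive step.  Returns the
    pairs plus a skip log of (lncrna_id, target_id, reason) tuples for trans
    candidates lacking both a sequence and a precomputed energy.
    """
    if expression.kind != "fpkm":
        raise ValueError("assign_targets expects an FPKM matrix")
    genes = list(genes)
    pairs: list[TargetPair] = []
    skipped: list[tuple[str, str, str]] = []
    n_trans = 0
    expr = expression.values
    for lnc in lncs:
        if lnc.transcript_id not in expr.index:
            skipped.append((lnc.transcript_id, "*", "no_expression"))
            continue
        x = expr.loc[lnc.transcript_id].to_numpy()
        for gene in genes:
            if gene.transcript_id not in expr.index:
                skipped.append((lnc.transcript_id, gene.transcript_id, "no_expression"))
                continue
            y = expr.loc[gene.transcript_id].to_numpy()
            corr = correlation_gate(x, y, threshold=corr_min, absolute=corr_absolute)
            if not corr.passed:
                continue
            if lnc.chrom == gene.chrom:
                geom = locus_geometry(lnc, gene)
                if geom.relation is Relation.OVERLAP or geom.gap_bp <= cis_window:
                    pairs.append(
                        TargetPair(
                            lncrna_id=lnc.transcript_id,
                            target_id=gene.transcript_id,
                            mode="cis",
                            cis_subtype=classify_cis_subtype(geom, window=cis_window),
                            pearson=corr.pearson,
                            spearman=corr.spearman,
                            gap_bp=geom.gap_bp,
                        )
                    )
                    continue
            # trans candidate
            if trans_universe is not None and gene.transcript_id not in trans_universe:
                continue
            if max_trans_candidates is not None and n_trans >= max_trans_candidates:
                skipped.append((lnc.transcript_id, gene.transcript_id, "candidate_cap"))
                continue
            n_trans += 1
            energy = None
            if energy_table is not None:
                energy = energy_table.get((lnc.transcript_id, gene.transcript_id))
            if energy is None and sequences is not None:
                sa = sequences.get(lnc.transcript_id)
                sb = sequences.get(gene.transcript_id)
                if sa is not None and sb is not None:
                    energy = duplex_energy(sa, sb)
            if energy is None:
                skipped.append((lnc.transcript_id, gene.transcript_id, "no_energy"))
                continue
            if energy <= energy_max:
                pairs.append(
                    TargetPair(
                        lncrna_id=lnc.transcript_id,
                        target_id=gene.transcript_id,
                        mode="trans",
                        cis_subtype=None,
                        pearson=corr.pearson,
                        spearman=corr.spearman,
                        energy_kcal_mol=float(energy),
                    )
                )
    return pairs, skipped


def pairs_to_frame(pairs: Iterable[TargetPair]) -> pd.DataFrame:
    """Tidy TSV-ready table of pairs."""
    return pd.DataFrame(
        {
            "lncrna_id": [p.lncrna_id for p in pairs],
            "target_id": [p.target_id for p in pairs],
            "mode": [p.mode for p in pairs],
            "subtype": [p.cis_subtype.value if p.cis_subtype else "" for p in pairs],
            "pearson": [p.pearson for p in pairs],
            "spearman": [p.spearman for p in pairs],
            "energy": [p.energy_kcal_mol if p.energy_kcal_mol is not None else "" for p in pairs],
            "gap_bp": [p.gap_bp if p.gap_bp is not None else "" for p in pairs],
        }
    )


def cis_partition(pairs: Iterable[TargetPair]) -> dict[str, int]:
    """Positional partition counts of the cis pairs (mirrors survey reports).

    Keys: ``Upstream``, ``Downstream``, ``overlap`` and the six overlap
    subtypes.  The invariant Upstream + Downstream + overlap = total cis and
    sum(six subtypes) = overlap is enforced by construction.
    """
    counts: dict[str, int] = {s.value: 0 for s in CisSubtype}
    counts["overlap"] = 0
    counts["cis_total"] = 0
    for p in pairs:
        if p.mode != "cis":
            continue
        counts["cis_total"] += 1
        assert p.cis_subtype is not None
        counts[p.cis_subtype.value] += 1
        if p.cis_subtype not in (CisSubtype.UPSTREAM, CisSubtype.DOWNSTREAM):
            counts["overlap"] += 1
    return counts
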