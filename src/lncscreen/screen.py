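"""Cross-genotype contrast screening, key-pair selection, enrichment, qPCR.

A feature's cadmium response is summarised per genotype by a three-state
call (up / down / unchanged).  The tolerance screen contrasts the two
genotypes' states:

* ``T_up``      — up in the tolerant line, down or unchanged in the sensitive;
* ``T_down``    — down in the tolerant line, up or unchanged in the sensitive;
* ``S_only``    — unchanged in the tolerant line, up or down in the sensitive;
* ``not_linked``— concordant (same state in both genotypes).

Features in the first three categories are candidate tolerance regulators.
Key lncRNA-mRNA pairs are those whose lncRNA is tolerance-linked AND whose
target's state differs between the genotypes.

Also here: a generic hypergeometric over-representation test against a
user-supplied term map, the comparative-Ct (2^-ddCt) conversion of qPCR
cycle thresholds into relative expression, and the R^2 concordance between
sequencing and qPCR fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import DOWN, STATES, UNCHANGED, UP
from .pairing import TargetPair

T_UP = "T_up"
T_DOWN = "T_down"
S_ONLY = "S_only"
NOT_LINKED = "not_linked"
CATEGORIES = (T_UP, T_DOWN, S_ONLY, NOT_LINKED)


@dataclass(frozen=True)
class ToleranceCall:
    feature_id: str
    state_tolerant: str
    state_sensitive: str
    category: str


def contrast_classify(state_tolerant: str, state_sensitive: str) -> str:
    """Map a (tolerant, sensitive) state pair to its tolerance category.

    Concordant pairs — (up, up), (down, down), (unchanged, unchanged) —
    carry no genotype contrast and map to ``not_linked``.
    """
    for s in (state_tolerant, state_sensitive):
        if s not in STATES:
            raise ValueError(f"invalid state {s!r}")
    if state_tolerant == state_sensitive:
        return NOT_LINKED
    if state_tolerant == UP:
        return T_UP
    if state_tolerant == DOWN:
        return T_DOWN
    return S_ONLY  # unchanged in tolerant, up/down in sensitive


def screen_features(
    de_tolerant: pd.DataFrame, de_sensitive: pd.DataFrame
) -> tuple[list[ToleranceCall], pd.DataFrame]:
    """One ToleranceCall per feature in the union of both genotypes' DE tables.

    A feature present in only one genotype is treated as unchanged in the
    other and logged.  Returns the calls and a per-category summary table.
    """
    st = dict(zip(de_tolerant["feature_id"], de_tolerant["state"]))
    ss = dict(zip(de_sensitive["feature_id"], de_sensitive["state"]))
    universe = list(dict.fromkeys(list(st) + list(ss)))
    calls = []
    for fid in universe:
        a = st.get(fid, UNCHANGED)
        b = ss.get(fid, UNCHANGED)
        calls.append(ToleranceCall(fid, a, b, contrast_classify(a, b)))
    summary = (
        pd.Series([c.category for c in calls])
        .value_counts()
        .reindex(CATEGORIES, fill_value=0)
        .rename_axis("category")
        .reset_index(name="n")
    )
    return calls, summary


def select_key_pairs(
    pairs: Iterable[TargetPair] | pd.DataFrame,
    calls: Iterable[ToleranceCall],
    fold_changes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Retain pairs whose lncRNA is tolerance-linked and whose target state
    differs between genotypes.

    ``pairs`` may be TargetPair objects or a DataFrame with columns
    lncrna_id/target_id.  ``fold_changes`` (optional) is a long table with
    columns feature_id, genotype, log2fc used to annotate the output.
    """
    call_map = {c.feature_id: c for c in calls}
    if isinstance(pairs, pd.DataFrame):
        pair_iter = list(pairs[["lncrna_id", "target_id"]].itertuples(index=False))
    else:
        pair_iter = [(p.lncrna_id, p.target_id) for p in pairs]
    lfc = {}
    if fold_changes is not None:
        for r in fold_changes.itertuples(index=False):
            lfc[(r.feature_id, r.genotype)] = r.log2fc
    rows = []
    for lnc_id, tgt_id in pair_iter:
        lc = call_map.get(lnc_id)
        tc = call_map.get(tgt_id)
        if lc is None or tc is None:
            raise ValueError(f"missing tolerance call for pair ({lnc_id}, {tgt_id})")
        if lc.category == NOT_LINKED:
            continue
        if tc.state_tolerant == tc.state_sensitive:
            continue
        rows.append(
            {
                "lncrna_id": lnc_id,
                "target_id": tgt_id,
                "lnc_category": lc.category,
                "lnc_state_tolerant": lc.state_tolerant,
                "lnc_state_sensitive": lc.state_sensitive,
                "target_state_tolerant": tc.state_tolerant,
                "target_state_sensitive": tc.state_sensitive,
                "lnc_log2fc_tolerant": lfc.get((lnc_id, "tolerant"), np.nan),
                "lnc_log2fc_sensitive": lfc.get((lnc_id, "sensitive"), np.nan),
                "target_log2fc_tolerant": lfc.get((tgt_id, "tolerant"), np.nan),
                "target_log2fc_sensitive": lfc.get((tgt_id, "sensitive"), np.nan),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "lncrna_id", "target_id", "lnc_category",
            "lnc_state_tolerant", "lnc_state_sensitive",
            "target_state_tolerant", "target_state_sensitive",
            "lnc_log2fc_tolerant", "lnc_log2fc_sensitive",
            "target_log2fc_tolerant", "target_log2fc_sensitive",
        ],
    )


def overrepresentation(
    genes: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation test per term.

    For a term with K members in a universe of N, and a query set of n genes
    with k in the term: p = P(X >= k) for X ~ Hypergeom(N, K, n).  q-values
    are Benjamini-Hochberg; the table is sorted by p ascending.
    """
    from .expression import bh_fdr

    uni = set(universe)
    query = set(genes)
    if not query <= uni:
        raise ValueError("query genes must be a subset of the universe")
    if not term_map:
        raise ValueError("term_map is empty")
    if not query:
        return pd.DataFrame(columns=["term", "k", "n", "K", "N", "pvalue", "qvalue"])
    N, n = len(uni), len(query)
    rows = []
    for term, members in term_map.items():
        mem = set(members) & uni
        K = len(mem)
        k = len(mem & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "pvalue": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["qvalue"] = bh_fdr(df["pvalue"].to_numpy())
    return df.sort_values("pvalue", kind="mergesort").reset_index(drop=True)


def relative_expression_ddct(records: pd.DataFrame, control_group: str = "control") -> pd.DataFrame:
    """Comparative-Ct (2^-ddCt) relative expression per gene.

    ``records`` columns: sample, group, gene, target_ct, reference_ct.
    dCt = target_ct - reference_ct; ddCt = dCt - mean(dCt of the gene's
    control group); relative expression = 2^-ddCt.  The control-group mean
    (not a single calibrator sample) anchors ddCt, so the control group's
    mean ddCt is 0 by construction.
    """
    required = {"sample", "group", "gene", "target_ct", "reference_ct"}
    if not required.issubset(records.columns):
        raise ValueError(f"qPCR table must have columns {sorted(required)}")
    if records["reference_ct"].isna().any():
        bad = records.loc[records["reference_ct"].isna(), "sample"].tolist()
        raise ValueError(f"missing reference Ct for sample(s) {bad}")
    if records["target_ct"].isna().any():
        bad = records.loc[records["target_ct"].isna(), "sample"].tolist()
        raise ValueError(f"missing target Ct for sample(s) {bad}")
    df = records.copy()
    df["delta_ct"] = df["target_ct"] - df["reference_ct"]
    out = []
    for gene, grp in df.groupby("gene", sort=False):
        ctl = grp.loc[grp["group"] == control_group, "delta_ct"]
        if ctl.empty:
            raise ValueError(f"gene {gene!r} has no {control_group!r} samples")
        anchor = ctl.mean()
        g = grp.copy()
        g["delta_delta_ct"] = g["delta_ct"] - anchor
        g["relative_expression"] = 2.0 ** (-g["delta_delta_ct"])
        out.append(g)
    return pd.concat(out, ignore_index=True)


def qpcr_log2_fold_changes(rel: pd.DataFrame, treated_group: str = "treated") -> pd.DataFrame:
    """Per-gene log2 mean relative expression of the treated group.

    Because the control group's mean ddCt is 0, the treated group's mean
    relative expression is itself the fold change vs control.
    """
    rows = []
    for gene, grp in rel.groupby("gene", sort=False):
        tr = grp.loc[grp["group"] == treated_group, "relative_expression"]
        if tr.empty:
            raise ValueError(f"gene {gene!r} has no {treated_group!r} samples")
        rows.append({"gene": gene, "log2fc_qpcr": float(np.log2(tr.mean()))})
    return pd.DataFrame(rows)


def concordance_r2(seq_lfc: Sequence[float], qpcr_lfc: Sequence[float]) -> float:
    """Coefficient of determination of an OLS fit of sequencing on qPCR fold changes."""
    x = np.asarray(qpcr_lfc, dtype=float)
    y = np.asarray(seq_lfc, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("fold-change vectors must be equal-length 1-D with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance vector: R^2 undefined")
    res = stats.linregress(x, y)
    return float(res.rvalue**2)
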