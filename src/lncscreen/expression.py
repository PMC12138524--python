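"""FPKM quantification, per-genotype differential expression, three-state calls.

The design is two genotypes (a stress-tolerant and a stress-sensitive line)
x two treatments (control, cadmium) x replicates.  Expression is normalised
to FPKM:

    fpkm(f, s) = count(f, s) * 1e9 / (length(f) * library_size(s))

For each genotype, the cadmium-vs-control contrast is summarised as

    log2fc = log2((mean FPKM Cd + eps) / (mean FPKM control + eps))

with a pseudocount eps = 1 applied only when one of the means is zero, so
that exact ratios between nonzero means are preserved.  Significance comes
from a pooled-count two-proportion binomial test (the pooled count of a
feature in the treated arm against the two arms' summed library sizes),
followed by Benjamini-Hochberg FDR control across all features of the
genotype.  The fold change is then digitised by the three-state rule:
up if log2fc >= +1, down if log2fc <= -1, unchanged otherwise; optionally
up/down additionally require FDR <= 0.05 (the "FDR gate").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"
STATES = (UP, DOWN, UNCHANGED)


@dataclass(frozen=True)
class SampleInfo:
    sample: str
    genotype: str  # "tolerant" | "sensitive"
    treatment: str  # "control" | "cd"
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in {"tolerant", "sensitive"}:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.treatment not in {"control", "cd"}:
            raise ValueError(f"unknown treatment {self.treatment!r}")


@dataclass
class ExpressionMatrix:
    """Feature x sample matrix of counts or FPKM with its sample sheet."""

    values: pd.DataFrame  # index: feature ids, columns: sample names
    samples: list[SampleInfo]
    kind: str = "counts"  # "counts" | "fpkm"

    def __post_init__(self) -> None:
        if self.kind not in {"counts", "fpkm"}:
            raise ValueError(f"kind must be counts or fpkm, got {self.kind!r}")
        names = [s.sample for s in self.samples]
        if list(self.values.columns) != names:
            raise ValueError("sample sheet order does not match matrix columns")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dup[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    def columns_for(self, genotype: str, treatment: str | None = None) -> list[str]:
        return [
            s.sample
            for s in self.samples
            if s.genotype == genotype and (treatment is None or s.treatment == treatment)
        ]


@dataclass(frozen=True)
class DERecord:
    feature_id: str
    genotype: str
    log2fc: float
    pvalue: float
    fdr: float
    state: str


def compute_fpkm(counts: ExpressionMatrix, lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Length- and depth-normalise raw counts to FPKM.

    Library size is the per-sample column sum of counts; a zero library size
    or a missing/non-positive feature length is an error.
    """
    if counts.kind != "counts":
        raise ValueError("compute_fpkm expects a counts matrix")
    missing = [f for f in counts.values.index if f not in lengths]
    if missing:
        raise ValueError(f"no length for feature(s) {missing[:5]}")
    lens = np.array([lengths[f] for f in counts.values.index], dtype=float)
    if (lens <= 0).any():
        bad = counts.values.index[lens <= 0].tolist()
        raise ValueError(f"non-positive length for feature(s) {bad[:5]}")
    lib = counts.values.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = counts.values.columns[lib <= 0].tolist()
        raise ValueError(f"zero library size for sample(s) {bad}")
    fpkm = counts.values.to_numpy(dtype=float) * 1e9 / (lens[:, None] * lib[None, :])
    return ExpressionMatrix(
        values=pd.DataFrame(fpkm, index=counts.values.index, columns=counts.values.columns),
        samples=counts.samples,
        kind="fpkm",
    )


def log2_fold_change(mean_cd: float, mean_control: float, eps: float = 1.0) -> float:
    """log2 ratio of treated to control means; eps only when a mean is zero."""
    if mean_cd == 0.0 or mean_control == 0.0:
        return float(np.log2((mean_cd + eps) / (mean_control + eps)))
    return float(np.log2(mean_cd / mean_control))


def pooled_binomial_pvalue(
    count_cd: float, count_control: float, lib_cd: float, lib_control: float
) -> float:
    """Two-sided binomial test on pooled counts.

    Under the null of equal relative abundance, a fragment from the pooled
    count lands in the treated arm with probability lib_cd/(lib_cd+lib_control).
    """
    total = int(round(count_cd + count_control))
    if total == 0:
        return 1.0
    p0 = lib_cd / (lib_cd + lib_control)
    return float(stats.binomtest(int(round(count_cd)), total, p0).pvalue)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_state(log2fc: float, fdr: float = 0.0, lfc_min: float = 1.0,
               fdr_max: float = 0.05, fdr_gate: bool = False) -> str:
    """Digitise a fold change into up / down / unchanged.

    ``up`` iff log2fc >= +lfc_min, ``down`` iff log2fc <= -lfc_min, otherwise
    ``unchanged``; with ``fdr_gate`` a nominally up/down feature whose FDR
    exceeds ``fdr_max`` is demoted to unchanged.
    """
    if not np.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    if log2fc >= lfc_min:
        state = UP
    elif log2fc <= -lfc_min:
        state = DOWN
    else:
        return UNCHANGED
    if fdr_gate and fdr > fdr_max:
        return UNCHANGED
    return state


def differential_expression(
    counts: ExpressionMatrix,
    lengths: Mapping[str, int],
    genotype: str,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
    fdr_gate: bool = False,
    eps: float = 1.0,
) -> pd.DataFrame:
    """Cd-vs-control DE table for one genotype.

    Returns a DataFrame with columns feature_id, genotype, log2fc, pvalue,
    fdr, state.  Fold changes come from mean FPKM per arm; p-values from the
    pooled-count binomial test; FDR from BH over all features of the genotype.
    """
    if counts.kind != "counts":
        raise ValueError("differential_expression expects raw counts")
    cd_cols = counts.columns_for(genotype, "cd")
    ctl_cols = counts.columns_for(genotype, "control")
    if not cd_cols or not ctl_cols:
        raise ValueError(f"genotype {genotype!r} lacks a treatment arm")
    fpkm = compute_fpkm(counts, lengths)
    mean_cd = fpkm.values[cd_cols].mean(axis=1)
    mean_ctl = fpkm.values[ctl_cols].mean(axis=1)
    pooled_cd = counts.values[cd_cols].sum(axis=1)
    pooled_ctl = counts.values[ctl_cols].sum(axis=1)
    lib_cd = float(counts.values[cd_cols].to_numpy().sum())
    lib_ctl = float(counts.values[ctl_cols].to_numpy().sum())
    lfc = np.array(
        [log2_fold_change(c, k, eps) for c, k in zip(mean_cd, mean_ctl)]
    )
    pvals = np.array(
        [
            pooled_binomial_pvalue(c, k, lib_cd, lib_ctl)
            for c, k in zip(pooled_cd, pooled_ctl)
        ]
    )
    fdr = bh_fdr(pvals)
    states = [
        call_state(l, q, lfc_min=lfc_min, fdr_max=fdr_max, fdr_gate=fdr_gate)
        for l, q in zip(lfc, fdr)
    ]
    return pd.DataFrame(
        {
            "feature_id": counts.values.index,
            "genotype": genotype,
            "log2fc": lfc,
            "pvalue": pvals,
            "fdr": fdr,
            "state": states,
        }
    ).reset_index(drop=True)


def read_counts(counts_path, sheet_path) -> ExpressionMatrix:
    """Read a TSV count matrix (first column feature id) plus a sample sheet."""
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(sheet_path, sep="\t")
    required = {"sample", "genotype", "treatment", "replicate"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    samples = [
        SampleInfo(str(r.sample), str(r.genotype), str(r.treatment), int(r.replicate))
        for r in sheet.itertuples(index=False)
    ]
    values = values[[s.sample for s in samples]]
    return ExpressionMatrix(values=values, samples=samples, kind="counts")
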