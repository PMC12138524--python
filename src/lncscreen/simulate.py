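"""Synthetic desk-scale input bundles with planted ground truth.

The generator emulates the study design the screening pipeline expects: two
genotypes (stress-tolerant and stress-sensitive) x two treatments (control,
cadmium) x three replicates, with

* a GTF of known mRNAs, novel mRNAs, novel lncRNAs and deliberately short
  transcripts, including cassettes that realise every cis geometry
  (exon-overlapping, intronic, span-overlapping — each on both strands —
  plus upstream/downstream neighbours within the 10 kb window) and distant
  loci for trans pairs;
* a coding-evidence table with class-conditional scores (coding ~ N(+2,
  0.5), noncoding ~ N(-2, 0.5)) and class-conditional protein-DB hit flags;
* a negative-binomial count matrix around planted per-arm means, where
  planted up/down states shift the cadmium arm by 2^(+-effect);
* transcript FASTA with planted antisense-complementary segments for trans
  pairs and embedded miRNA hairpins for precursor lncRNAs;
* a qPCR Ct table whose 2^-ddCt analysis recovers the planted fold changes;
* a ground-truth manifest covering every emitted feature.

Members of a planted pair share their per-sample expression profile (a
multiplicative log-normal jitter plus identical planted states), so the
expression-correlation gate can recover them.  In noiseless mode every
stochastic layer collapses to its mean: counts are the rounded planted
means, scores are exactly +-2, flags are deterministic, and Ct values are
noise-free — the limit in which the pipeline must recover the ground truth
exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .expression import DOWN, UNCHANGED, UP, ExpressionMatrix, SampleInfo
from .screen import contrast_classify

GENOTYPES = ("tolerant", "sensitive")
TREATMENTS = ("control", "cd")

_CIS_SUBTYPES = (
    "Sense", "AntiSense", "Intronic", "AntiIntronic",
    "Overlapping", "AntiOverlapping", "Upstream", "Downstream",
)


class ParameterError(ValueError):
    """Infeasible or inconsistent simulation parameters."""


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults are the study conditions.

    Counts follow NB(mean, dispersion) via the gamma-Poisson mixture; planted
    differential effects are ``2**effect_log2fc`` on the cadmium arm.
    """

    n_known_mrna: int = 40
    n_novel_mrna: int = 80
    n_lncrna: int = 170
    n_too_short: int = 10
    cis_pairs_per_subtype: int = 3
    n_trans_pairs: int = 12
    n_precursor_lnc: int = 4
    n_hairpins: int = 6
    n_qpcr_genes: int = 10
    replicates: int = 3
    effect_log2fc: float = 3.0
    nb_dispersion: float = 0.1
    state_prob_up: float = 0.15
    state_prob_down: float = 0.15
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    profile_log_sd: float = 0.6
    score_mu: float = 2.0
    score_sd: float = 0.5
    db_hit_p_coding: float = 0.9
    db_hit_p_noncoding: float = 0.05
    lnc_length: tuple[int, int] = (350, 600)
    mrna_length: tuple[int, int] = (600, 1000)
    short_length: int = 150
    hairpin_length: int = 80
    trans_insert_length: int = 48
    trans_insert_gc: float = 0.7
    cassette_spacing: int = 50_000
    chrom_length: int = 10_000_000
    ct_intercept: float = 25.0
    ct_reference: float = 20.0
    ct_noise_sd: float = 0.15
    noiseless: bool = False

    def __post_init__(self) -> None:
        n_cis = self.cis_pairs_per_subtype * len(_CIS_SUBTYPES)
        if n_cis + self.n_trans_pairs + self.n_precursor_lnc > self.n_lncrna:
            raise ParameterError("not enough lncRNAs for the requested pairs")
        if n_cis + self.n_trans_pairs > self.n_novel_mrna:
            raise ParameterError("not enough novel mRNAs for the requested pairs")
        if self.n_precursor_lnc > 0 and self.n_hairpins < 1:
            raise ParameterError("precursor lncRNAs requested but no hairpins")
        if self.n_qpcr_genes > self.n_novel_mrna:
            raise ParameterError("more qPCR genes than novel mRNAs")
        for label, n in (("cis cassettes", n_cis), ("trans loci", self.n_trans_pairs)):
            if (n + 1) * self.cassette_spacing > self.chrom_length:
                raise ParameterError(
                    f"{label} do not fit on a {self.chrom_length} bp chromosome "
                    f"at {self.cassette_spacing} bp spacing"
                )
        n_rest = self.n_known_mrna + self.n_too_short + self.n_novel_mrna + self.n_lncrna
        if (n_rest + 1) * 25_000 > self.chrom_length:
            raise ParameterError("background loci do not fit on the background chromosome")


@dataclass
class GroundTruthManifest:
    """Planted truth for every emitted feature; the recovery-testing oracle."""

    seed: int
    params: dict
    classes: dict[str, str]  # tid -> known_mRNA | novel_mRNA | novel_lncRNA
    too_short_ids: list[str]
    de_states: dict[str, dict[str, str]]  # genotype -> {feature: state}
    tolerance_categories: dict[str, str]
    cis_pairs: list[dict]  # {lncrna_id, target_id, subtype}
    trans_pairs: list[dict]  # {lncrna_id, target_id}
    precursor_pairs: list[dict]  # {lncrna_id, mirna_id}
    qpcr_log2fc: dict[str, float]  # gene -> planted tolerant-genotype log2fc

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class Bundle:
    """In-memory input bundle for the whole pipeline.

    Simulated bundles carry a manifest; bundles assembled from user files
    may leave the optional members empty.
    """

    transcripts: list[TranscriptModel]
    known_ids: list[str]
    evidence: pd.DataFrame
    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    sequences: dict[str, str] = field(default_factory=dict)
    hairpins: dict[str, str] = field(default_factory=dict)
    energies: pd.DataFrame = field(default_factory=pd.DataFrame)
    qpcr: pd.DataFrame = field(default_factory=pd.DataFrame)
    manifest: GroundTruthManifest | None = None

    def expression(self) -> ExpressionMatrix:
        samples = [
            SampleInfo(str(r.sample), str(r.genotype), str(r.treatment), int(r.replicate))
            for r in self.sample_sheet.itertuples(index=False)
        ]
        return ExpressionMatrix(values=self.counts.copy(), samples=samples, kind="counts")

    def lengths(self) -> dict[str, int]:
        return {t.transcript_id: t.length for t in self.transcripts}


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), size=n, p=p))


def _draw_states(rng: np.random.Generator, p: SimulationParams) -> tuple[str, str]:
    probs = [p.state_prob_up, p.state_prob_down, 1 - p.state_prob_up - p.state_prob_down]
    return tuple(rng.choice([UP, DOWN, UNCHANGED], size=2, p=probs))


def _single_exon(tid, gid, chrom, strand, start, length, origin="novel_candidate"):
    return TranscriptModel(tid, gid, chrom, strand, ((start, start + length - 1),), origin)


def _cassette(p: SimulationParams, subtype: str, chrom: str, origin: int,
              lnc_id: str, tgt_id: str, lnc_len: int, tgt_len: int):
    """Transcript pair realising one planted cis geometry (lncRNA on '+')."""
    o = origin
    gstrand = "-" if subtype.startswith("Anti") else "+"
    lgene, tgene = f"G_{lnc_id}", f"G_{tgt_id}"
    if subtype in ("Sense", "AntiSense"):
        lnc = _single_exon(lnc_id, lgene, chrom, "+", o + 300, lnc_len)
        tgt = _single_exon(tgt_id, tgene, chrom, gstrand, o, tgt_len)
    elif subtype in ("Intronic", "AntiIntronic"):
        # target has two exons; the lncRNA sits strictly inside the intron
        half = tgt_len // 2
        intron_len = lnc_len + 400
        tgt = TranscriptModel(
            tgt_id, tgene, chrom, gstrand,
            ((o, o + half - 1), (o + half + intron_len, o + tgt_len + intron_len - 1)),
        )
        lnc = _single_exon(lnc_id, lgene, chrom, "+", o + half + 200, lnc_len)
    elif subtype in ("Overlapping", "AntiOverlapping"):
        # lncRNA has two exons; the target's single exon sits in the lncRNA's
        # intron, so the spans overlap with no exonic overlap
        half = lnc_len // 2
        intron_len = tgt_len + 400
        lnc = TranscriptModel(
            lnc_id, lgene, chrom, "+",
            ((o, o + half - 1), (o + half + intron_len, o + lnc_len + intron_len - 1)),
        )
        tgt = _single_exon(tgt_id, tgene, chrom, gstrand, o + half + 200, tgt_len)
    elif subtype == "Upstream":
        # target upstream of a '+'-strand lncRNA: before its 5' end
        tgt = _single_exon(tgt_id, tgene, chrom, "+", o, tgt_len)
        lnc = _single_exon(lnc_id, lgene, chrom, "+", o + tgt_len + 3000, lnc_len)
    elif subtype == "Downstream":
        lnc = _single_exon(lnc_id, lgene, chrom, "+", o, lnc_len)
        tgt = _single_exon(tgt_id, tgene, chrom, "+", o + lnc_len + 3000, tgt_len)
    else:  # pragma: no cover
        raise ParameterError(f"unknown subtype {subtype}")
    return lnc, tgt


def simulate_dataset(params: SimulationParams | None = None, seed: int = 0) -> Bundle:
    """Generate a full input bundle plus its ground-truth manifest."""
    p = params or SimulationParams()
    rng = np.random.default_rng(seed)

    lnc_ids = [f"LNC{i:04d}" for i in range(p.n_lncrna)]
    novel_ids = [f"NOV{i:04d}" for i in range(p.n_novel_mrna)]
    known_ids = [f"KWN{i:04d}" for i in range(p.n_known_mrna)]
    short_ids = [f"SRT{i:04d}" for i in range(p.n_too_short)]

    lnc_lens = {t: int(rng.integers(*p.lnc_length)) for t in lnc_ids}
    mrna_lens = {t: int(rng.integers(*p.mrna_length)) for t in novel_ids + known_ids}

    n_cis = p.cis_pairs_per_subtype * len(_CIS_SUBTYPES)
    cis_lncs, trans_lncs = lnc_ids[:n_cis], lnc_ids[n_cis : n_cis + p.n_trans_pairs]
    prec_lncs = lnc_ids[n_cis + p.n_trans_pairs : n_cis + p.n_trans_pairs + p.n_precursor_lnc]
    cis_tgts = novel_ids[:n_cis]
    trans_tgts = novel_ids[n_cis : n_cis + p.n_trans_pairs]

    transcripts: list[TranscriptModel] = []
    cis_pairs = []
    for i, (lnc_id, tgt_id) in enumerate(zip(cis_lncs, cis_tgts)):
        subtype = _CIS_SUBTYPES[i % len(_CIS_SUBTYPES)]
        lnc, tgt = _cassette(
            p, subtype, "chr1", (i + 1) * p.cassette_spacing,
            lnc_id, tgt_id, lnc_lens[lnc_id], mrna_lens[tgt_id],
        )
        transcripts += [lnc, tgt]
        cis_pairs.append({"lncrna_id": lnc_id, "target_id": tgt_id, "subtype": subtype})

    trans_pairs = []
    for i, (lnc_id, tgt_id) in enumerate(zip(trans_lncs, trans_tgts)):
        o = (i + 1) * p.cassette_spacing
        transcripts.append(_single_exon(lnc_id, f"G_{lnc_id}", "chr2", "+", o, lnc_lens[lnc_id]))
        transcripts.append(
            _single_exon(tgt_id, f"G_{tgt_id}", "chr4", "+", o, mrna_lens[tgt_id])
        )
        trans_pairs.append({"lncrna_id": lnc_id, "target_id": tgt_id})

    # everything else on a background chromosome, spaced beyond the cis window
    rest = (
        [(t, lnc_lens[t]) for t in lnc_ids[n_cis + p.n_trans_pairs :]]
        + [(t, mrna_lens[t]) for t in novel_ids[n_cis + p.n_trans_pairs :]]
        + [(t, mrna_lens[t]) for t in known_ids]
        + [(t, p.short_length) for t in short_ids]
    )
    for i, (tid, length) in enumerate(rest):
        strand = "+" if i % 2 == 0 else "-"
        origin = "known_mRNA" if tid.startswith("KWN") else "novel_candidate"
        transcripts.append(
            _single_exon(tid, f"G_{tid}", "chr3", strand, (i + 1) * 25_000, length, origin)
        )

    # ---- planted classes and coding evidence -------------------------------
    classes = {t: "novel_lncRNA" for t in lnc_ids}
    classes.update({t: "novel_mRNA" for t in novel_ids})
    classes.update({t: "known_mRNA" for t in known_ids})
    classes.update({t: "novel_lncRNA" for t in short_ids})

    ev_rows = []
    for tid in lnc_ids + novel_ids + short_ids:
        coding = classes[tid] == "novel_mRNA"
        mu = p.score_mu if coding else -p.score_mu
        if p.noiseless:
            scores = (mu, mu, mu)
            pfam = swiss = coding
        else:
            scores = tuple(rng.normal(mu, p.score_sd, size=3))
            hit_p = p.db_hit_p_coding if coding else p.db_hit_p_noncoding
            pfam, swiss = (rng.random() < hit_p), (rng.random() < hit_p)
        ev_rows.append(
            {"transcript_id": tid, "cpc": scores[0], "cnci": scores[1],
             "lgc": scores[2], "pfam": int(pfam), "swissprot": int(swiss)}
        )
    evidence = pd.DataFrame(ev_rows)

    # ---- planted DE states and counts --------------------------------------
    all_ids = [t.transcript_id for t in transcripts]
    paired_targets = {d["target_id"]: d["lncrna_id"] for d in cis_pairs + trans_pairs}
    states: dict[str, tuple[str, str]] = {}
    trans_lnc_set = set(trans_lncs)
    for tid in all_ids:
        if tid in paired_targets:
            continue  # inherits its lncRNA's states below
        st = _draw_states(rng, p)
        if tid in trans_lnc_set:
            # trans targets must be differentially expressed somewhere, or the
            # screen's trans candidate universe (DE mRNAs) can never see them
            while st == (UNCHANGED, UNCHANGED):
                st = _draw_states(rng, p)
        states[tid] = st
    for tgt, lnc in paired_targets.items():
        states[tgt] = states[lnc]

    # shared per-sample profile per pair; singletons get their own
    group_of = {tid: tid for tid in all_ids}
    for d in cis_pairs + trans_pairs:
        group_of[d["target_id"]] = d["lncrna_id"]
    # Shared per-sample expression profile per pair group (singletons get
    # their own).  Profiles are renormalised to mean 1 within each of the four
    # genotype x treatment arms, so they create within-arm co-variation for
    # the correlation gate without perturbing arm means (and hence planted
    # fold changes).
    n_samples = 2 * 2 * p.replicates
    profiles = {}
    for g in sorted(set(group_of.values())):
        prof = rng.lognormal(0.0, p.profile_log_sd, size=n_samples)
        arms = prof.reshape(4, p.replicates)
        profiles[g] = (arms / arms.mean(axis=1, keepdims=True)).ravel()

    sample_rows = []
    for genotype in GENOTYPES:
        for treatment in TREATMENTS:
            for rep in range(1, p.replicates + 1):
                sample_rows.append(
                    {"sample": f"{genotype[:3]}_{treatment}_{rep}",
                     "genotype": genotype, "treatment": treatment, "replicate": rep}
                )
    sample_sheet = pd.DataFrame(sample_rows)

    base = {tid: rng.lognormal(p.baseline_log_mean, p.baseline_log_sd) for tid in all_ids}
    effect = 2.0**p.effect_log2fc

    # Balance the planted up- and down-regulated mass within each genotype by
    # scaling the baselines of the genotype's purely-down features (unchanged
    # in the other genotype, so the two constraints decouple).  Without this
    # the cadmium arm's library would grow by the planted up-mass, and the
    # compositional shift would push every unchanged feature's FPKM fold
    # change toward the down boundary.
    for gi in (0, 1):
        up = [t for t in all_ids if states[t][gi] == UP]
        down = [t for t in all_ids if states[t][gi] == DOWN]
        down_pure = [t for t in down if states[t][1 - gi] == UNCHANGED]
        gain = (effect - 1.0) * sum(base[t] for t in up)
        loss_other = (1.0 - 1.0 / effect) * sum(
            base[t] for t in down if t not in down_pure
        )
        x = (1.0 - 1.0 / effect) * sum(base[t] for t in down_pure)
        if x > 0 and gain > loss_other:
            k = (gain - loss_other) / x
            for t in down_pure:
                base[t] *= k
    counts = np.zeros((len(all_ids), n_samples))
    for fi, tid in enumerate(all_ids):
        st, ss = states[tid]
        prof = profiles[group_of[tid]]
        for si, srow in enumerate(sample_rows):
            state = st if srow["genotype"] == "tolerant" else ss
            mult = 1.0
            if srow["treatment"] == "cd":
                mult = effect if state == UP else (1 / effect if state == DOWN else 1.0)
            mean = base[tid] * mult * prof[si]
            if p.noiseless or p.nb_dispersion <= 0:
                counts[fi, si] = round(mean)
            else:
                shape = 1.0 / p.nb_dispersion
                counts[fi, si] = rng.poisson(rng.gamma(shape, mean / shape))
    counts_df = pd.DataFrame(
        counts, index=pd.Index(all_ids, name="feature_id"),
        columns=[r["sample"] for r in sample_rows],
    )

    # ---- sequences: trans complements and embedded hairpins ----------------
    sequences = {t.transcript_id: _random_seq(rng, t.length) for t in transcripts}
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    for d in trans_pairs:
        ins = _random_seq(rng, p.trans_insert_length, gc=p.trans_insert_gc)
        rc = "".join(comp[c] for c in reversed(ins))
        for tid, seg in ((d["target_id"], ins), (d["lncrna_id"], rc)):
            s = sequences[tid]
            pos = int(rng.integers(0, len(s) - len(seg)))
            sequences[tid] = s[:pos] + seg + s[pos + len(seg) :]

    hairpins = {
        f"mir-{i:03d}": _random_seq(rng, p.hairpin_length) for i in range(p.n_hairpins)
    }
    precursor_pairs = []
    for i, lnc_id in enumerate(prec_lncs):
        hp_id = list(hairpins)[i % p.n_hairpins]
        hp = hairpins[hp_id]
        s = sequences[lnc_id]
        pos = int(rng.integers(0, len(s) - len(hp)))
        sequences[lnc_id] = s[:pos] + hp + s[pos + len(hp) :]
        precursor_pairs.append({"lncrna_id": lnc_id, "mirna_id": hp_id})

    from .pairing import duplex_energy

    energies = pd.DataFrame(
        [
            {
                "lncrna_id": d["lncrna_id"],
                "target_id": d["target_id"],
                "energy": duplex_energy(sequences[d["lncrna_id"]], sequences[d["target_id"]]),
            }
            for d in trans_pairs
        ],
        columns=["lncrna_id", "target_id", "energy"],
    )

    # ---- qPCR table anchored to the planted tolerant-genotype fold change --
    de_novel = [t for t in novel_ids if states[t][0] != UNCHANGED]
    qpcr_genes = de_novel[: p.n_qpcr_genes]
    if len(qpcr_genes) < p.n_qpcr_genes:
        qpcr_genes += [t for t in novel_ids if t not in qpcr_genes][
            : p.n_qpcr_genes - len(qpcr_genes)
        ]
    qpcr_rows = []
    qpcr_lfc = {}
    for gene in qpcr_genes:
        st = states[gene][0]
        lfc = p.effect_log2fc if st == UP else (-p.effect_log2fc if st == DOWN else 0.0)
        qpcr_lfc[gene] = lfc
        for group, expr_log2 in (("control", np.log2(base[gene])),
                                 ("treated", np.log2(base[gene]) + lfc)):
            for rep in range(1, p.replicates + 1):
                noise = 0.0 if p.noiseless else rng.normal(0, p.ct_noise_sd)
                rnoise = 0.0 if p.noiseless else rng.normal(0, p.ct_noise_sd)
                qpcr_rows.append(
                    {"sample": f"{gene}_{group}_{rep}", "group": group, "gene": gene,
                     "target_ct": p.ct_intercept - expr_log2 + noise,
                     "reference_ct": p.ct_reference + rnoise}
                )
    qpcr = pd.DataFrame(qpcr_rows)

    manifest = GroundTruthManifest(
        seed=seed,
        params={
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(p).items()
        },
        classes=classes,
        too_short_ids=short_ids,
        de_states={
            "tolerant": {tid: states[tid][0] for tid in all_ids},
            "sensitive": {tid: states[tid][1] for tid in all_ids},
        },
        tolerance_categories={
            tid: contrast_classify(states[tid][0], states[tid][1]) for tid in all_ids
        },
        cis_pairs=cis_pairs,
        trans_pairs=trans_pairs,
        precursor_pairs=precursor_pairs,
        qpcr_log2fc=qpcr_lfc,
    )
    return Bundle(
        transcripts=transcripts,
        known_ids=known_ids,
        evidence=evidence,
        counts=counts_df,
        sample_sheet=sample_sheet,
        sequences=sequences,
        hairpins=hairpins,
        energies=energies,
        qpcr=qpcr,
        manifest=manifest,
    )


def _write_gtf(transcripts, path: Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tlncscreen\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fixture(bundle: Bundle, out_dir) -> dict[str, Path]:
    """Write the bundle in every module's on-disk format; returns file paths."""
    if not bundle.transcripts:
        raise ValueError("empty bundle")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": out / "annotation.gtf",
        "known_ids": out / "known_ids.txt",
        "evidence": out / "evidence.tsv",
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "transcripts_fasta": out / "transcripts.fasta",
        "hairpins_fasta": out / "hairpins.fasta",
        "energies": out / "energies.tsv",
        "qpcr": out / "qpcr.tsv",
        "manifest": out / "manifest.json",
    }
    _write_gtf(bundle.transcripts, paths["gtf"])
    paths["known_ids"].write_text("".join(f"{k}\n" for k in bundle.known_ids))
    bundle.evidence.to_csv(paths["evidence"], sep="\t", index=False)
    bundle.counts.to_csv(paths["counts"], sep="\t")
    bundle.sample_sheet.to_csv(paths["samples"], sep="\t", index=False)
    _write_fasta(bundle.sequences, paths["transcripts_fasta"])
    _write_fasta(bundle.hairpins, paths["hairpins_fasta"])
    bundle.energies.to_csv(paths["energies"], sep="\t", index=False)
    bundle.qpcr.to_csv(paths["qpcr"], sep="\t", index=False)
    if bundle.manifest is not None:
        paths["manifest"].write_text(bundle.manifest.to_json())
    else:
        del paths["manifest"]
    return paths
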