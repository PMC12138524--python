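# Methods

## Scope and design

`lncscreen` implements the decision layer of a comparative lncRNA screen:
everything downstream of transcript assembly and per-tool coding-potential
scoring. Upstream artifacts (read QC, alignment, assembly, the internal
models of the coding-potential tools, database annotation) are inputs, not
computations. The design under study is two genotypes (one stress-tolerant,
one stress-sensitive) × two treatments (control, cadmium) × three
biological replicates.

## Coordinates and locus geometry

All coordinates are 1-based closed intervals (GTF convention); a single
exon 100–300 is 201 nt. Distances between loci are nearest span-to-span
gaps in bp over gene boundaries (not exon boundaries): adjacent intervals
have gap 0 without overlapping. Upstream/downstream orientation is taken
relative to the lncRNA locus and its strand. Unstranded records are
rejected at parse time because the subtype logic requires strand.

The six overlap subtypes are assigned by a fixed precedence: any
exon–exon intersection ⇒ Sense/AntiSense; else lncRNA span strictly inside
one intron of the gene ⇒ Intronic/AntiIntronic; else mere span overlap ⇒
Overlapping/AntiOverlapping; strand agreement selects the non-Anti form.
Non-overlapping pairs within the 10 kb window are Upstream/Downstream.
These definitions are declared, not inferred from data: published surveys
name the subtypes without defining them, so the precedence above is the
package's operative definition, chosen so the eight labels partition all
cis pairs (an exhaustively enumerated test).

## Consensus classification

Five binary verdicts per candidate: three scores vote coding iff > 0 (a
score of exactly 0 votes noncoding by default; configurable) and the two
protein-database flags vote coding when set. The asymmetric rule — mRNA
needs ≥ 3 coding votes *and* ≥ 1 database hit, lncRNA needs ≥ 3 noncoding
votes — makes an "ambiguous" class possible (e.g. 3 coding score votes
with no database support); ambiguous transcripts are excluded from both
downstream sets and reported separately. The rule is monotone: adding
coding evidence never demotes an mRNA call.

## Expression, DE test and states

FPKM uses per-sample column sums of raw counts as library sizes. The fold
change is computed on arm means of FPKM with a pseudocount of 1 applied
*only* when a mean is zero, so exact ratios between nonzero means are
preserved. Significance comes from a two-sided binomial test on pooled
counts (the feature's summed counts in the treated arm against the two
arms' summed library sizes as the null proportion) — a deliberate,
pluggable stand-in in the spirit of MA-plot random-sampling DE methods for
designs quantified at the FPKM level; it is not a replicate-aware
negative-binomial model and will be anti-conservative when biological
replicate variance is large. BH-FDR is applied per genotype.

States use the fold-change-only three-state rule by default (up iff
log₂FC ≥ 1, down iff ≤ −1, else unchanged, with 0 counted as unchanged);
an optional FDR gate (≤ 0.05) demotes non-significant up/down calls to
unchanged. The screen's published tallies use the fold-change-only rule;
DE lists for downstream filtering can enable the gate.

## Target pairing

The correlation gate computes Pearson and Spearman on log₂(FPKM+1) across
all 12 samples and requires both to strictly exceed 0.6, read as a signed
inequality; an absolute-value mode exists because negative regulation is
biologically plausible. The gate applies to cis and trans candidates
alike. Constant expression vectors fail the gate with an explicit reason
rather than propagating an undefined correlation.

Cis assignment is inclusive at the 10 kb boundary (gap = 10 000 is cis;
10 001 is evaluated as a trans candidate). A pair is never both cis and
trans: cis takes precedence.

The hybridisation-energy backend is pluggable: a precomputed energy table
(e.g. from a dedicated RNA–RNA interaction tool), or the built-in
stand-in. The stand-in slides the two sequences against each other in
antisense orientation (every ungapped offset), finds Watson–Crick
complementary runs of ≥ 4 bp and scores each run by the Turner 2004
nearest-neighbor stack free energies (37 °C), returning the most stable
single run. Scoring one contiguous helix — rather than summing all runs at
an offset — keeps the statistic length-stable: a sum over runs grows
roughly linearly with sequence length for random sequences and would make
any fixed threshold meaningless, whereas the best single helix of two
random ~1 kb sequences stays far above −60 kcal/mol. The stand-in has no
loop penalties, no GU wobble and no intramolecular structure; it is a
monotone proxy, not a replacement for a thermodynamic interaction
predictor, and no equivalence is claimed.

The trans candidate universe is lncRNA × differentially expressed mRNA
pairs passing the correlation gate (quadratic; a configurable cap guards
desk-scale runs).

## Tolerance screen

The cross-genotype contrast maps the 3 × 3 state grid to four categories:
`T_up` (up in tolerant, down/unchanged in sensitive), `T_down` (mirror),
`S_only` (unchanged in tolerant, up/down in sensitive), `not_linked` (the
three concordant cells). Key pairs retain pairs whose lncRNA is
tolerance-linked *and* whose target's state differs between genotypes —
the operative selection rule, which reproduces the published 18-pair
worked example from its own printed fold changes. Features present in only
one genotype's DE table are counted as unchanged in the other and logged.

One published tally ("12 unchanged in the tolerant genotype" for the 16
remaining targets) is inconsistent with the printed fold changes under the
stated rule, which yields 13; the package asserts only the internally
consistent counts (3 up in tolerant; 8/5/3 in sensitive).

## qPCR and enrichment

ΔCt = target Ct − reference Ct; ΔΔCt anchors to the *control-group mean*
(not a single calibrator), so the control group's mean ΔΔCt is 0 by
construction; relative expression is 2^−ΔΔCt. Concordance with sequencing
is the R² of an OLS fit of sequencing log₂FC on qPCR log₂FC. Enrichment is
a generic hypergeometric upper-tail test against a user-supplied term map
with BH-adjusted q-values; term assignment itself is out of scope.

## Precursor scan

Each hairpin is locally aligned (Smith–Waterman scoring +1/−2/−3 via
Biopython's PairwiseAligner) against each lncRNA on both strands; a hit
requires identity ≥ 0.9 over the aligned columns (gap columns count
against identity) and hairpin coverage ≥ 0.9. These parameters are
declared defaults — the published scan reported only "BLAST against
miRBase" — so absolute hit counts are not comparable across parameter
choices, only the monotone behaviour (raising either threshold never adds
hits) is guaranteed.

## Synthetic data generator

The generator emits a complete desk-scale bundle — GTF, evidence table,
counts, transcript and hairpin FASTA, energy table, qPCR Ct table — plus a
manifest of every planted truth. Defaults (the study conditions of the
test suite): 300 transcripts (40 known mRNA, 80 novel mRNA, 170 lncRNA, 10
sub-200 nt), 12 samples, planted |log₂FC| = 3, NB dispersion 0.1, baseline
count means log-normal(μ=5, σ=1), coding scores N(±2, 0.5), database-hit
flags Bernoulli conditioned on class, 3 planted cis pairs per positional
subtype, 12 trans pairs (48 nt GC-rich antisense-complementary inserts,
energies ≈ −120 kcal/mol), 4 embedded hairpins, 10 qPCR genes with
Ct = 25 − log₂(expression) + N(0, 0.15) against a flat reference gene.

Three structural choices matter:

* **Compositional balance.** Planting a substantial DE fraction at 8-fold
  would inflate the treated arm's library size and shift every unchanged
  feature's FPKM fold change toward the down boundary (relative-abundance
  closure). The generator therefore rescales the baselines of each
  genotype's purely-down features so planted up- and down-mass cancel;
  library sizes then stay within 2× across samples (a tested invariant)
  and "unchanged" means what it says in FPKM space.
* **Arm-centred co-expression profiles.** Members of a planted pair share
  a per-sample log-normal expression profile (σ = 0.6) renormalised to
  mean 1 within each genotype × treatment arm: it creates the within-arm
  covariation the correlation gate needs without perturbing arm means, and
  hence without corrupting planted fold changes.
* **Trans pairs are planted differentially expressed**, because the
  screen's trans candidate universe is DE mRNAs; a non-DE trans pair would
  be undetectable by construction.

In noiseless mode every stochastic layer collapses to its mean (counts =
rounded means, scores exactly ±2, deterministic flags, noise-free Ct), the
limit in which the pipeline recovers 100 % of planted classes, cis and
trans pairs, states and precursor hits. What the generator does *not*
emulate: read-level artifacts, positional coverage bias, batch effects,
correlated gene programs beyond pairs, and realistic DE effect-size
distributions — passing recovery tests therefore validates the decision
logic, not performance on real libraries.

## Problem sizes and numerics

Tests and the acceptance script run the default 300-feature bundle (one
noiseless, one at default noise), chosen so a full end-to-end run takes
tens of seconds on one CPU. Recovery at default noise is ~97–99 % for DE
states and ~95–98 % for tolerance categories across seeds (the residual
errors are unchanged features whose estimated |log₂FC| crosses 1, and
near-boundary category flips); thresholds in the tests are ≥ 90 %.
Tie-breaks and degenerate inputs are explicit throughout: score 0 votes
noncoding, log₂FC exactly ±1 is up/down, gap exactly 10 kb is cis,
constant vectors fail gates with reasons, empty inputs yield empty outputs
or named errors.

## Known limitations

The DE test ignores replicate-level biological variance; the energy
stand-in ignores loop entropies and wobble pairs; the correlation gate at
n = 12 has limited discrimination, so weakly co-varying true pairs are
missed (noisy cis recovery is ~70–95 % depending on seed) and co-DE false
positives reach the energy gate, where nearly all are rejected; survey
absolute counts (e.g. genome-wide lncRNA totals) require the original raw
libraries and are outside what synthetic bundles can reproduce.
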