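"""Correlation gating, the nearest-neighbor duplex stand-in, pair assignment."""

import numpy as np
import pandas as pd
import pytest

from lncscreen.annotation import TranscriptModel
from lncscreen.expression import ExpressionMatrix, SampleInfo
from lncscreen.pairing import (
    NN_STACK,
    _COMPLEMENT,
    assign_targets,
    cis_partition,
    correlation_gate,
    duplex_energy,
)

# a fixed 40-mer whose reverse complement forms one full 39-stack helix
HELIX_40 = "UCACCUCACGUGUAUAGCAGCGCAGCGGUCAGUUUGCCAA"


def revcomp(s):
    return "".join(_COMPLEMENT[c] for c in s[::-1])


class TestCorrelationGate:
    def test_identity_passes(self):
        x = [1.0, 5.0, 2.0, 9.0]
        res = correlation_gate(x, x)
        assert res.passed and res.pearson == pytest.approx(1.0)
        assert res.spearman == pytest.approx(1.0)

    def test_perfect_anticorrelation_fails_signed_gate(self):
        res = correlation_gate([1, 2, 3, 4], [4, 3, 2, 1], log_transform=False)
        assert res.pearson == pytest.approx(-1.0)
        assert not res.passed
        # the absolute-value mode admits negative regulation
        assert correlation_gate([1, 2, 3, 4], [4, 3, 2, 1], absolute=True,
                                log_transform=False).passed

    def test_hand_computed_moment_and_rank_coefficients(self):
        # frozen from the closed-form moment/rank sums
        res = correlation_gate(
            [1, 2, 3, 4, 100], [1, 2, 3, 4, -100], log_transform=False
        )
        assert res.pearson == pytest.approx(-0.9987492197274769)
        assert res.spearman == pytest.approx(0.0)
        assert not res.passed

    def test_constant_vector_fails_with_reason(self):
        res = correlation_gate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.passed and res.reason == "constant_vector"


class TestDuplexEnergy:
    def test_reverse_complement_is_full_helix(self):
        manual = sum(NN_STACK[HELIX_40[k : k + 2]] for k in range(39))
        assert duplex_energy(HELIX_40, revcomp(HELIX_40)) == pytest.approx(manual)
        assert manual < -60

    def test_no_complementarity_is_zero(self):
        assert duplex_energy("A" * 20, "A" * 20) == 0.0

    def test_symmetric(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = "".join(rng.choice(list("ACGU"), 30))
            b = "".join(rng.choice(list("ACGU"), 45))
            assert duplex_energy(a, b) == pytest.approx(duplex_energy(b, a))

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError, match="invalid RNA"):
            duplex_energy("ACGUACGUXX", "ACGUACGUAC")

    def test_agrees_with_bruteforce_run_scan(self):
        # oracle: enumerate every antisense offset, find complementary runs,
        # score each run by its stacks, take the best single run
        def brute(a, b, min_run=4):
            a = a.upper().replace("T", "U")
            br = revcomp(b.upper().replace("T", "U"))
            best = 0.0
            for off in range(-(len(br) - 1), len(a)):
                lo, hi = max(0, off), min(len(a), off + len(br))
                start = None
                for i in range(lo, hi + 1):
                    match = i < hi and a[i] == br[i - off]
                    if match and start is None:
                        start = i
                    elif not match and start is not None:
                        if i - start >= min_run:
                            e = sum(NN_STACK[a[k : k + 2]] for k in range(start, i - 1))
                            best = min(best, e)
                        start = None
            return best

        rng = np.random.default_rng(11)
        for _ in range(30):
            a = "".join(rng.choice(list("ACGU"), rng.integers(12, 60)))
            b = "".join(rng.choice(list("ACGU"), rng.integers(12, 60)))
            assert duplex_energy(a, b) == pytest.approx(brute(a, b))


def _expr(features, n=6):
    rng = np.random.default_rng(0)
    shared = rng.lognormal(0, 1, size=n)
    vals = {f: shared * (i + 1) for i, f in enumerate(features)}
    samples = [
        SampleInfo(f"s{i}", "tolerant", "control" if i < n // 2 else "cd", i)
        for i in range(n)
    ]
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=[s.sample for s in samples]).T,
        samples=samples,
        kind="fpkm",
    )


def _tr(tid, chrom, start, length, strand="+"):
    return TranscriptModel(tid, f"G_{tid}", chrom, strand, ((start, start + length - 1),))


class TestAssignTargets:
    def test_cis_window_boundary_inclusive(self):
        lnc = _tr("l", "chr1", 1000, 500)
        near = _tr("g1", "chr1", 1500 + 10_000, 500)  # gap exactly 10 000
        far = _tr("g2", "chr1", 1501 + 10_000, 500)  # gap 10 001
        expr = _expr(["l", "g1", "g2"])
        pairs, _ = assign_targets([lnc], [near, far], expr, energy_table={})
        modes = {p.target_id: p.mode for p in pairs}
        assert modes == {"g1": "cis"}  # far pair lacks energy -> skipped

    def test_trans_requires_energy_at_most_threshold(self):
        lnc = _tr("l", "chr1", 1000, 500)
        g1 = _tr("g1", "chr2", 1000, 500)
        g2 = _tr("g2", "chr2", 9000, 500)
        expr = _expr(["l", "g1", "g2"])
        pairs, _ = assign_targets(
            [lnc], [g1, g2], expr,
            energy_table={("l", "g1"): -65.0, ("l", "g2"): -30.0},
        )
        assert [(p.target_id, p.mode) for p in pairs] == [("g1", "trans")]
        assert pairs[0].energy_kcal_mol == -65.0

    def test_missing_energy_logged_and_skipped(self):
        lnc = _tr("l", "chr1", 1000, 500)
        g = _tr("g", "chr2", 1000, 500)
        pairs, skipped = assign_targets([lnc], [g], _expr(["l", "g"]), energy_table={})
        assert pairs == []
        assert ("l", "g", "no_energy") in skipped

    def test_mode_partition_and_cis_precedence(self):
        lnc = _tr("l", "chr1", 1000, 500)
        overlapping = _tr("g", "chr1", 1200, 500)
        expr = _expr(["l", "g"])
        # even with a qualifying energy available, an overlapping pair is cis
        pairs, _ = assign_targets([lnc], [overlapping], expr,
                                  energy_table={("l", "g"): -99.0})
        (p,) = pairs
        assert p.mode == "cis" and p.gap_bp == 0

    def test_monotone_in_thresholds(self):
        lnc = _tr("l", "chr1", 1000, 500)
        genes = [_tr(f"g{i}", "chr2", 1000 * (i + 1), 500) for i in range(4)]
        expr = _expr(["l"] + [g.transcript_id for g in genes])
        table = {("l", f"g{i}"): -40.0 - 10 * i for i in range(4)}
        base = len(assign_targets([lnc], genes, expr, energy_table=table)[0])
        stricter_energy = len(
            assign_targets([lnc], genes, expr, energy_table=table, energy_max=-75)[0]
        )
        stricter_corr = len(
            assign_targets([lnc], genes, expr, energy_table=table, corr_min=1.01)[0]
        )
        assert stricter_energy <= base
        assert stricter_corr == 0

    def test_cis_partition_sums(self):
        lnc = _tr("l", "chr1", 1000, 500)
        near = _tr("g1", "chr1", 3000, 500)
        overlapping = _tr("g2", "chr1", 1100, 200)
        expr = _expr(["l", "g1", "g2"])
        pairs, _ = assign_targets([lnc], [near, overlapping], expr, energy_table={})
        part = cis_partition(pairs)
        assert part["cis_total"] == 2
        assert part["Upstream"] + part["Downstream"] + part["overlap"] == part["cis_total"]
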