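import math
from decimal import Decimal, getcontext

import numpy as np
import pytest

from taumark.distances import (
    compare_pair,
    concatenate,
    core_ani_matrix,
    jc69,
    k80,
    locus_matrix,
)
from taumark.seqio import Alignment

getcontext().prec = 50


def jc69_decimal(p: float) -> float:
    """Independent high-precision JC69 evaluation via decimal ln."""
    arg = Decimal(1) - Decimal(4) / Decimal(3) * Decimal(p)
    return float(-(Decimal(3) / Decimal(4)) * arg.ln())


def k80_decimal(P: float, Q: float) -> float:
    a1 = Decimal(1) - 2 * Decimal(P) - Decimal(Q)
    a2 = Decimal(1) - 2 * Decimal(Q)
    return float(-(a1.ln()) / 2 - (a2.ln()) / 4)


class TestComparePair:
    @pytest.mark.parametrize(
        "a,b,p,n,P,Q",
        [
            ("ACGT", "ACGA", 0.25, 4, 0.0, 0.25),  # T<->A is a transversion
            ("AC-T", "ACGT", 0.0, 3, 0.0, 0.0),    # gap column excluded
            ("ACGT", "ACGT", 0.0, 4, 0.0, 0.0),
            ("AG", "GA", 1.0, 2, 1.0, 0.0),        # both A<->G transitions
            ("ACNT", "ACGT", 0.0, 3, 0.0, 0.0),    # ambiguity excluded
        ],
    )
    def test_counts(self, a, b, p, n, P, Q):
        c = compare_pair(a, b)
        assert (c.p, c.n_sites, c.P, c.Q) == (p, n, P, Q)

    def test_no_shared_sites(self):
        c = compare_pair("--AC", "AC--")
        assert c.n_sites == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_pair("ACG", "AC")


class TestModelFormulas:
    def test_jc69_zero(self):
        assert jc69(0.0) == 0.0

    def test_jc69_saturation_masked(self):
        assert math.isnan(jc69(0.75))
        assert math.isnan(jc69(0.9))

    def test_jc69_domain_check(self):
        with pytest.raises(ValueError):
            jc69(-0.1)
        with pytest.raises(ValueError):
            jc69(1.1)

    def test_jc69_closed_form(self):
        assert jc69(0.3) == pytest.approx(-0.75 * math.log(0.6), abs=1e-15)
        rng = np.random.default_rng(0)
        for p in rng.uniform(0, 0.74, size=50):
            assert jc69(p) == pytest.approx(jc69_decimal(p), abs=1e-12)

    def test_jc69_inflates(self):
        for p in np.linspace(0.01, 0.7, 30):
            assert jc69(p) >= p

    def test_k80_zero(self):
        assert k80(0.0, 0.0) == 0.0

    def test_k80_saturation_masked(self):
        assert math.isnan(k80(0.5, 0.1))   # 1-2P-Q <= 0
        assert math.isnan(k80(0.0, 0.5))   # 1-2Q <= 0

    def test_k80_domain_check(self):
        with pytest.raises(ValueError):
            k80(-0.1, 0.0)
        with pytest.raises(ValueError):
            k80(0.7, 0.4)

    def test_k80_closed_form(self):
        assert k80(0.1, 0.05) == pytest.approx(k80_decimal(0.1, 0.05), abs=1e-12)
        rng = np.random.default_rng(1)
        for _ in range(50):
            P, Q = rng.uniform(0, 0.2, size=2)
            assert k80(P, Q) == pytest.approx(k80_decimal(P, Q), abs=1e-12)

    def test_k80_at_least_p(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            P, Q = rng.uniform(0, 0.15, size=2)
            assert k80(P, Q) >= P + Q - 1e-12


class TestLocusMatrix:
    def test_identical_sequences_zero_under_all_models(self):
        aln = Alignment("x", ["A", "B"], ["ACGTACGT", "ACGTACGT"])
        for model in ("identity", "jc69", "k80"):
            dm = locus_matrix(aln, model=model)
            assert dm.get("A", "B") == 0.0

    def test_matches_per_pair_oracle(self):
        rng = np.random.default_rng(3)
        taxa = [f"G{i}" for i in range(3)]
        seqs = ["".join(rng.choice(list("ACGT-"), size=60)) for _ in taxa]
        aln = Alignment("x", taxa, seqs)
        for model, f in (("jc69", lambda c: jc69(c.p)),
                         ("k80", lambda c: k80(c.P, c.Q)),
                         ("identity", lambda c: c.p)):
            dm = locus_matrix(aln, model=model)
            for i in range(3):
                for j in range(i + 1, 3):
                    c = compare_pair(seqs[i], seqs[j])
                    assert dm.get(taxa[i], taxa[j]) == pytest.approx(
                        f(c), abs=1e-12, nan_ok=True)

    def test_no_shared_sites_masked(self):
        aln = Alignment("x", ["A", "B", "C"], ["AC--", "--GT", "ACGT"])
        dm = locus_matrix(aln, min_sites=1)
        assert dm.is_masked("A", "B")
        assert not dm.is_masked("A", "C")

    def test_min_sites_masking(self):
        aln = Alignment("x", ["A", "B"], ["AC--", "ACGT"])
        assert locus_matrix(aln, min_sites=3).is_masked("A", "B")
        assert not locus_matrix(aln, min_sites=2).is_masked("A", "B")

    def test_saturated_pair_masked_or_capped(self):
        # maximally divergent pair: p = 1 >= 3/4
        aln = Alignment("x", ["A", "B", "C"], ["AAAA", "CCCC", "AAAA"])
        dm = locus_matrix(aln, model="jc69")
        assert dm.is_masked("A", "B")
        capped = locus_matrix(aln, model="jc69", saturation_cap=5.0)
        assert capped.get("A", "B") == 5.0

    def test_labels_sorted(self):
        aln = Alignment("x", ["B", "A"], ["ACGT", "ACGA"])
        assert locus_matrix(aln).labels == ["A", "B"]


class TestCoreAni:
    def test_hand_weighted_mean(self):
        # (p=0.10, n=100) and (p=0.00, n=100) -> identity 0.95, distance 0.05
        a = Alignment("l1", ["A", "B"], ["A" * 100, "C" * 10 + "A" * 90])
        b = Alignment("l2", ["A", "B"], ["G" * 100, "G" * 100])
        dm = core_ani_matrix([a, b])
        assert dm.get("A", "B") == pytest.approx(0.05, abs=1e-12)
        assert dm.meta == "core_ani"

    def test_identical_loci_distance_zero(self):
        a = Alignment("l1", ["A", "B"], ["ACGT", "ACGT"])
        assert core_ani_matrix([a]).get("A", "B") == 0.0

    def test_absent_pair_masked(self):
        a = Alignment("l1", ["A", "B"], ["ACGT", "ACGA"])
        b = Alignment("l2", ["C", "D"], ["ACGT", "ACGA"])
        dm = core_ani_matrix([a, b])
        assert dm.is_masked("A", "C")
        assert not dm.is_masked("A", "B")

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            core_ani_matrix([])

    def test_equals_identity_of_concatenation_when_complete(self):
        rng = np.random.default_rng(4)
        taxa = [f"G{i}" for i in range(5)]
        loci = [
            Alignment(f"l{k}", taxa,
                      ["".join(rng.choice(list("ACGT"), size=40)) for _ in taxa])
            for k in range(4)
        ]
        ani = core_ani_matrix(loci)
        ident = locus_matrix(concatenate(loci, "cat"), model="identity")
        assert np.allclose(ani.values, ident.values, atol=1e-12)


class TestConcatenate:
    def test_lengths_add(self, toy_loci):
        cat = concatenate(toy_loci[:2], "cat")
        assert cat.length == 16

    def test_single_locus_identity(self, toy_loci):
        cat = concatenate([toy_loci[0]], "new")
        assert cat.locus_id == "new"
        assert cat.seqs == toy_loci[0].seqs

    def test_missing_taxon_gap_filled(self, toy_loci):
        cat = concatenate(toy_loci, "cat")  # locusC lacks G4
        assert cat.row("G4").endswith("-" * 8)
        assert cat.length == 24

    def test_identity_on_concat_is_weighted_mean_of_p(self):
        # with equal per-pair n_sites the concatenated p is the
        # length-weighted mean of per-locus p
        rng = np.random.default_rng(5)
        taxa = ["A", "B"]
        loci = [
            Alignment(f"l{k}", taxa,
                      ["".join(rng.choice(list("ACGT"), size=ln)) for _ in taxa])
            for k, ln in enumerate([30, 70])
        ]
        ps = [compare_pair(a.seqs[0], a.seqs[1]).p for a in loci]
        expected = (30 * ps[0] + 70 * ps[1]) / 100
        cat = locus_matrix(concatenate(loci, "cat"), model="identity")
        assert cat.get("A", "B") == pytest.approx(expected, abs=1e-12)
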