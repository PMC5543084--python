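"""Binding-site search, in-silico PCR, coverage and specificity."""

import numpy as np
import pytest

from comaprime.insilico import (
    ReferenceDatabase,
    SeqRec,
    coverage,
    find_sites,
    insilico_pcr,
    site_eligibility,
    specificity,
)
from comaprime.iupac import IupacPattern, expand, pattern_mismatches, revcomp
from comaprime.primers import PrimerSet


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def _revcomp_str(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestFindSites:
    def test_exact_site_single_hit(self, clade_a_mix):
        rng = np.random.default_rng(11)
        oligo = clade_a_mix.forward[0]  # comaA-244f_a, concrete
        for _ in range(20):
            tpl = _rand_seq(rng, 150) + oligo.bases + _rand_seq(rng, 150)
            hits = find_sites(tpl, [oligo], "sense", 0)
            if len(hits) == 1:
                assert hits[0].start == 150 and hits[0].mismatches == 0
                return
        pytest.fail("no clean fixture found")

    def test_mutated_site_counts_one_mismatch(self, clade_a_mix):
        oligo = clade_a_mix.forward[0]
        tpl = "C" * 50 + oligo.bases + "C" * 50
        mutated = tpl[:50] + "G" + tpl[51:]  # first site base T -> G
        hits = find_sites(mutated, [oligo], "sense", 2)
        best = min(hits, key=lambda h: h.mismatches)
        assert best.start == 50 and best.mismatches == 1

    def test_degenerate_scan_equals_union_of_variant_scans(self, clade_a_pair):
        rng = np.random.default_rng(5)
        primer = clade_a_pair.forward[0]
        tpl = _rand_seq(rng, 400)
        got = {(h.start, h.mismatches) for h in find_sites(tpl, [primer], "sense", 2)}
        union = {}
        for v in expand(primer):
            for h in find_sites(tpl, [IupacPattern(v)], "sense", 2):
                union[h.start] = min(union.get(h.start, 99), h.mismatches)
        assert got == set(union.items())

    def test_template_shorter_than_primer_is_empty(self, clade_a_pair):
        assert find_sites("ACGT", clade_a_pair.forward, "sense", 3) == []


class TestEligibility:
    def test_gap_in_forward_window(self, clade_a_pair, default_template):
        seq = default_template.seq
        gapped = seq[:250] + "-" + seq[251:]  # inside the forward footprint
        e = site_eligibility(SeqRec("x", gapped), clade_a_pair)
        assert not e.eligible and e.reason == "gap"

    def test_fully_concrete_record(self, clade_a_pair, default_template):
        e = site_eligibility(SeqRec("x", default_template.seq), clade_a_pair)
        assert e.eligible
        assert e.forward[0] == 0 and e.reverse[0] == 0

    def test_truncated_before_reverse_window(self, clade_a_pair, default_template):
        e = site_eligibility(
            SeqRec("x", default_template.seq[:300]), clade_a_pair
        )
        assert not e.eligible and e.reason == "truncated"


class TestInsilicoPcr:
    def test_default_template_yields_415(self, clade_a_pair, clade_a_mix,
                                         default_template):
        for ps in (clade_a_pair, clade_a_mix):
            prods = insilico_pcr(default_template.seq, ps)
            assert len(prods) == 1
            assert prods[0].length == 415

    def test_no_reverse_site_no_product(self, clade_a_pair):
        from comaprime.simulate import TemplateSpec, gen_template
        rec = gen_template(TemplateSpec(include_reverse=False, seed=2))
        assert insilico_pcr(rec.seq, clade_a_pair) == []

    def test_two_forward_sites_nested_products(self, clade_a_pair):
        from comaprime.simulate import TemplateSpec, gen_template
        rec = gen_template(TemplateSpec(extra_forward_coords=(150,), seed=3))
        prods = insilico_pcr(rec.seq, clade_a_pair)
        assert len(prods) == 2
        lens = sorted(p.length for p in prods)
        assert lens == [415, 415 + (244 - 150)]
        # nested: the longer product contains the shorter one
        a, b = sorted(prods, key=lambda p: p.start)
        assert a.start < b.start and a.end == b.end

    def test_strand_symmetry_random_fixtures(self, clade_a_pair):
        rng = np.random.default_rng(0)
        for _ in range(60):
            tpl = _rand_seq(rng, 300)
            fwd = sorted(
                (a.start, a.end)
                for a in insilico_pcr(tpl, clade_a_pair, 3, 50, 300)
            )
            rc = _revcomp_str(tpl)
            mapped = sorted(
                (300 - a.end, 300 - a.start)
                for a in insilico_pcr(rc, clade_a_pair, 3, 50, 300)
            )
            assert fwd == mapped

    def test_hits_monotone_in_max_mismatches(self, clade_a_pair, default_template):
        tpl = default_template.seq
        prev = -1
        for mm in range(4):
            n = len(find_sites(tpl, clade_a_pair.forward, "sense", mm))
            assert n >= prev
            prev = n

    def test_bad_length_bounds_rejected(self, clade_a_pair):
        with pytest.raises(ValueError, match="min_len"):
            insilico_pcr("ACGT" * 100, clade_a_pair, min_len=500, max_len=100)


def _planted_db(seed=3):
    from comaprime.simulate import DbSpec, GroupSpec, gen_reference_db
    spec = DbSpec(
        {
            "comammox clade A": GroupSpec(8, 0, 0, gap_rate=0.0),
            "betaproteobacterial amoA": GroupSpec(12, (2, 3, 4), (3, 4, 5)),
        },
        seed=seed,
    )
    return gen_reference_db(spec)


class TestCoverage:
    def test_constructed_counts(self, clade_a_pair, default_template):
        """4 records: 1 gapped at the forward window, 2 of 3 perfect -> 2/3."""
        good = default_template.seq
        gapped = good[:250] + "-" + good[251:]
        mutated = good[:250] + {"A": "C", "C": "A", "G": "A", "T": "G"}[good[250]] + good[251:]
        db = ReferenceDatabase(
            [
                SeqRec("g1", good, "clade"),
                SeqRec("g2", good, "clade"),
                SeqRec("bad", mutated, "clade"),
                SeqRec("gap", gapped, "clade"),
            ]
        )
        rep = coverage(db, clade_a_pair, "clade").for_group("clade")
        assert (rep.eligible, rep.matched) == (3, 2)
        assert rep.percent_display == 67

    def test_mix_coverage_le_degenerate(self, clade_a_pair, clade_a_mix):
        """Clade-A mix members lie in the expansion: mix can never beat it."""
        db, _ = _planted_db(9)
        for g in db.groups:
            deg = coverage(db, clade_a_pair, g).for_group(g)
            mix = coverage(db, clade_a_mix, g).for_group(g)
            assert mix.matched <= deg.matched

    def test_empty_group_flagged(self, clade_a_pair):
        db = ReferenceDatabase([SeqRec("a", "ACGT" * 20, "clade")])
        rep = coverage(db, clade_a_pair, "clade").for_group("clade")
        assert rep.eligible == 0 and rep.percent is None

    def test_zero_planted_mismatches_full_coverage(self, clade_a_pair):
        from comaprime.simulate import DbSpec, GroupSpec, gen_reference_db
        db, _ = gen_reference_db(
            DbSpec({"comammox clade A": GroupSpec(10)}, seed=1)
        )
        rep = coverage(db, clade_a_pair, "comammox clade A")
        g = rep.for_group("comammox clade A")
        assert (g.eligible, g.matched, g.percent_display) == (10, 10, 100)


class TestSpecificity:
    def test_constructed_rule_application(self, clade_a_pair):
        from comaprime.simulate import DbSpec, GroupSpec, gen_reference_db
        db, _ = gen_reference_db(
            DbSpec(
                {"off": GroupSpec(2, (2, 0), (2, 5))}, seed=4
            ),
        )
        rep = specificity(db, clade_a_pair, ["off"]).for_group("off")
        # seq 1: 2 vs 2 -> bin 2; seq 2: 0 forward but 5 reverse -> bin 5
        assert rep.histogram == {2: 1, 5: 1}

    def test_planted_histogram_reproduced(self, clade_a_pair):
        db, truth = _planted_db()
        rep = specificity(db, clade_a_pair, ["betaproteobacterial amoA"])
        g = rep.for_group("betaproteobacterial amoA")
        t = truth[truth.group == "betaproteobacterial amoA"]
        want = (
            t[["forward_mismatches", "reverse_mismatches"]]
            .astype(int)
            .max(axis=1)
            .value_counts()
            .to_dict()
        )
        assert g.histogram == want
        assert sum(g.histogram.values()) == g.eligible

    def test_cross_clade_pattern_distance(self, clade_a_pair, clade_b_pair):
        fwd = pattern_mismatches(
            clade_a_pair.forward[0], clade_b_pair.forward[0]
        )
        rev = pattern_mismatches(
            clade_a_pair.reverse[0], clade_b_pair.reverse[0]
        )
        assert (fwd, rev) == (6, 5)


class TestDatabase:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ReferenceDatabase([SeqRec("a", "ACGT"), SeqRec("a", "ACGT")])

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            ReferenceDatabase(
                [SeqRec("a", "ACGT-"), SeqRec("b", "ACG")], aligned=True
            )
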