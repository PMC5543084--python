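"""Primer catalog, binding windows, equimolar mixture design and Tm."""

import itertools

import numpy as np
import pytest

from comaprime.iupac import IupacPattern, expand, pattern_mismatches
from comaprime.primers import (
    ThermoParams,
    builtin_catalog,
    candidate_windows,
    design_equimolar_mix,
    melt_temp,
    read_primer_tsv,
    write_primer_tsv,
    _candidate_patterns,
)


class TestCatalog:
    def test_four_sets_with_table_values(self, catalog):
        assert [ps.set_name for ps in catalog] == [
            "comaA degenerate", "comaB degenerate",
            "comaA equimolar mix", "comaB equimolar mix",
        ]
        assert all(ps.expected_amplicon_length == 415 for ps in catalog)
        a_deg = catalog[0]
        assert a_deg.forward[0].name == "comaA-244F"
        assert a_deg.forward[0].bases == "TAYAAYTGGGTSAAYTA"
        assert a_deg.reverse[0].bases == "ARATCATSGTGCTRTG"
        b_mix = catalog[3]
        assert len(b_mix.forward) == 6 and len(b_mix.reverse) == 6
        assert b_mix.forward[0].bases == "TAYTTCTGGACGTTCTA"

    def test_equimolar_members_at_most_one_ambiguity(self, catalog):
        for ps in catalog[2:]:
            for m in ps.forward + ps.reverse:
                assert len(m.degenerate_positions) <= 1

    def test_tsv_round_trip_byte_identical(self, catalog, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_primer_tsv(p1, catalog)
        write_primer_tsv(p2, read_primer_tsv(p1))
        assert p1.read_bytes() == p2.read_bytes()


class TestCandidateWindows:
    def _alignment(self, covered_rows, total=10, width=17, pad=5):
        """Rows concrete over the window; the rest gapped inside it."""
        mid = width // 2
        rows = []
        for i in range(total):
            core = (
                "A" * width
                if i < covered_rows
                else "A" * mid + "-" + "A" * (width - mid - 1)
            )
            rows.append("C" * pad + core + "C" * pad)
        return rows

    def test_inclusion_threshold(self):
        aln = self._alignment(9)
        ws = candidate_windows(aln, 17, 0.8)
        assert any(w.start_column == 5 and w.nongap_fraction == 0.9 for w in ws)
        aln = self._alignment(7)
        ws = candidate_windows(aln, 17, 0.8)
        assert not any(w.start_column == 5 for w in ws)

    def test_zero_threshold_returns_every_window(self):
        aln = self._alignment(3, total=4, width=6, pad=2)
        ws = candidate_windows(aln, 6, 0.0)
        assert len(ws) == len(aln[0]) - 6 + 1
        assert [w.start_column for w in ws] == sorted(w.start_column for w in ws)

    def test_width_longer_than_alignment_rejected(self):
        with pytest.raises(ValueError, match="width"):
            candidate_windows(["ACGT"], 5, 0.8)


class TestEquimolarDesign:
    def test_weighted_cover_example(self):
        d = design_equimolar_mix({"AAA": 5, "AAT": 3, "ATA": 1}, 2, 1)
        assert d.covered_observations == d.total_observations == 9
        assert len(d.oligos) <= 2
        observed = {"AAA", "AAT", "ATA"}
        for o in d.oligos:
            assert len(o.degenerate_positions) <= 1
            assert expand(o) <= observed  # no phantom variants

    def test_single_variant_identity(self):
        d = design_equimolar_mix({"ACGT": 1}, 1, 1)
        assert [o.bases for o in d.oligos] == ["ACGT"]
        assert d.coverage == 1.0

    def test_frequency_preference_under_budget(self):
        d = design_equimolar_mix({"AAA": 1, "TTT": 2}, 1, 1)
        assert [o.bases for o in d.oligos] == ["TTT"]
        assert d.covered_observations == 2 < d.total_observations

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            design_equimolar_mix({}, 1, 1)

    def test_matches_brute_force_optimum_on_clade_kmers(self):
        """Coverage equals exhaustive optimum on small synthetic instances."""
        rng = np.random.default_rng(42)
        variants = sorted(expand("TAYAAYTGGGTSAAYTA"))
        for _ in range(15):
            k = int(rng.integers(2, 7))
            idx = rng.choice(len(variants), size=k, replace=False)
            counts = {variants[i]: int(rng.integers(1, 10)) for i in idx}
            for max_oligos in (1, 2, 3):
                d = design_equimolar_mix(counts, max_oligos, 1)
                cands = _candidate_patterns(sorted(counts), 1)
                cover = {c: expand(c) & set(counts) for c in cands}
                best = 0
                for r in range(1, max_oligos + 1):
                    for combo in itertools.combinations(cands, r):
                        hit = set().union(*(cover[c] for c in combo))
                        best = max(best, sum(counts[x] for x in hit))
                assert d.covered_observations == best

    def test_coverage_nondecreasing_in_max_oligos(self):
        rng = np.random.default_rng(7)
        variants = sorted(expand("TAYTTCTGGACRTTYTA"))
        idx = rng.choice(len(variants), size=6, replace=False)
        counts = {variants[i]: int(rng.integers(1, 8)) for i in idx}
        prev = -1
        for max_oligos in range(1, 7):
            cov = design_equimolar_mix(counts, max_oligos, 1).covered_observations
            assert cov >= prev
            prev = cov


class TestMeltTemp:
    def test_basic_hand_value(self):
        s = melt_temp("TACAACTGGGTGAACTA", ThermoParams("basic"))
        assert s.min == s.mean == s.max == pytest.approx(42.23, abs=0.005)

    def test_salt_adjusted_hand_value(self):
        s = melt_temp("TACAACTGGGTGAACTA", ThermoParams("salt_adjusted", 0.05))
        assert s.mean == pytest.approx(47.55, abs=0.005)

    def test_basic_depends_only_on_gc_and_length(self):
        a = melt_temp("AAAAGGGG", ThermoParams("basic"))
        b = melt_temp("GCGCATAT", ThermoParams("basic"))
        assert a.mean == b.mean

    def test_degenerate_summary_ordering(self, clade_a_pair):
        s = melt_temp(clade_a_pair.forward[0], ThermoParams("salt_adjusted", 0.05))
        assert s.min <= s.mean <= s.max
        assert s.min < s.max  # GC varies across the S position

    def test_invalid_sodium_rejected(self):
        with pytest.raises(ValueError, match="sodium"):
            ThermoParams("salt_adjusted", 0.0)
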