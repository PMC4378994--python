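"""Flank read collection, isoform grouping, quantification, statistics."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import rankdata

import mornaseq as m
from mornaseq.morna_caller import IsoMember

CFG = m.PipelineConfig()


def _ext_hairpin(start=200, end=280, strand="+", chrom_len=1000):
    hp = m.HairpinRecord("mir-t", m.GenomicInterval("c", start, end, strand),
                         "A" * (end - start))
    return m.build_extended_hairpin(hp, CFG, chrom_len)


def _aln(start, end, strand="+", mm=0, seq=None):
    seq = seq or "A" * (end - start)
    return m.Alignment(seq, m.GenomicInterval("c", start, end, strand), mm, seq)


class TestCollectOffsetReads:
    def test_read_inside_5p_flank_is_candidate(self):
        eh = _ext_hairpin()
        out = m.collect_offset_reads([(_aln(175, 195), 1)], [eh], CFG)
        assert ("mir-t", "5p") in out

    def test_read_inside_hairpin_excluded(self):
        eh = _ext_hairpin()
        out = m.collect_offset_reads([(_aln(210, 230), 1)], [eh], CFG)
        assert out == {}

    def test_antisense_read_excluded(self):
        eh = _ext_hairpin()
        out = m.collect_offset_reads([(_aln(175, 195, "-"), 1)], [eh], CFG)
        assert out == {}

    def test_majority_overlap_assigns_boundary_spanner(self):
        """Read overlapping the flank by 18 nt and the hairpin by 2 nt is
        a 5p candidate; the reverse split is not."""
        eh = _ext_hairpin()
        out = m.collect_offset_reads([(_aln(182, 202), 1)], [eh], CFG)
        assert ("mir-t", "5p") in out
        out = m.collect_offset_reads([(_aln(198, 218), 1)], [eh], CFG)
        assert out == {}

    def test_minus_strand_flanks_mirrored(self):
        eh = _ext_hairpin(strand="-")
        # genome [280, 300) is the 5' flank of a minus-strand hairpin
        out = m.collect_offset_reads([(_aln(282, 300, "-"), 1)], [eh], CFG)
        assert ("mir-t", "5p") in out


class TestGroupIsoforms:
    def test_modal_by_multiplicity(self):
        members = [IsoMember(_aln(180, 199, seq="G" * 19), 2, "l"),
                   IsoMember(_aln(180, 200, seq="T" * 20), 1, "l")]
        g = m.group_isoforms(members, "mir-t", "5p", "+")
        assert g.modal_seq == "G" * 19

    def test_tie_broken_by_longer_sequence(self):
        members = [IsoMember(_aln(181, 200, seq="G" * 19), 2, "l"),
                   IsoMember(_aln(180, 200, seq="T" * 20), 2, "l")]
        g = m.group_isoforms(members, "mir-t", "5p", "+")
        assert g.modal_seq == "T" * 20

    def test_empty_candidate_set_yields_none(self):
        assert m.group_isoforms([], "mir-t", "5p", "+") is None

    @given(st.lists(st.tuples(st.integers(180, 185), st.integers(16, 22),
                              st.integers(1, 5)), min_size=1, max_size=15))
    def test_modal_equals_exhaustive_max(self, items):
        """Random multisets: the modal sequence carries maximal total
        multiplicity (exhaustive tally oracle)."""
        rng = np.random.default_rng(0)
        members = []
        for start, ln, mult in items:
            seq = "".join(rng.choice(list("ACGT"), size=ln))
            members.append(IsoMember(_aln(start, start + ln, seq=seq), mult, "l"))
        g = m.group_isoforms(members, "h", "5p", "+")
        tally = Counter()
        for mb in members:
            tally[mb.alignment.read_seq] += mb.multiplicity
        assert tally[g.modal_seq] == max(tally.values())


class TestQuantify:
    def _group(self):
        members = [IsoMember(_aln(180, 199, seq="G" * 19), 7, "l1")]
        return m.group_isoforms(members, "mir-t", "5p", "+")

    def test_single_library_counts_modal_reads(self):
        g = self._group()
        call = m.quantify_morna(g, {"l1": g.members}, CFG, {"l1": 1000})
        assert call.raw_count["l1"] == 7
        assert call.rpm["l1"] == pytest.approx(7000.0)
        assert call.name == "moR-t-5p"

    def test_read_outside_widened_locus_not_counted(self):
        g = self._group()
        outside = IsoMember(_aln(177, 199, seq="C" * 22), 3, "l1")
        call = m.quantify_morna(g, {"l1": g.members + [outside]}, CFG, {"l1": 1000})
        assert call.raw_count["l1"] == 7  # starts 3 nt before the window

    def test_hand_evaluated_isomor_fixture(self):
        """Five isomoRs with varying ends/mismatches vs the containment
        rule worked by hand (modal locus [180,199), window [178,201))."""
        g = self._group()
        extra = [
            IsoMember(_aln(178, 198, seq="A" * 20), 2, "l1"),   # inside: counted
            IsoMember(_aln(181, 201, seq="C" * 20), 3, "l1"),   # inside: counted
            IsoMember(_aln(178, 198, mm=1, seq="T" * 20), 5, "l1"),  # 1 mm: mode 0 drops
            IsoMember(_aln(177, 197, seq="G" * 20), 11, "l1"),  # start 177 < 178
        ]
        call0 = m.quantify_morna(g, {"l1": g.members + extra}, CFG, {"l1": 10 ** 6})
        assert call0.raw_count["l1"] == 7 + 2 + 3
        relaxed = m.PipelineConfig(quant_mismatches=2)
        call2 = m.quantify_morna(g, {"l1": g.members + extra}, relaxed, {"l1": 10 ** 6})
        assert call2.raw_count["l1"] == 7 + 2 + 3 + 5

    @given(st.lists(st.tuples(st.integers(175, 205), st.integers(16, 24),
                              st.integers(0, 2), st.integers(1, 4)),
                    min_size=1, max_size=20))
    def test_relaxed_mode_is_superset_of_exact_mode(self, items):
        """raw_count with 2 allowed mismatches >= raw_count with 0, always."""
        members = [IsoMember(_aln(s, s + ln, mm=mm), mult, "l")
                   for s, ln, mm, mult in items]
        g = m.group_isoforms(members, "h", "5p", "+")
        exact = m.quantify_morna(g, {"l": members}, CFG, {"l": 100})
        relaxed = m.quantify_morna(
            g, {"l": members}, m.PipelineConfig(quant_mismatches=2), {"l": 100})
        assert relaxed.raw_count["l"] >= exact.raw_count["l"]


class TestFivePrimeConsistency:
    def test_uniform_start_gives_one(self):
        members = [IsoMember(_aln(180, 180 + ln), 2, "l") for ln in (18, 19, 20)]
        g = m.group_isoforms(members, "h", "5p", "+")
        assert m.five_prime_consistency(g) == 1.0

    def test_symmetric_split_gives_half(self):
        members = [IsoMember(_aln(180, 199), 2, "l"),
                   IsoMember(_aln(181, 200), 2, "l")]
        g = m.group_isoforms(members, "h", "5p", "+")
        assert m.five_prime_consistency(g) == 0.5

    @given(st.lists(st.tuples(st.integers(180, 186), st.integers(1, 6)),
                    min_size=1, max_size=12))
    def test_equals_direct_tally(self, items):
        members = [IsoMember(_aln(s, s + 19), mult, "l") for s, mult in items]
        g = m.group_isoforms(members, "h", "5p", "+")
        tally = Counter()
        for s, mult in items:
            tally[s] += mult
        assert m.five_prime_consistency(g) == pytest.approx(
            max(tally.values()) / sum(tally.values()))

    def test_minus_strand_uses_transcript_orientation(self):
        # same genome end = same 5' end on the minus strand
        members = [IsoMember(_aln(180, 199, "-"), 3, "l"),
                   IsoMember(_aln(182, 199, "-"), 1, "l")]
        g = m.group_isoforms(members, "h", "5p", "-")
        assert m.five_prime_consistency(g) == 1.0


class TestStatsAndCorrelation:
    def _call(self, arm, count, rpm, lengths):
        call = m.MoRNACall("n", "h", arm, "A" * 19,
                           m.GenomicInterval("c", 180, 199, "+"))
        call.raw_count = {"l": count}
        call.rpm = {"l": rpm}
        call.length_histogram = lengths
        return call

    def test_no_call_passes_filters_gives_empty_histograms(self):
        calls = [self._call("5p", 3, 0.2, {19: 3})]
        hists = m.morna_stats(calls, CFG, "l")
        assert hists == {"5p": {}, "3p": {}}

    def test_single_passing_call_masses_at_its_length(self):
        calls = [self._call("5p", 10, 1.0, {19: 10})]
        hists = m.morna_stats(calls, CFG, "l")
        assert hists["5p"] == {19: 10}

    def test_perfectly_monotone_pairs_give_rho_one(self):
        mir = {("h%d" % i, "5p"): float(i + 1) for i in range(6)}
        mor = {("h%d" % i, "5p"): float((i + 1) * 3) for i in range(6)}
        rho, n = m.mir_mor_correlation(mir, mor, CFG)
        assert rho == pytest.approx(1.0) and n == 6

    def test_low_rpm_pair_excluded(self):
        mir = {("a", "5p"): 2.0, ("b", "5p"): 3.0, ("c", "5p"): 4.0,
               ("d", "5p"): 5.0}
        mor = {("a", "5p"): 0.3, ("b", "5p"): 1.0, ("c", "5p"): 2.0,
               ("d", "5p"): 3.0}
        rho, n = m.mir_mor_correlation(mir, mor, CFG)
        assert n == 3  # pair "a" dropped by the 0.5 RPM filter

    def test_too_few_pairs_reported_absent(self):
        rho, n = m.mir_mor_correlation({("a", "5p"): 2.0}, {("a", "5p"): 2.0}, CFG)
        assert rho is None and n == 1

    def test_spearman_equals_rank_then_pearson_oracle(self):
        """20-pair fixture: Spearman must equal average-rank Pearson."""
        rng = np.random.default_rng(4)
        keys = [("h%02d" % i, "5p") for i in range(20)]
        x = np.round(rng.uniform(0.6, 50, 20), 1)
        y = np.round(x * rng.uniform(0.5, 2, 20) + rng.normal(0, 5, 20), 1)
        y = np.clip(y, 0.6, None)
        rho, n = m.mir_mor_correlation(dict(zip(keys, x)), dict(zip(keys, y)), CFG)
        oracle = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
        assert n == 20 and rho == pytest.approx(oracle)


class TestExportMatrix:
    def test_rpm_threshold_filters_rows(self):
        counts = pd.DataFrame({"l1": [5, 20, 1], "l2": [0, 3, 1]},
                              index=["low", "high", "mid"])
        rpm = pd.DataFrame({"l1": [0.5, 2.0, 0.9], "l2": [0.0, 0.3, 0.9]},
                           index=counts.index)
        out = m.export_count_matrix(counts, rpm, CFG)
        assert list(out.index) == ["high"]

    def test_fixture_matrix_equals_hand_built_table(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(
            rng.integers(0, 40, size=(10, 2)),
            index=[f"f{i}" for i in range(10)], columns=["l1", "l2"],
        )
        totals = {"l1": 10_000, "l2": 20_000}
        rpm = m.rpm_normalize(counts, totals)
        out = m.export_count_matrix(counts, rpm, CFG)
        expect = [
            f"f{i}" for i in range(10)
            if counts.iloc[i, 0] / 0.01 >= 1.0 or counts.iloc[i, 1] / 0.02 >= 1.0
        ]
        assert list(out.index) == expect
        pd.testing.assert_frame_equal(out, counts.loc[expect])
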