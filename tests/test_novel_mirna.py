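"""Minor-arm miRNA calling, novel-hairpin filters and conservation calls."""

import io
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mornaseq as m
from mornaseq.novel_mirna import gc_fraction, minor_arm_decision

CFG = m.PipelineConfig()

# a published novel human hairpin candidate (hsa-mir-10522 locus sequence)
MIR_10522 = (
    "AGAAGAATTGGCCTACTCAGGtgtcagcaaagccttcctctcTGAATAGGTCAATTCCCCTCA"
)

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WB = {("G", "T"), ("T", "G")}


def _naive_pair_count(cand, mature, window=20, wobble=True):
    """Independent registration scan used as the duplex oracle."""
    c = cand[:window]
    mate = mature[::-1]
    best = 0
    for shift in range(-(len(c) - 1), len(mate)):
        n = 0
        for i, x in enumerate(c):
            j = i + shift
            if 0 <= j < len(mate):
                p = (x, mate[j])
                if p in _WC or (wobble and p in _WB):
                    n += 1
        best = max(best, n)
    return best


class TestDuplexPairCount:
    def test_perfect_reverse_complement_pairs_fully(self):
        mature = "ACGGTTCAGGATCCATGGCATCA"
        cand = m.revcomp(mature[:20])
        assert m.duplex_pair_count(cand, mature, 20) == 20

    def test_no_complementarity_scores_zero(self):
        assert m.duplex_pair_count("A" * 20, "A" * 20, 20, wobble_pairs=False) == 0

    @given(st.integers(0, 10 ** 6))
    def test_equals_exhaustive_registration_scan(self, seed):
        rng = np.random.default_rng(seed)
        cand = "".join(rng.choice(list("ACGT"), size=int(rng.integers(15, 25))))
        mature = "".join(rng.choice(list("ACGT"), size=int(rng.integers(18, 24))))
        assert m.duplex_pair_count(cand, mature, 20) == _naive_pair_count(cand, mature)

    @given(st.integers(0, 10 ** 6))
    def test_symmetric_when_window_covers_both(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), size=18))
        b = "".join(rng.choice(list("ACGT"), size=18))
        w = 25
        assert m.duplex_pair_count(a, b, w) == m.duplex_pair_count(b, a, w)

    @given(st.integers(0, 10 ** 6), st.integers(10, 19))
    def test_wider_window_never_decreases_pairs(self, seed, w):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), size=22))
        b = "".join(rng.choice(list("ACGT"), size=22))
        assert m.duplex_pair_count(a, b, w + 1) >= m.duplex_pair_count(a, b, w)


@given(st.integers(0, 40), st.booleans(), st.integers(0, 25))
def test_acceptance_logic_is_pure(reads, zero_mm, pairs):
    """The accept flag is fully determined by the three measured values."""
    expected = reads >= 10 and zero_mm and pairs >= 14
    assert minor_arm_decision(reads, zero_mm, pairs, CFG) == expected


def _make_hairpin(mature, cand, annotated="5p"):
    """Precursor = mature(22) + loop + candidate(20) + pad, one annotated arm."""
    loop = "TTCAAGAGA"
    pad = "GC"
    seq = mature + loop + cand + pad
    locus = m.GenomicInterval("c", 0, len(seq), "+")
    m5 = m.GenomicInterval("c", 0, 22, "+") if annotated == "5p" else None
    m3 = (m.GenomicInterval("c", len(seq) - 22, len(seq), "+")
          if annotated == "3p" else None)
    return m.HairpinRecord("mir-n", locus, seq, m5, m3)


def _reads_for(cand, start, n, mm=0):
    aln = m.Alignment(cand, m.GenomicInterval("c", start, start + len(cand), "+"),
                      mm, cand)
    return [(aln, n)]


class TestCallMinorArm:
    MATURE = "ACGGTTCAGGATCCATGGCATC"  # 22 nt

    def test_strong_candidate_accepted(self):
        cand = m.revcomp(self.MATURE)[:20]  # pairs 20/20
        hp = _make_hairpin(self.MATURE, cand)
        out = m.call_minor_arm(hp, _reads_for(cand, 31, 12), CFG)
        assert out.accepted and out.read_support == 12 and out.arm == "3p"
        assert out.candidate_seq == cand

    def test_nine_reads_rejected_on_support(self):
        cand = m.revcomp(self.MATURE)[:20]
        hp = _make_hairpin(self.MATURE, cand)
        out = m.call_minor_arm(hp, _reads_for(cand, 31, 9), CFG)
        assert not out.accepted and out.read_support == 9

    def test_mismatched_reads_not_candidates(self):
        cand = m.revcomp(self.MATURE)[:20]
        hp = _make_hairpin(self.MATURE, cand)
        out = m.call_minor_arm(hp, _reads_for(cand, 31, 12, mm=1), CFG)
        assert out.read_support == 0 and not out.accepted

    def test_fully_annotated_hairpin_skipped(self):
        seq = self.MATURE + "TTCAAGAGA" + m.revcomp(self.MATURE)
        hp = m.HairpinRecord(
            "mir-b", m.GenomicInterval("c", 0, len(seq), "+"), seq,
            m.GenomicInterval("c", 0, 22, "+"),
            m.GenomicInterval("c", len(seq) - 22, len(seq), "+"),
        )
        assert m.call_minor_arm(hp, [], CFG) is None

    def test_planted_minor_product_recovered_from_simulation(self, std_sim, std_result):
        """Synthetic single-mature hairpins: the recovered candidate equals
        the planted opposite-arm product."""
        cfg, ref, reads, truth = std_sim
        _, res = std_result
        by_name = {c.hairpin_name: c for c in res.minor_arm_candidates}
        for hp_name, (product, n) in truth.minor_arm.items():
            cand = by_name[hp_name]
            assert cand.candidate_seq == product
            assert cand.read_support >= n  # sequencing errors never inflate
            assert cand.accepted  # 30 planted reads, stem pairing >= 14


class TestNovelHairpinFilters:
    def _genome(self, hairpin, copies=1, seed=0):
        rng = np.random.default_rng(seed)
        parts = []
        for _ in range(copies):
            parts.append("".join(rng.choice(list("ACGT"), size=60)))
            parts.append(hairpin)
        parts.append("".join(rng.choice(list("ACGT"), size=60)))
        return {"g": "".join(parts)}

    def test_low_gc_fails_composition_criterion(self):
        hp = "AT" * 40  # GC 0
        rep = m.filter_novel_hairpin("cand", hp, [(hp[:20], 50)],
                                     self._genome(hp), CFG)
        assert not rep.passed and rep.gc_fraction == 0.0

    def test_twelve_genomic_copies_fail(self):
        rng = np.random.default_rng(1)
        hp = "".join(rng.choice(list("ACGT"), size=60))
        rep = m.filter_novel_hairpin("cand", hp, [(hp[:20], 50)],
                                     self._genome(hp, copies=12), CFG)
        assert rep.genomic_copies >= 12 and not rep.passed

    def test_published_hairpin_gc_matches_character_count(self):
        """GC fraction of the printed hairpin sequence equals a direct
        character tally, and the composition criterion passes."""
        seq = MIR_10522.upper()
        counts = Counter(seq)
        expected = (counts["G"] + counts["C"]) / len(seq)
        rep = m.filter_novel_hairpin("hsa-mir-10522", seq, [(seq[:20], 20)],
                                     self._genome(seq, seed=3), CFG)
        assert rep.gc_fraction == pytest.approx(expected)
        assert 0.15 <= rep.gc_fraction <= 0.90
        assert rep.passed

    def test_insufficient_main_product_reads_fail(self):
        rng = np.random.default_rng(2)
        hp = "".join(rng.choice(list("ACGT"), size=60))
        rep = m.filter_novel_hairpin("cand", hp, [(hp[:20], 9)],
                                     self._genome(hp), CFG)
        assert rep.main_product_reads == 9 and not rep.passed


class TestConservation:
    def _track(self, values, n=200):
        arr = np.zeros(n)
        arr[50:150] = values
        return m.ConservationTrack({"c": arr})

    def test_constant_high_track_is_conserved(self):
        flag, mean = m.conservation_class(
            m.GenomicInterval("c", 50, 150), self._track(0.8), CFG)
        assert flag and mean == pytest.approx(0.8)

    def test_boundary_mean_is_not_conserved(self):
        """Mean exactly at the threshold fails the strict inequality."""
        flag, mean = m.conservation_class(
            m.GenomicInterval("c", 50, 150), self._track(0.5), CFG)
        assert not flag and mean == pytest.approx(0.5)

    @given(st.integers(0, 10 ** 6))
    def test_mixed_track_mean_equals_direct_average(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 1, size=100)
        track = m.ConservationTrack({"c": vals})
        iv = m.GenomicInterval("c", 10, 90)
        _, mean = m.conservation_class(iv, track, CFG)
        assert mean == pytest.approx(vals[10:90].mean())

    def test_missing_positions_score_zero(self):
        track = m.ConservationTrack({"c": np.full(100, 1.0)})
        flag, mean = m.conservation_class(m.GenomicInterval("c", 80, 120), track, CFG)
        assert mean == pytest.approx(20 / 40)
        assert not flag

    def test_bedgraph_roundtrip(self):
        text = "c\t10\t20\t0.8\nc\t20\t30\t0.4\n"
        track = m.ConservationTrack.from_bedgraph(io.StringIO(text), {"c": 50})
        _, mean = m.conservation_class(m.GenomicInterval("c", 10, 30), track, CFG)
        assert mean == pytest.approx(0.6)


def test_gc_fraction_rejects_empty():
    with pytest.raises(ValueError):
        gc_fraction("")
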