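"""Synthetic reference and small RNA-seq library generator with ground truth.

The generator emulates the layout of an adapter-ligated small-RNA
sequencing experiment over miRNA hairpin loci: stem-loop precursors (3p
arm ~ reverse complement of the 5p arm with a few mutations) embedded in a
random genome with 30 nt flanks, planted moRNA populations on a subset of
hairpin arms, isomiR/isomoR end variation, decoy ncRNA classes, adapter
artifacts and a two-state quality model.  Default parameters reflect the
observed biology of human moRNAs: moR-5p lengths peaking at 19 nt over
16-26, moR-3p lengths spread over 16-29, ~97% consistent 5' ends for 3p
moRNAs, and a 58% 5'-arm share of moRNA reads.

Every emitted read traces to a truth record; identical configuration
(including the seed) gives byte-identical outputs.
"""

from __future__ import annotations

from collections import Counter, OrderedDict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

from .morna_caller import MoRNACall
from .novel_mirna import ConservationTrack
from .preprocess import SmallRead, write_fastq
from .refmodel import (
    GenomicInterval,
    HairpinRecord,
    PipelineConfig,
    revcomp,
    transcript_to_genome,
)

BASES = "ACGT"
_FLANK = 30  # moRNA search space per side; mirrors PipelineConfig.flank

_DEF_MOR5P_PMF = {
    16: 0.02, 17: 0.05, 18: 0.12, 19: 0.45, 20: 0.14,
    21: 0.10, 22: 0.05, 23: 0.03, 24: 0.02, 25: 0.01, 26: 0.01,
}


@dataclass
class SimConfig:
    """Study conditions for the simulator (defaults are the conditions the
    pipeline is validated under; see docs/methods.md)."""

    seed: int = 0
    # reference layer
    n_hairpins: int = 20
    mature_len: int = 22
    loop_len: tuple = (12, 18)
    arm_mutations: int = 3  # mismatches between 3p arm and rc(5p arm)
    spacing: tuple = (100, 220)  # intergenic gap between extended loci
    clustered_pairs: int = 0  # hairpin pairs placed < 60 nt apart
    minus_strand_frac: float = 0.4
    n_single_mature: int = 2  # hairpins annotated on one arm only
    conserved_frac: float = 0.65
    # planted moRNA populations
    n_planted_mornas: int = 12
    morna_reads_range: tuple = (20, 400)
    total_morna_reads: Optional[int] = None  # rescale planted counts to this
    arm_bias_5p: float = 0.58
    mor5p_len_pmf: dict = field(default_factory=lambda: dict(_DEF_MOR5P_PMF))
    mor5p_len_stay: float = 0.55  # P(read keeps the reference length)
    mor3p_len_range: tuple = (16, 29)
    mor3p_len_stay: float = 0.70
    five_prime_consistency_3p: float = 0.97
    anchor_jitter_5p: float = 0.05  # P(5p read overhangs the hairpin 1-2 nt)
    # planted minor-arm products on single-mature hairpins
    minor_arm_reads: int = 30
    # isomiR model
    mirna_canonical_p: float = 0.82
    # library layer
    library_size: int = 50_000
    error_rate: float = 0.001
    adapter: str = "TCGTATGCCGTCTTCTGCTTG"
    read_len: int = 36
    frac_low_quality: float = 0.02
    frac_dimer: float = 0.01
    frac_homopolymer: float = 0.005
    frac_short: float = 0.005
    background_fracs: dict = field(
        default_factory=lambda: {
            "tRNA": 0.09, "rRNA": 0.04, "snoRNA": 0.03,
            "snRNA": 0.02, "piRNA": 0.02,
        }
    )
    frac_genome_background: float = 0.08
    qual_good: int = 38
    qual_bad: int = 8

    def rngs(self):
        """Independent RNG streams for the reference and the reads, both
        derived from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        ref_ss, lib_ss = ss.spawn(2)
        return np.random.default_rng(ref_ss), np.random.default_rng(lib_ss)


@dataclass
class PlantedMoRNA:
    hairpin_name: str
    arm: str
    strand: str
    ref_seq: str
    ref_locus: GenomicInterval
    n_reads: int = 0
    n_compatible_exact: int = 0  # countable at 0 quantifier mismatches
    n_compatible_relaxed: int = 0  # countable allowing sequencing errors


@dataclass
class ReadOrigin:
    read_id: str
    category: str
    feature: str
    error_positions: tuple


@dataclass
class SimTruth:
    planted_mornas: list
    read_origins: list
    category_counts: Counter
    minor_arm: dict  # hairpin name -> (expected sequence, n reads)
    n_mor5p_reads: int = 0
    n_mor3p_reads: int = 0

    @property
    def arm_fraction_5p(self) -> Optional[float]:
        total = self.n_mor5p_reads + self.n_mor3p_reads
        return self.n_mor5p_reads / total if total else None


@dataclass
class SimReference:
    genome: dict  # chrom -> sequence
    hairpins: list  # HairpinRecord
    class_refs: "OrderedDict[str, dict]"  # cascade-ordered references
    conservation: ConservationTrack
    conserved_truth: dict  # hairpin name -> bool
    planted_mornas: list  # PlantedMoRNA templates (counts pre-allocated)
    single_mature: list  # hairpin names annotated on one arm
    free_intervals: list  # (start, end) intergenic spans for background

    @property
    def chrom(self) -> str:
        return next(iter(self.genome))


def _rand_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _mutate(rng, seq: str, n_mut: int) -> str:
    seq = list(seq)
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        seq[p] = rng.choice([b for b in BASES if b != seq[p]])
    return "".join(seq)


def _build_hairpin_seq(rng, cfg: SimConfig) -> str:
    """Stem-loop: 5p arm + loop + (reverse complement of 5p arm with a few
    mutations) so the two arms form a strong but imperfect duplex."""
    arm5 = _rand_seq(rng, cfg.mature_len)
    loop = _rand_seq(rng, int(rng.integers(cfg.loop_len[0], cfg.loop_len[1] + 1)))
    arm3 = _mutate(rng, revcomp(arm5), cfg.arm_mutations)
    return arm5 + loop + arm3


def simulate_reference(cfg: SimConfig) -> SimReference:
    """Build the genome, hairpin annotations, decoys and conservation track.

    Hairpins are embedded with at least ``cfg.spacing[0]`` nt between
    extended loci (clustered pairs, when requested, sit closer than 60 nt
    to exercise shared flanks).  Planted moRNA loci, reference isoform
    lengths and read allocations are fixed here so the reference stream is
    independent of the library size.
    """
    rng, _ = cfg.rngs()
    flank = 30
    chrom = "chrS"
    parts: list = []
    pos = 0
    free: list = []
    hairpins: list = []

    n_minus = int(round(cfg.n_hairpins * cfg.minus_strand_frac))
    strands = ["-"] * n_minus + ["+"] * (cfg.n_hairpins - n_minus)
    strands = [strands[i] for i in rng.permutation(cfg.n_hairpins)]
    single_idx = set(
        rng.choice(cfg.n_hairpins, size=cfg.n_single_mature, replace=False).tolist()
    ) if cfg.n_single_mature else set()

    clustered_partner = set()
    for k in range(cfg.clustered_pairs):
        clustered_partner.add(2 * k + 1)  # follows its even-index partner closely

    for i in range(cfg.n_hairpins):
        if i in clustered_partner:
            gap = int(rng.integers(5, 25))  # hairpins < 60 nt apart incl. flanks
        else:
            gap = int(rng.integers(cfg.spacing[0], cfg.spacing[1] + 1)) + 2 * flank
            # keep clear of both neighbouring extended loci
            free.append((pos + flank, pos + gap - flank))
        parts.append(_rand_seq(rng, gap))
        pos += gap

        hp_seq = _build_hairpin_seq(rng, cfg)
        L = len(hp_seq)
        strand = strands[i]
        genome_seq = hp_seq if strand == "+" else revcomp(hp_seq)
        start, end = pos, pos + L
        parts.append(genome_seq)
        pos = end

        name = f"sim-mir-{i + 1:03d}"
        m5 = transcript_to_genome(start, end, strand, 0, cfg.mature_len, chrom)
        m3 = transcript_to_genome(start, end, strand, L - cfg.mature_len, L, chrom)
        if i in single_idx:
            # annotate one arm only; the other arm is the minor-arm target
            if rng.random() < 0.5:
                m3 = None
            else:
                m5 = None
        hairpins.append(
            HairpinRecord(
                name=name,
                locus=GenomicInterval(chrom, start, end, strand),
                sequence=hp_seq,
                mature5p=m5,
                mature3p=m3,
            )
        )
    tail = int(rng.integers(cfg.spacing[0], cfg.spacing[1])) + flank
    parts.append(_rand_seq(rng, tail))
    free.append((pos + flank, pos + tail))
    pos += tail

    # decoy ncRNA classes, embedded on the plus strand after the hairpins
    decoy_plan = {
        "tRNA": (15, 72), "rRNA": (2, 500), "snoRNA": (8, 100),
        "snRNA": (5, 120), "piRNA": (20, 28),
    }
    class_refs: "OrderedDict[str, dict]" = OrderedDict()
    decoys: "OrderedDict[str, dict]" = OrderedDict()
    for label, (n, ln) in decoy_plan.items():
        seqs = {}
        for j in range(n):
            gap = int(rng.integers(40, 80))
            parts.append(_rand_seq(rng, gap))
            pos += gap
            s = _rand_seq(rng, ln)
            seqs[f"{label}-{j + 1}"] = s
            parts.append(s)
            pos += ln
        decoys[label] = seqs
    parts.append(_rand_seq(rng, 100))
    pos += 100
    genome = {chrom: "".join(parts)}

    class_refs["mirna_hairpin"] = {hp.name: hp.sequence for hp in hairpins}
    for label in ("snRNA", "snoRNA", "rRNA"):
        class_refs[label] = decoys[label]
    class_refs["piRNA"] = decoys["piRNA"]
    class_refs["tRNA"] = decoys["tRNA"]

    # conservation: a planted conserved/nonconserved label per hairpin
    arrays = {chrom: np.zeros(len(genome[chrom]))}
    conserved_truth = {}
    for hp in hairpins:
        ext = hp.locus.widened(flank, len(genome[chrom]))
        conserved = bool(rng.random() < cfg.conserved_frac)
        conserved_truth[hp.name] = conserved
        lo, hi = (0.55, 1.0) if conserved else (0.0, 0.45)
        arrays[chrom][ext.start : ext.end] = rng.uniform(lo, hi, size=len(ext))
    track = ConservationTrack(arrays)

    planted = _plan_mornas(rng, cfg, hairpins, single_idx, chrom)
    return SimReference(
        genome=genome,
        hairpins=hairpins,
        class_refs=class_refs,
        conservation=track,
        conserved_truth=conserved_truth,
        planted_mornas=planted,
        single_mature=[hairpins[i].name for i in sorted(single_idx)],
        free_intervals=free,
    )


def _plan_mornas(rng, cfg, hairpins, single_idx, chrom) -> list:
    """Choose planted (hairpin, arm) loci, reference isoforms and read
    counts; counts are rescaled so the 5' arm carries ``arm_bias_5p`` of
    the planted moRNA reads."""
    eligible = [i for i in range(len(hairpins)) if i not in single_idx]
    chosen = rng.choice(eligible, size=min(cfg.n_planted_mornas, len(eligible)),
                        replace=False)
    lens5 = sorted(cfg.mor5p_len_pmf)
    p5 = np.array([cfg.mor5p_len_pmf[k] for k in lens5])
    p5 = p5 / p5.sum()
    planted = []
    for i in sorted(chosen.tolist()):
        hp = hairpins[i]
        arm = "5p" if rng.random() < 0.5 else "3p"
        L = len(hp.sequence)
        if arm == "5p":
            ref_len = int(rng.choice(lens5, p=p5))
            t1, t2 = -ref_len, 0
        else:
            ref_len = int(rng.integers(cfg.mor3p_len_range[0],
                                       cfg.mor3p_len_range[1] + 1))
            t1, t2 = L, L + ref_len
        loc = hp.locus
        ref_iv = transcript_to_genome(loc.start, loc.end, loc.strand, t1, t2, chrom)
        n = int(rng.integers(cfg.morna_reads_range[0], cfg.morna_reads_range[1] + 1))
        planted.append(
            PlantedMoRNA(hp.name, arm, loc.strand, "", ref_iv, n_reads=n)
        )
    # rescale counts toward the configured 5' arm share
    total = cfg.total_morna_reads or sum(p.n_reads for p in planted)
    s5 = sum(p.n_reads for p in planted if p.arm == "5p")
    s3 = sum(p.n_reads for p in planted if p.arm == "3p")
    for p in planted:
        if p.arm == "5p" and s5:
            p.n_reads = max(cfg.morna_reads_range[0],
                            int(round(p.n_reads * cfg.arm_bias_5p * total / s5)))
        elif p.arm == "3p" and s3:
            p.n_reads = max(cfg.morna_reads_range[0],
                            int(round(p.n_reads * (1 - cfg.arm_bias_5p) * total / s3)))
    return planted


def _extract(genome: Mapping[str, str], iv: GenomicInterval) -> str:
    seq = genome[iv.chrom][iv.start : iv.end]
    return seq if iv.strand == "+" else revcomp(seq)


def _apply_errors(rng, seq: str, rate: float) -> tuple:
    if rate <= 0:
        return seq, ()
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq, ()
    pos = sorted(rng.choice(len(seq), size=n_err, replace=False).tolist())
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out), tuple(pos)


def simulate_library(ref: SimReference, cfg: SimConfig) -> tuple:
    """Sample a FASTQ-ready read list plus its ground truth.

    Reads are feature isoforms with per-base errors and an appended 3'
    adapter, padded/truncated to a fixed machine read length; qualities
    follow a two-state model (good Q38 / bad Q8).  Planted artifact
    classes (adapter dimers, homopolymers, short inserts, low-quality
    reads) are emitted at their configured rates.
    """
    _, rng = cfg.rngs()
    chrom = ref.chrom
    L_total = cfg.library_size
    n_low = int(round(cfg.frac_low_quality * L_total))
    n_dimer = int(round(cfg.frac_dimer * L_total))
    n_homo = int(round(cfg.frac_homopolymer * L_total))
    n_short = int(round(cfg.frac_short * L_total))
    n_bg = {c: int(round(f * L_total)) for c, f in cfg.background_fracs.items()}
    n_gbg = int(round(cfg.frac_genome_background * L_total))

    planted = [replace(p) for p in ref.planted_mornas]
    n_morna = sum(p.n_reads for p in planted)
    minor_total = cfg.minor_arm_reads * len(ref.single_mature)
    n_mirna = (
        L_total - n_low - n_dimer - n_homo - n_short
        - sum(n_bg.values()) - n_gbg - n_morna - minor_total
    )
    if n_mirna < 0:
        raise ValueError("library_size too small for the planted populations")

    hp_by_name = {hp.name: hp for hp in ref.hairpins}
    raw: list = []  # (insert, category, feature, errors)

    # --- planted moRNAs ---------------------------------------------------
    n_mor5 = n_mor3 = 0
    lens5 = sorted(cfg.mor5p_len_pmf)
    for p in planted:
        hp = hp_by_name[p.hairpin_name]
        loc = hp.locus
        L = len(hp.sequence)
        if p.arm == "5p":
            ref_len = len(p.ref_locus)
            ref_t = (-ref_len, 0)
        else:
            ref_len = len(p.ref_locus)
            ref_t = (L, L + ref_len)
        p.ref_seq = _extract(ref.genome, p.ref_locus)
        for _ in range(p.n_reads):
            if p.arm == "5p":
                t_end = 0
                if rng.random() < cfg.anchor_jitter_5p:
                    t_end = int(rng.integers(1, 3))  # overhang into the hairpin
                ln = ref_len
                if rng.random() >= cfg.mor5p_len_stay:
                    d = int(rng.choice([-3, -2, -1, 1, 2, 3]))
                    ln = min(max(ref_len + d, lens5[0]), lens5[-1])
                t1, t2 = t_end - ln, t_end
            else:
                t_start = L
                if rng.random() >= cfg.five_prime_consistency_3p:
                    t_start = L + int(rng.choice([-2, -1, 1, 2]))
                ln = ref_len
                if rng.random() >= cfg.mor3p_len_stay:
                    d = int(rng.choice([-2, -1, 1, 2]))
                    ln = min(max(ref_len + d, cfg.mor3p_len_range[0]),
                             cfg.mor3p_len_range[1])
                t1, t2 = t_start, t_start + ln
            iv = transcript_to_genome(loc.start, loc.end, loc.strand, t1, t2, chrom)
            seq, errs = _apply_errors(rng, _extract(ref.genome, iv), cfg.error_rate)
            # countable by the +-2 nt quantifier, and inside the flank
            # search space (reads past the 30 nt flank are not moRNA
            # evidence by definition)
            compatible = (
                ref_t[0] - 2 <= t1
                and t2 <= ref_t[1] + 2
                and -_FLANK <= t1
                and t2 <= L + _FLANK
            )
            if compatible:
                p.n_compatible_relaxed += 1
                if not errs:
                    p.n_compatible_exact += 1
            raw.append((seq, "morna", f"{p.hairpin_name}:{p.arm}", errs))
        if p.arm == "5p":
            n_mor5 += p.n_reads
        else:
            n_mor3 += p.n_reads

    # --- planted minor-arm products --------------------------------------
    minor_truth = {}
    for name in ref.single_mature:
        hp = hp_by_name[name]
        L = len(hp.sequence)
        if hp.mature5p is not None:
            t1, t2 = L - cfg.mature_len, L  # product on the 3p arm
        else:
            t1, t2 = 0, cfg.mature_len
        iv = transcript_to_genome(
            hp.locus.start, hp.locus.end, hp.locus.strand, t1, t2, chrom
        )
        product = _extract(ref.genome, iv)
        minor_truth[name] = (product, cfg.minor_arm_reads)
        for _ in range(cfg.minor_arm_reads):
            raw.append((product, "minor_arm", name, ()))

    # --- miRNA reads with isomiR end variation ----------------------------
    arms = []
    for hp in ref.hairpins:
        for arm in ("5p", "3p"):
            if hp.mature(arm) is not None:
                arms.append((hp, arm))
    w = rng.lognormal(mean=0.0, sigma=1.0, size=len(arms))
    alloc = rng.multinomial(n_mirna, w / w.sum())
    shift_vals = np.array([0, -1, 1, -2, 2])
    off_p = (1 - cfg.mirna_canonical_p) / 4
    shift_p = np.array([cfg.mirna_canonical_p, off_p, off_p, off_p, off_p])
    for (hp, arm), n in zip(arms, alloc):
        loc = hp.locus
        L = len(hp.sequence)
        t0 = (0, cfg.mature_len) if arm == "5p" else (L - cfg.mature_len, L)
        for _ in range(int(n)):
            ds = int(rng.choice(shift_vals, p=shift_p))
            de = int(rng.choice(shift_vals, p=shift_p))
            t1, t2 = t0[0] + ds, t0[1] + de
            if t2 - t1 < 16:
                t1, t2 = t0
            iv = transcript_to_genome(loc.start, loc.end, loc.strand, t1, t2, chrom)
            seq, errs = _apply_errors(rng, _extract(ref.genome, iv), cfg.error_rate)
            raw.append((seq, "mirna", f"{hp.name}-{arm}", errs))

    # --- decoy ncRNA background -------------------------------------------
    for label, n in n_bg.items():
        seqs = list(ref.class_refs.get(label, {}).items())
        for _ in range(n):
            name, s = seqs[int(rng.integers(len(seqs)))]
            ln = int(rng.integers(18, 26))
            ln = min(ln, len(s))
            start = int(rng.integers(0, len(s) - ln + 1))
            seq, errs = _apply_errors(rng, s[start : start + ln], cfg.error_rate)
            raw.append((seq, f"background:{label}", name, errs))

    # --- unannotated genome background ------------------------------------
    spans = [iv for iv in ref.free_intervals if iv[1] - iv[0] > 40]
    widths = np.array([b - a for a, b in spans], dtype=float)
    for _ in range(n_gbg):
        k = int(rng.choice(len(spans), p=widths / widths.sum()))
        a, b = spans[k]
        ln = int(rng.integers(18, 26))
        start = int(rng.integers(a, b - ln))
        seq, errs = _apply_errors(
            rng, ref.genome[chrom][start : start + ln], cfg.error_rate
        )
        raw.append((seq, "genome_background", f"{chrom}:{start}", errs))

    # --- artifacts ---------------------------------------------------------
    for _ in range(n_dimer):
        raw.append(("", "dimer", "adapter_dimer", ()))
    for _ in range(n_homo):
        raw.append(("A" * 20, "homopolymer", "polyA", ()))
    for _ in range(n_short):
        raw.append((_rand_seq(rng, int(rng.integers(8, 13))), "short", "short", ()))
    for _ in range(n_low):
        hp = ref.hairpins[int(rng.integers(len(ref.hairpins)))]
        seq = hp.sequence[: cfg.mature_len]
        raw.append((seq, "low_quality", hp.name, ()))

    # --- assemble reads ----------------------------------------------------
    order = rng.permutation(len(raw))
    reads: list = []
    origins: list = []
    cat_counts: Counter = Counter()
    for out_i, idx in enumerate(order):
        insert, category, feature, errs = raw[idx]
        rid = f"r{out_i + 1:06d}"
        full = (insert + cfg.adapter * 3)[: cfg.read_len]
        q = cfg.qual_bad if category == "low_quality" else cfg.qual_good
        reads.append(SmallRead(rid, full, tuple([q] * len(full))))
        origins.append(ReadOrigin(rid, category, feature, errs))
        cat_counts[category] += 1

    truth = SimTruth(
        planted_mornas=planted,
        read_origins=origins,
        category_counts=cat_counts,
        minor_arm=minor_truth,
        n_mor5p_reads=n_mor5,
        n_mor3p_reads=n_mor3,
    )
    return reads, truth


@dataclass
class RecoveryReport:
    n_planted: int
    n_recovered: int
    n_detected_calls: int
    n_false_calls: int
    recall: float
    precision: Optional[float]
    seq_exact: bool  # every recovered reference equals the planted modal
    abundance_rel_err: dict  # moRNA name -> relative count error (n>=50 only)


def evaluate_recovery(
    calls: Iterable[MoRNACall], truth: SimTruth, cfg: PipelineConfig
) -> RecoveryReport:
    """Compare pipeline moRNA calls against the planted truth.

    A planted moRNA is recovered iff a call at the same (hairpin, arm) has
    a reference sequence identical to the planted modal isoform.  Calls
    are considered detected at the >= ``cfg.sizedist_min_reads`` pooled
    read threshold; detected calls at unplanted loci count as false.
    Abundance errors compare the quantified count with the planted number
    of window-compatible reads (exact or mismatch-relaxed, matching
    ``cfg.quant_mismatches``).
    """
    planted_by_key = {(p.hairpin_name, p.arm): p for p in truth.planted_mornas}
    detected = [c for c in calls if c.pooled_count() >= cfg.sizedist_min_reads]
    n_rec = 0
    seq_exact = True
    abundance = {}
    n_false = 0
    det_by_key = {(c.hairpin_name, c.arm): c for c in detected}
    for key, c in det_by_key.items():
        if key not in planted_by_key:
            n_false += 1
    for key, p in planted_by_key.items():
        c = det_by_key.get(key)
        if c is None:
            continue
        if c.ref_seq == p.ref_seq:
            n_rec += 1
        else:
            seq_exact = False
        expected = (
            p.n_compatible_exact
            if cfg.quant_mismatches == 0
            else p.n_compatible_relaxed
        )
        if p.n_reads >= 50 and expected > 0:
            abundance[c.name] = (c.pooled_count() - expected) / expected
    n_planted = len(planted_by_key)
    return RecoveryReport(
        n_planted=n_planted,
        n_recovered=n_rec,
        n_detected_calls=len(detected),
        n_false_calls=n_false,
        recall=n_rec / n_planted if n_planted else float("nan"),
        precision=(
            (len(detected) - n_false) / len(detected) if detected else None
        ),
        seq_exact=seq_exact,
        abundance_rel_err=abundance,
    )


# ---------------------------------------------------------------------------
# file export / import


def write_reference(ref: SimReference, outdir) -> None:
    """Write genome FASTA, miRBase-dialect GFF3, per-class decoy FASTAs and
    the conservation bedGraph."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fa", "w") as fh:
        for name, seq in ref.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(out / "hairpins.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for i, hp in enumerate(ref.hairpins, 1):
            loc = hp.locus
            fh.write(
                f"{loc.chrom}\t.\tmiRNA_primary_transcript\t{loc.start + 1}\t"
                f"{loc.end}\t.\t{loc.strand}\t.\tID=MI{i:04d};Name={hp.name}\n"
            )
            for arm in ("5p", "3p"):
                m = hp.mature(arm)
                if m is None:
                    continue
                mname = hp.name.replace("mir", "miR") + f"-{arm}"
                fh.write(
                    f"{m.chrom}\t.\tmiRNA\t{m.start + 1}\t{m.end}\t.\t{m.strand}"
                    f"\t.\tID=MIMAT{i:04d}{arm};Name={mname};"
                    f"Derives_from=MI{i:04d}\n"
                )
    for label, seqs in ref.class_refs.items():
        if label == "mirna_hairpin":
            continue
        with open(out / f"{label}.fa", "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")
    with open(out / "conservation.bedgraph", "w") as fh:
        for chrom, arr in ref.conservation.chroms.items():
            # run-length encode equal consecutive values
            start = 0
            for i in range(1, len(arr) + 1):
                if i == len(arr) or arr[i] != arr[start]:
                    if arr[start] != 0.0:
                        fh.write(f"{chrom}\t{start}\t{i}\t{arr[start]:.4f}\n")
                    start = i


def write_library(reads, truth: SimTruth, outdir, name: str = "sim") -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fastq(reads, out / f"{name}.fastq")
    with open(out / f"{name}.truth.tsv", "w") as fh:
        fh.write("read_id\tcategory\tfeature\terror_positions\n")
        for o in truth.read_origins:
            errs = ",".join(map(str, o.error_positions))
            fh.write(f"{o.read_id}\t{o.category}\t{o.feature}\t{errs}\n")
    with open(out / f"{name}.planted.tsv", "w") as fh:
        fh.write(
            "hairpin\tarm\tstrand\tref_seq\tchrom\tstart\tend\t"
            "n_reads\tn_compatible_exact\tn_compatible_relaxed\n"
        )
        for p in truth.planted_mornas:
            fh.write(
                f"{p.hairpin_name}\t{p.arm}\t{p.strand}\t{p.ref_seq}\t"
                f"{p.ref_locus.chrom}\t{p.ref_locus.start}\t{p.ref_locus.end}\t"
                f"{p.n_reads}\t{p.n_compatible_exact}\t{p.n_compatible_relaxed}\n"
            )


def reverse_complement_reference(ref: SimReference) -> SimReference:
    """Mirror the whole reference: reverse-complement the genome and flip
    every coordinate and strand.  Used by strand-involution tests."""
    chrom = ref.chrom
    n = len(ref.genome[chrom])

    def flip(iv: Optional[GenomicInterval]) -> Optional[GenomicInterval]:
        if iv is None:
            return None
        return GenomicInterval(
            iv.chrom, n - iv.end, n - iv.start, "+" if iv.strand == "-" else "-"
        )

    hairpins = [
        HairpinRecord(
            name=hp.name,
            locus=flip(hp.locus),
            sequence=hp.sequence,  # sense sequence is strand-invariant
            mature5p=flip(hp.mature5p),
            mature3p=flip(hp.mature3p),
        )
        for hp in ref.hairpins
    ]
    arrays = {c: a[::-1].copy() for c, a in ref.conservation.chroms.items()}
    planted = [
        PlantedMoRNA(
            p.hairpin_name, p.arm, flip(p.ref_locus).strand, p.ref_seq,
            flip(p.ref_locus), p.n_reads,
            p.n_compatible_exact, p.n_compatible_relaxed,
        )
        for p in ref.planted_mornas
    ]
    return SimReference(
        genome={chrom: revcomp(ref.genome[chrom])},
        hairpins=hairpins,
        class_refs=ref.class_refs,
        conservation=ConservationTrack(arrays),
        conserved_truth=dict(ref.conserved_truth),
        planted_mornas=planted,
        single_mature=list(ref.single_mature),
        free_intervals=[(n - b, n - a) for a, b in ref.free_intervals],
    )
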