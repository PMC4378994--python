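"""Novel miRNA calling: minor-arm products, hairpin post-filters, conservation.

Minor-arm candidates come from precursors with a single annotated mature:
the modal perfectly-mapping read on the opposite arm is accepted when it
has at least 10 occurrences and pairs strongly (>=14 bp within its first
20 nt, antiparallel, G:U wobble allowed by default) with the known mature.
Externally predicted novel hairpins pass three post-filters: >=10 exactly
mapping reads on the main product, <=10 genomic copies, GC content within
the known miRNA range (15-90%).  A locus is conserved when its mean
per-base conservation score exceeds 0.5 (strict).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from Bio.SeqUtils import gc_fraction as _bio_gc_fraction

from .align_annotate import UngappedAligner
from .refmodel import GenomicInterval, HairpinRecord, PipelineConfig

log = logging.getLogger(__name__)

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


def _pairs(a: str, b: str, wobble: bool) -> bool:
    p = (a, b)
    return p in _WC or (wobble and p in _WOBBLE)


def duplex_pair_count(
    candidate: str,
    known_mature: str,
    window: int = 20,
    wobble_pairs: bool = True,
) -> int:
    """Maximal paired positions of the candidate's first ``window`` nt
    against the known mature over all ungapped antiparallel registrations.

    Watson-Crick pairs always count; G:U (here G:T, DNA alphabet) wobble
    counts when ``wobble_pairs`` is on.  The window is anchored on the
    candidate (its first ``window`` nt), which is the package's reading of
    "within the first 20 nt".
    """
    if not candidate or not known_mature:
        raise ValueError("sequences must be non-empty")
    cand = candidate.upper().replace("U", "T")[:window]
    mate = known_mature.upper().replace("U", "T")[::-1]  # antiparallel
    best = 0
    for shift in range(-(len(cand) - 1), len(mate)):
        n = 0
        for i, c in enumerate(cand):
            j = i + shift
            if 0 <= j < len(mate) and _pairs(c, mate[j], wobble_pairs):
                n += 1
        best = max(best, n)
    return best


@dataclass
class MinorArmCandidate:
    hairpin_name: str
    candidate_seq: str
    arm: str
    read_support: int
    pair_count: int
    accepted: bool


@dataclass
class HairpinFilterReport:
    candidate_name: str
    main_product_reads: int
    genomic_copies: int
    gc_fraction: float
    conserved: Optional[bool] = None
    passed: bool = False


def minor_arm_decision(
    read_support: int, zero_mismatch: bool, pair_count: int, cfg: PipelineConfig
) -> bool:
    """The pure three-criteria acceptance rule for a minor-arm candidate."""
    return (
        read_support >= cfg.minor_arm_min_reads
        and zero_mismatch
        and pair_count >= cfg.minor_arm_min_pairs
    )


def call_minor_arm(
    hairpin: HairpinRecord, arm_reads: Iterable, cfg: PipelineConfig
) -> Optional[MinorArmCandidate]:
    """Search the arm opposite a single known mature for a novel miRNA.

    ``arm_reads`` yields ``(Alignment, multiplicity)`` placements on the
    hairpin's chromosome.  Candidate reads map with zero mismatches, lie
    fully inside the precursor on its strand, and do not overlap the known
    mature.  The modal candidate sequence is scored against the known
    mature with :func:`duplex_pair_count`.  Hairpins with both arms
    annotated are skipped (returns None, logged).
    """
    if hairpin.n_matures() != 1:
        log.info("skipping %s: both arms annotated or none", hairpin.name)
        return None
    known_arm = "5p" if hairpin.mature5p is not None else "3p"
    known = hairpin.mature(known_arm)
    opposite = "3p" if known_arm == "5p" else "5p"
    known_seq = _mature_seq(hairpin, known)

    tally: Counter = Counter()
    for aln, mult in arm_reads:
        loc = aln.locus
        if (
            aln.mismatches == 0
            and loc.strand == hairpin.locus.strand
            and hairpin.locus.contains(loc)
            and loc.overlap(known) == 0
        ):
            tally[aln.read_seq] += mult
    if not tally:
        return MinorArmCandidate(hairpin.name, "", opposite, 0, 0, False)
    seq, support = max(tally.items(), key=lambda kv: (kv[1], len(kv[0]), kv[0]))
    pairs = duplex_pair_count(
        seq, known_seq, cfg.minor_arm_window, cfg.wobble_pairs
    )
    accepted = minor_arm_decision(support, True, pairs, cfg)
    return MinorArmCandidate(hairpin.name, seq, opposite, support, pairs, accepted)


def _mature_seq(hp: HairpinRecord, m: GenomicInterval) -> str:
    """Mature sequence in sense orientation, sliced from the precursor."""
    if hp.locus.strand == "+":
        a = m.start - hp.locus.start
        b = m.end - hp.locus.start
    else:
        a = hp.locus.end - m.end
        b = hp.locus.end - m.start
    return hp.sequence[a:b]


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return _bio_gc_fraction(seq.upper())


def filter_novel_hairpin(
    candidate_name: str,
    hairpin_seq: str,
    read_stack: Iterable,
    genome: Mapping[str, str],
    cfg: PipelineConfig,
    conservation: Optional["ConservationTrack"] = None,
    locus: Optional[GenomicInterval] = None,
) -> HairpinFilterReport:
    """Apply the three novel-hairpin post-filters to a predicted candidate.

    ``read_stack`` yields ``(seq, multiplicity)`` of the reads supporting
    the candidate.  The main product is the modal read sequence occurring
    exactly within the hairpin; genomic copies are full-length placements
    of the hairpin sequence in the genome within
    ``cfg.novel_copy_mismatches`` mismatches.
    """
    hp = hairpin_seq.upper()
    tally: Counter = Counter()
    for seq, mult in read_stack:
        if seq.upper() in hp:
            tally[seq.upper()] += mult
    main_reads = max(tally.values()) if tally else 0

    aligner = UngappedAligner(genome, cfg.novel_copy_mismatches)
    copies = len(aligner.align(hp))

    gc = gc_fraction(hp)
    lo, hi = cfg.gc_bounds
    passed = (
        main_reads >= cfg.novel_min_reads
        and copies <= cfg.novel_max_copies
        and lo <= gc <= hi
    )
    conserved = None
    if conservation is not None and locus is not None:
        conserved, _ = conservation_class(locus, conservation, cfg)
    return HairpinFilterReport(
        candidate_name=candidate_name,
        main_product_reads=main_reads,
        genomic_copies=copies,
        gc_fraction=gc,
        conserved=conserved,
        passed=passed,
    )


class ConservationTrack:
    """Per-base conservation scores backed by bedGraph intervals.

    Positions without data score 0 (logged once per query interval).
    """

    def __init__(self, chrom_arrays: Mapping[str, np.ndarray]):
        self.chroms = {c: np.asarray(a, dtype=float) for c, a in chrom_arrays.items()}

    @classmethod
    def from_bedgraph(cls, source, chrom_lengths: Mapping[str, int]) -> "ConservationTrack":
        arrays = {c: np.zeros(n) for c, n in chrom_lengths.items()}
        df = pd.read_csv(
            source, sep="\t", header=None, names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        df = df[~df["chrom"].str.startswith(("track", "#"))]
        df = df.astype({"start": int, "end": int, "value": float})
        for row in df.itertuples(index=False):
            if row.chrom in arrays:
                arrays[row.chrom][row.start : row.end] = row.value
        return cls(arrays)

    def values(self, interval: GenomicInterval) -> np.ndarray:
        if interval.chrom not in self.chroms:
            log.info("no conservation data for %s; scoring 0", interval.chrom)
            return np.zeros(len(interval))
        arr = self.chroms[interval.chrom]
        out = np.zeros(len(interval))
        a, b = interval.start, min(interval.end, len(arr))
        if b > a:
            out[: b - a] = arr[a:b]
        if b - a < len(interval):
            log.info("conservation track shorter than %s; missing scored 0", interval)
        return out


def conservation_class(
    interval: GenomicInterval, track: ConservationTrack, cfg: PipelineConfig
) -> tuple:
    """Mean conservation over an interval and the conserved flag.

    Conserved iff mean > ``cfg.conservation_threshold`` (strict).
    """
    vals = track.values(interval)
    if vals.size == 0:
        raise ValueError("empty interval")
    mean = float(vals.mean())
    return mean > cfg.conservation_threshold, mean
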