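"""Ungapped mismatch-tolerant alignment and the ncRNA annotation cascade.

The aligner reproduces Bowtie's -v-style behaviour: end-to-end, ungapped
placements with at most ``max_mismatches`` Hamming mismatches, reported on
both strands, with reads mapping to more than ``max_loci`` positions
discarded as multimapper overflow.  N bases count as mismatches against
every reference nucleotide.

Implementation is pigeonhole seed-and-verify: a read within k mismatches
of a reference window must match at least one of k+1 disjoint segments
exactly, so exact segment hits (C-speed ``str.find``) enumerate all
candidate offsets, each verified by bounded Hamming comparison.  This is
exhaustive - tested against a brute-force all-offsets scan.
"""

from __future__ import annotations

from collections import Counter, OrderedDict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .refmodel import GenomicInterval, HairpinRecord, PipelineConfig, revcomp

CASCADE_ORDER = (
    "mirna_hairpin",
    "snRNA",
    "snoRNA",
    "rRNA",
    "mt_tRNA",
    "miscRNA",
    "piRNA",
    "tRNA",
    "repeat",
)
ANNOTATION_LABELS = CASCADE_ORDER + ("unannotated",)


@dataclass(frozen=True)
class Alignment:
    """An end-to-end ungapped read placement."""

    read_id: str
    locus: GenomicInterval
    mismatches: int
    read_seq: str

    def __post_init__(self):
        if len(self.locus) != len(self.read_seq):
            raise ValueError("alignment is end-to-end: locus length != read length")


def _hamming_leq(a: str, b: str, limit: int) -> Optional[int]:
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return None
    return mm


class UngappedAligner:
    """Exhaustive ungapped alignment of short queries to a reference set."""

    def __init__(self, reference: Mapping[str, str], max_mismatches: int = 2):
        self.reference = {name: seq.upper() for name, seq in reference.items()}
        self.max_mismatches = max_mismatches

    def _candidates(self, text: str, query: str):
        """Candidate start offsets from exact hits of pigeonhole segments."""
        L = len(query)
        k = self.max_mismatches + 1
        if L < k:
            yield from range(len(text) - L + 1)
            return
        bounds = [round(i * L / k) for i in range(k + 1)]
        seen = set()
        n = len(text)
        for a, b in zip(bounds, bounds[1:]):
            seg = query[a:b]
            pos = text.find(seg)
            while pos != -1:
                start = pos - a
                if 0 <= start <= n - L and start not in seen:
                    seen.add(start)
                    yield start
                pos = text.find(seg, pos + 1)

    def align(self, seq: str) -> list:
        """All placements of ``seq`` (both strands) within the tolerance.

        Minus-strand placements compare the reverse-complemented query
        against the forward reference.
        """
        seq = seq.upper()
        hits = []
        queries = [(seq, "+"), (revcomp(seq), "-")]
        for name, text in self.reference.items():
            for query, strand in queries:
                if len(query) > len(text):
                    continue
                for start in self._candidates(text, query):
                    mm = _hamming_leq(
                        query, text[start : start + len(query)], self.max_mismatches
                    )
                    if mm is not None:
                        hits.append(
                            (
                                GenomicInterval(name, start, start + len(query), strand),
                                mm,
                            )
                        )
        # deterministic order
        hits.sort(key=lambda h: (h[0].chrom, h[0].start, h[0].strand))
        return hits


def brute_force_align(
    seq: str, reference: Mapping[str, str], max_mismatches: int = 2
) -> list:
    """All-offsets Hamming scan; the independent oracle for the aligner."""
    seq = seq.upper()
    hits = []
    for name, text in reference.items():
        text = text.upper()
        for query, strand in ((seq, "+"), (revcomp(seq), "-")):
            L = len(query)
            for start in range(len(text) - L + 1):
                mm = sum(x != y for x, y in zip(query, text[start : start + L]))
                if mm <= max_mismatches:
                    hits.append(
                        (GenomicInterval(name, start, start + L, strand), mm)
                    )
    hits.sort(key=lambda h: (h[0].chrom, h[0].start, h[0].strand))
    return hits


def align_reads(
    reads: Iterable, reference: Mapping[str, str], cfg: PipelineConfig
) -> tuple:
    """Align reads end-to-end to a reference.

    ``reads`` yields ``(read_id, seq)`` pairs (SmallReads also work).
    Returns ``(alignments, overflow, unaligned)`` where ``alignments`` maps
    read_id to a list of Alignment; reads with more than ``cfg.max_loci``
    placements land in ``overflow`` with no alignments kept.
    """
    aligner = UngappedAligner(reference, cfg.max_mismatches)
    cache: dict[str, list] = {}
    alignments: dict[str, list] = {}
    overflow: set = set()
    unaligned: set = set()
    for item in reads:
        if hasattr(item, "read_id"):
            read_id, seq = item.read_id, item.seq
        else:
            read_id, seq = item
        if seq not in cache:
            cache[seq] = aligner.align(seq)
        hits = cache[seq]
        if not hits:
            unaligned.add(read_id)
        elif len(hits) > cfg.max_loci:
            overflow.add(read_id)
        else:
            alignments[read_id] = [
                Alignment(read_id, locus, mm, seq) for locus, mm in hits
            ]
    return alignments, overflow, unaligned


def annotate_cascade(
    reads: Iterable,
    class_references: "OrderedDict[str, Mapping[str, str]]",
    cfg: PipelineConfig,
) -> dict:
    """First-match-wins annotation of reads against ncRNA class references.

    The ``mirna_hairpin`` class is tested with the mismatch-tolerant
    aligner; every later class requires exact (0-mismatch) containment of
    the read (or its reverse complement) in a reference sequence.  Reads
    matching nothing are ``unannotated``.
    """
    for label in class_references:
        if label not in ANNOTATION_LABELS:
            raise ValueError(f"unknown annotation class {label!r}")
    hairpin_aligner = None
    exact_texts = {}
    for label, refs in class_references.items():
        if label == "mirna_hairpin":
            hairpin_aligner = UngappedAligner(refs, cfg.max_mismatches)
        else:
            joined = "\n".join(s.upper() for s in refs.values())
            exact_texts[label] = joined + "\n" + revcomp(joined)

    labels: dict[str, str] = {}
    cache: dict[str, str] = {}
    for item in reads:
        if hasattr(item, "read_id"):
            read_id, seq = item.read_id, item.seq
        else:
            read_id, seq = item
        if seq not in cache:
            label = "unannotated"
            for cls in class_references:
                if cls == "mirna_hairpin":
                    if hairpin_aligner.align(seq):
                        label = cls
                        break
                elif seq in exact_texts[cls]:
                    label = cls
                    break
            cache[seq] = label
        labels[read_id] = cache[seq]
    return labels


def count_mature_mirna(
    lib_alignments: Mapping[str, Iterable],
    hairpins: Iterable[HairpinRecord],
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Count reads per mature miRNA with the +-2 nt locus-extension rule.

    ``lib_alignments`` maps library name to an iterable of
    ``(Alignment, multiplicity)``.  A read counts for a mature miRNA iff
    its aligned interval is contained within the mature locus widened by
    ``cfg.locus_extension`` per side on the same strand; a read may count
    at every locus it satisfies (paralogous loci with a shared sequence
    receive identical counts).  Returns a raw-count matrix
    (rows = mature names, columns = libraries).
    """
    matures = []
    for hp in hairpins:
        for arm in ("5p", "3p"):
            m = hp.mature(arm)
            if m is not None:
                matures.append((f"{hp.name}-{arm}", m.widened(cfg.locus_extension)))
    libs = list(lib_alignments)
    counts = pd.DataFrame(0, index=[n for n, _ in matures], columns=libs, dtype=int)
    for lib in libs:
        for aln, mult in lib_alignments[lib]:
            for name, widened in matures:
                if (
                    aln.locus.strand == widened.strand
                    and widened.contains(aln.locus)
                ):
                    counts.loc[name, lib] += mult
    return counts


def rpm_normalize(counts: pd.DataFrame, totals: Mapping[str, int]) -> pd.DataFrame:
    """Reads-per-million normalization with per-library denominators."""
    out = counts.astype(float).copy()
    for lib in counts.columns:
        denom = totals[lib]
        out[lib] = counts[lib] * 1e6 / denom if denom else float("nan")
    return out


def alignments_to_bed(alignments: Iterable[Alignment]) -> pd.DataFrame:
    """BED6-shaped table of placements (score column = mismatches)."""
    rows = [
        {
            "chrom": a.locus.chrom,
            "start": a.locus.start,
            "end": a.locus.end,
            "name": a.read_id,
            "score": a.mismatches,
            "strand": a.locus.strand,
        }
        for a in alignments
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
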