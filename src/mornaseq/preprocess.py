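"""Raw small-RNA read cleaning.

Stages, applied in order to each FASTQ record: mean-quality filter
(drop reads with mean Phred < Q20), 3'-end quality trimming, 3' adapter
removal, then dimer / homopolymer / minimum-length filters.  The 5' end is
never trimmed: for small RNAs it defines the biological molecule boundary
and trimming it would corrupt isoform-end statistics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

from .refmodel import PipelineConfig


@dataclass(frozen=True)
class SmallRead:
    read_id: str
    seq: str
    qual: tuple

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(f"{self.read_id}: seq/qual length mismatch")
        if len(self.seq) < 1:
            raise ValueError(f"{self.read_id}: empty read")


@dataclass
class PreprocessSummary:
    """Per-library rejection bookkeeping; counts are conserved."""

    n_raw: int = 0
    n_quality_fail: int = 0
    n_dimer: int = 0
    n_homopolymer: int = 0
    n_too_short: int = 0
    n_clean: int = 0

    def check(self) -> None:
        total = (
            self.n_quality_fail
            + self.n_dimer
            + self.n_homopolymer
            + self.n_too_short
            + self.n_clean
        )
        if total != self.n_raw:
            raise AssertionError("preprocess counts not conserved")


def filter_quality(read: SmallRead, cfg: PipelineConfig) -> bool:
    """Keep decision: arithmetic mean Phred >= cfg.min_mean_quality."""
    return sum(read.qual) / len(read.qual) >= cfg.min_mean_quality


def trim_ends(read: SmallRead, cfg: PipelineConfig) -> SmallRead:
    """Strip 3' bases while their quality is below cfg.min_mean_quality.

    May return a length-0 sequence (handled by downstream filters); the
    SmallRead container requires length >= 1, so a fully trimmed read is
    represented with an empty seq via an internal tuple result instead.
    """
    n = len(read.qual)
    while n > 0 and read.qual[n - 1] < cfg.min_mean_quality:
        n -= 1
    if n == len(read.qual):
        return read
    if n == 0:
        # placeholder single-N so the container invariant holds; classified
        # as too_short downstream
        return SmallRead(read.read_id, "N", (0,))
    return SmallRead(read.read_id, read.seq[:n], read.qual[:n])


def _hamming_leq(a: str, b: str, limit: int) -> Optional[int]:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return None
    return mm


def find_adapter(seq: str, adapter: str, cfg: PipelineConfig) -> Optional[int]:
    """Position of the leftmost adapter-prefix occurrence, or None.

    A prefix of the adapter anchored at position ``i`` matches when the
    overlap is at least ``adapter_min_overlap`` nt and carries at most one
    mismatch per ``adapter_mismatch_per`` matched bases.
    """
    n, m = len(seq), len(adapter)
    for i in range(0, n - cfg.adapter_min_overlap + 1):
        matched = min(m, n - i)
        allowed = matched // cfg.adapter_mismatch_per
        if _hamming_leq(seq[i : i + matched], adapter[:matched], allowed) is not None:
            return i
    return None


def _is_homopolymer(seq: str, frac: float) -> bool:
    if not seq:
        return False
    return Counter(seq).most_common(1)[0][1] / len(seq) >= frac


def trim_adapter(
    read: SmallRead, adapter: str, cfg: PipelineConfig
) -> tuple:
    """Remove the 3' adapter and classify the insert.

    Returns ``(trimmed_read_or_None, klass)`` with klass one of
    ``clean`` / ``dimer`` / ``homopolymer`` / ``too_short``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    pos = find_adapter(read.seq, adapter, cfg)
    if pos is None:
        insert, qual = read.seq, read.qual
    else:
        insert, qual = read.seq[:pos], read.qual[:pos]
    if len(insert) == 0:
        return None, "dimer"
    if _is_homopolymer(insert, cfg.homopolymer_frac):
        return None, "homopolymer"
    if len(insert) < cfg.min_read_len:
        return None, "too_short"
    return SmallRead(read.read_id, insert, qual), "clean"


def read_fastq(source) -> Iterator[SmallRead]:
    """Iterate a FASTQ (Phred+33) file or handle as SmallReads."""
    n = 0
    try:
        for rec in SeqIO.parse(source, "fastq"):
            n += 1
            yield SmallRead(
                rec.id,
                str(rec.seq).upper(),
                tuple(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ near record {n + 1}: {exc}") from exc


def write_fastq(reads: Iterable[SmallRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qual)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")


def preprocess_library(
    reads: Iterable[SmallRead], adapter: str, cfg: PipelineConfig
) -> tuple:
    """Clean a library; returns ``(clean_reads, PreprocessSummary)``."""
    summary = PreprocessSummary()
    clean = []
    for read in reads:
        summary.n_raw += 1
        if not filter_quality(read, cfg):
            summary.n_quality_fail += 1
            continue
        read = trim_ends(read, cfg)
        if read.seq == "N" and read.qual == (0,):
            summary.n_too_short += 1
            continue
        trimmed, klass = trim_adapter(read, adapter, cfg)
        if klass == "clean":
            summary.n_clean += 1
            clean.append(trimmed)
        else:
            setattr(summary, f"n_{klass}", getattr(summary, f"n_{klass}") + 1)
    summary.check()
    return clean, summary
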