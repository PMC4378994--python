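"""Genomic coordinate types, hairpin annotation parsing and the extended-hairpin model.

A miRNA precursor (hairpin) is widened by a fixed flank on each side; the
widened locus is partitioned into five regions in 5'->3' transcript order:

    moR-5p | miR-5p | loop | miR-3p | moR-3p

The moR regions are exactly the flanks measured from the precursor
boundaries.  Offset RNAs (moRNAs) are the short reads that fall into the
flanks; everything downstream of alignment consumes this region model.

Coordinates are 0-based half-open throughout the package; GFF3 input is
converted from 1-based inclusive on parse.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, fields, replace
from typing import Mapping, Optional

import gffutils
import yaml

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result is DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded half-open interval on a named reference sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies fully inside this interval (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap(self, other: Optional["GenomicInterval"]) -> int:
        """Number of overlapping bases with *other* (0 if None/other chrom)."""
        if other is None or self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def widened(self, by: int, chrom_len: Optional[int] = None) -> "GenomicInterval":
        start = max(0, self.start - by)
        end = self.end + by
        if chrom_len is not None:
            end = min(end, chrom_len)
        return GenomicInterval(self.chrom, start, end, self.strand)

    def five_prime_pos(self) -> int:
        """Genome coordinate keying the 5' end in transcript orientation."""
        return self.start if self.strand == "+" else self.end


def transcript_to_genome(
    hp_start: int, hp_end: int, strand: str, t1: int, t2: int, chrom: str
) -> Optional[GenomicInterval]:
    """Map a transcript-coordinate window [t1, t2) to genome coordinates.

    Transcript coordinate 0 is the 5' end of the hairpin; negative values
    reach into the 5' flank, values beyond the hairpin length into the 3'
    flank.  Returns None for empty windows.
    """
    if t2 <= t1:
        return None
    if strand == "+":
        return GenomicInterval(chrom, hp_start + t1, hp_start + t2, "+")
    return GenomicInterval(chrom, hp_end - t2, hp_end - t1, "-")


@dataclass(frozen=True)
class HairpinRecord:
    """A miRNA precursor with optional mature-arm annotations.

    ``sequence`` is the precursor in sense (5'->3' transcript) orientation;
    minus-strand records therefore hold the reverse complement of the
    genome slice.
    """

    name: str
    locus: GenomicInterval
    sequence: str
    mature5p: Optional[GenomicInterval] = None
    mature3p: Optional[GenomicInterval] = None

    def __post_init__(self):
        if len(self.sequence) != len(self.locus):
            raise ValueError(
                f"{self.name}: sequence length {len(self.sequence)} != "
                f"locus length {len(self.locus)}"
            )
        for arm, m in (("5p", self.mature5p), ("3p", self.mature3p)):
            if m is not None and not self.locus.contains(m):
                raise ValueError(f"{self.name}: mature {arm} outside precursor")
        if self.mature5p is not None and self.mature3p is not None:
            if self.locus.strand == "+":
                ok = self.mature5p.start < self.mature3p.start
            else:
                ok = self.mature5p.end > self.mature3p.end
            if not ok:
                raise ValueError(
                    f"{self.name}: mature5p does not precede mature3p in "
                    f"transcript orientation"
                )

    def mature(self, arm: str) -> Optional[GenomicInterval]:
        return self.mature5p if arm == "5p" else self.mature3p

    def n_matures(self) -> int:
        return (self.mature5p is not None) + (self.mature3p is not None)


@dataclass(frozen=True)
class RegionMap:
    """Five-region partition of an extended hairpin, in genome coordinates.

    The mir regions are extended outward to the precursor boundary so that
    the five regions always tile the extended locus; the exact mature loci
    stay available on the HairpinRecord.  On the minus strand moR5p lies at
    the higher genome coordinates.
    """

    moR5p: Optional[GenomicInterval]
    mir5p: Optional[GenomicInterval]
    loop: Optional[GenomicInterval]
    mir3p: Optional[GenomicInterval]
    moR3p: Optional[GenomicInterval]

    def as_dict(self) -> dict:
        return {
            "moR5p": self.moR5p,
            "mir5p": self.mir5p,
            "loop": self.loop,
            "mir3p": self.mir3p,
            "moR3p": self.moR3p,
        }


@dataclass(frozen=True)
class ExtendedHairpin:
    """A hairpin together with its flanks and region map."""

    hairpin: HairpinRecord
    flank: int
    extended_locus: GenomicInterval
    regions: RegionMap
    truncated_5p: bool = False
    truncated_3p: bool = False

    @property
    def name(self) -> str:
        return self.hairpin.name

    @property
    def strand(self) -> str:
        return self.hairpin.locus.strand

    def flank_region(self, arm: str) -> Optional[GenomicInterval]:
        return self.regions.moR5p if arm == "5p" else self.regions.moR3p


@dataclass
class PipelineConfig:
    """Every numeric threshold of the pipeline, with its published default.

    min_mean_quality: Phred; reads with a lower arithmetic mean are dropped
        and 3' bases below it are trimmed.
    min_read_len: inserts shorter than this after adapter removal are
        discarded.
    max_mismatches / max_loci: ungapped alignment tolerance and the
        multimapper cap (placements beyond it discard the read).
    flank: moRNA search space on each side of the precursor, nt.
    locus_extension: widening of a mature/reference locus when counting
        reads against it, nt per side.
    quant_mismatches: mismatch tolerance of the moRNA quantifier (0 for
        exact-match tables, 2 for DE-style tables).
    minor_arm_*: novel minor-arm miRNA criteria.
    novel_*: post-filters for externally predicted novel hairpins.
    gc_bounds: accepted GC-content range for a novel hairpin.
    conservation_threshold: mean per-base conservation above which a locus
        counts as conserved (strict inequality).
    de_min_rpm: inclusion threshold for the exported count matrix.
    sizedist_min_reads / sizedist_min_rpm: filters applied before length
        distributions.
    corr_min_rpm: both members of a miR/moR pair must exceed this RPM to
        enter the correlation.
    seed_span: 1-based inclusive positions of the seed on the small RNA.
    """

    min_mean_quality: float = 20.0
    min_read_len: int = 14
    max_mismatches: int = 2
    max_loci: int = 10
    flank: int = 30
    locus_extension: int = 2
    quant_mismatches: int = 0
    minor_arm_min_reads: int = 10
    minor_arm_min_pairs: int = 14
    minor_arm_window: int = 20
    novel_min_reads: int = 10
    novel_max_copies: int = 10
    gc_bounds: tuple = (0.15, 0.90)
    conservation_threshold: float = 0.5
    de_min_rpm: float = 1.0
    sizedist_min_reads: int = 5
    sizedist_min_rpm: float = 0.5
    corr_min_rpm: float = 0.5
    seed_span: tuple = (2, 8)
    # adapter matching (the study's in-house trimmer is unspecified; these
    # are the package's documented choices)
    adapter_min_overlap: int = 5
    adapter_mismatch_per: int = 7
    homopolymer_frac: float = 0.9
    # duplex scoring
    wobble_pairs: bool = True
    # "genome": per million genome-mapped reads; "exact": per million
    # exactly (0-mismatch) mapped reads
    rpm_denominator: str = "genome"
    novel_copy_mismatches: int = 2

    def __post_init__(self):
        self.gc_bounds = tuple(self.gc_bounds)
        self.seed_span = tuple(self.seed_span)
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if not (0 <= self.gc_bounds[0] <= self.gc_bounds[1] <= 1):
            raise ValueError("gc_bounds must be within [0, 1]")
        if self.seed_span[1] - self.seed_span[0] != 6:
            raise ValueError("seed_span must cover 7 positions")
        if self.rpm_denominator not in ("genome", "exact"):
            raise ValueError("rpm_denominator must be 'genome' or 'exact'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            f.name: (list(v) if isinstance(v := getattr(self, f.name), tuple) else v)
            for f in fields(self)
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def build_extended_hairpin(
    hp: HairpinRecord, cfg: PipelineConfig, chrom_len: int
) -> ExtendedHairpin:
    """Widen a hairpin by ``cfg.flank`` nt per side and map its five regions.

    Flanks are truncated silently (but flagged and logged) at chromosome
    edges; the region map always partitions the extended locus.
    """
    loc = hp.locus
    L = len(loc)
    ext = loc.widened(cfg.flank, chrom_len)
    # transcript-coordinate extents of the two flanks after clipping
    if loc.strand == "+":
        up = loc.start - ext.start  # 5' flank width
        down = ext.end - loc.end
    else:
        up = ext.end - loc.end
        down = loc.start - ext.start
    trunc5, trunc3 = up < cfg.flank, down < cfg.flank
    if trunc5 or trunc3:
        log.info("flank truncated at chromosome edge for %s", hp.name)

    # region boundaries in transcript coordinates
    if loc.strand == "+":
        m5_end_t = hp.mature5p.end - loc.start if hp.mature5p else 0
        m3_start_t = hp.mature3p.start - loc.start if hp.mature3p else L
    else:
        m5_end_t = loc.end - hp.mature5p.start if hp.mature5p else 0
        m3_start_t = loc.end - hp.mature3p.end if hp.mature3p else L

    def span(t1, t2):
        return transcript_to_genome(loc.start, loc.end, loc.strand, t1, t2, loc.chrom)

    regions = RegionMap(
        moR5p=span(-up, 0),
        mir5p=span(0, m5_end_t),
        loop=span(m5_end_t, m3_start_t),
        mir3p=span(m3_start_t, L),
        moR3p=span(L, L + down),
    )
    return ExtendedHairpin(
        hairpin=hp,
        flank=cfg.flank,
        extended_locus=ext,
        regions=regions,
        truncated_5p=trunc5,
        truncated_3p=trunc3,
    )


def parse_hairpin_annotations(
    gff_source, genome: Mapping[str, str]
) -> list:
    """Parse miRBase-dialect GFF3 into HairpinRecords.

    ``gff_source`` may be a path or GFF3 text.  Precursors are
    ``miRNA_primary_transcript`` features; matures are ``miRNA`` features
    pointing at their precursor through a ``Derives_from`` attribute.
    Sequences are extracted from ``genome`` with minus-strand records
    reverse complemented into sense orientation; mature arms are assigned
    5p/3p by their precursor-relative position.
    """
    text = gff_source
    if "\n" not in str(gff_source):
        with open(gff_source) as fh:
            text = fh.read()
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    precursors: dict[str, dict] = {}
    for feat in db.features_of_type("miRNA_primary_transcript"):
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        fid = feat.attributes.get("ID", [feat.id])[0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        if feat.seqid not in genome:
            raise ValueError(f"precursor {name} on unknown sequence {feat.seqid}")
        if iv.end > len(genome[feat.seqid]):
            raise ValueError(f"precursor {name} outside {feat.seqid}")
        seq = genome[feat.seqid][iv.start : iv.end].upper()
        if iv.strand == "-":
            seq = revcomp(seq)
        precursors[fid] = {"name": name, "locus": iv, "seq": seq, "matures": []}

    for feat in db.features_of_type("miRNA"):
        parent = feat.attributes.get("Derives_from", [None])[0]
        mname = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        if parent is None or parent not in precursors:
            raise ValueError(
                f"mature feature {mname} has no matching precursor "
                f"(Derives_from={parent})"
            )
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        pre = precursors[parent]
        if not pre["locus"].contains(iv):
            raise ValueError(f"mature {mname} outside precursor {pre['name']}")
        pre["matures"].append(iv)

    records = []
    for pre in precursors.values():
        loc = pre["locus"]
        matures = pre["matures"]
        m5 = m3 = None
        if len(matures) == 1:
            m = matures[0]
            # arm by which half of the precursor holds the mature midpoint
            mid = (m.start + m.end) / 2
            pmid = (loc.start + loc.end) / 2
            is5p = (mid < pmid) if loc.strand == "+" else (mid > pmid)
            m5, m3 = (m, None) if is5p else (None, m)
        elif len(matures) >= 2:
            if len(matures) > 2:
                raise ValueError(f"{pre['name']}: more than two mature features")
            a, b = sorted(matures, key=lambda m: m.start)
            m5, m3 = (a, b) if loc.strand == "+" else (b, a)
        records.append(
            HairpinRecord(
                name=pre["name"],
                locus=loc,
                sequence=pre["seq"],
                mature5p=m5,
                mature3p=m3,
            )
        )
    return records


def morna_name(hairpin_name: str, arm: str) -> str:
    """moRNA naming convention: hsa-mir-367 + 3p -> hsa-moR-367-3p."""
    for tag in ("mir-", "miR-"):
        if tag in hairpin_name:
            return hairpin_name.replace(tag, "moR-", 1) + f"-{arm}"
    return f"moR-{hairpin_name}-{arm}"
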