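"""moRNA discovery, isoform grouping, quantification and descriptive statistics.

moRNAs are the short reads immediately flanking a miRNA precursor.  The
caller gathers strand-concordant reads from the 30 nt flanks of each
extended hairpin (excluding reads fully inside the hairpin; boundary
spanners are assigned by majority overlap), groups overlapping isoforms
(isomoRs), picks the most abundant isomoR as the moRNA's reference
sequence, and quantifies each library by counting reads contained in the
reference locus widened by 2 nt per side within the configured mismatch
tolerance.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
from scipy import stats as _scistats

from .align_annotate import Alignment
from .refmodel import (
    ExtendedHairpin,
    GenomicInterval,
    PipelineConfig,
    morna_name,
)


@dataclass(frozen=True)
class IsoMember:
    """One aligned isoform observation with its read multiplicity."""

    alignment: Alignment
    multiplicity: int
    library: str


@dataclass
class IsoGroup:
    """Overlapping isoform reads at one hairpin arm."""

    hairpin_name: str
    arm: str  # 5p | 3p
    strand: str
    members: list  # of IsoMember
    modal_seq: str = ""
    modal_locus: Optional[GenomicInterval] = None

    def total_multiplicity(self, library: Optional[str] = None) -> int:
        return sum(
            m.multiplicity
            for m in self.members
            if library is None or m.library == library
        )

    def n_unique_seqs(self) -> int:
        return len({m.alignment.read_seq for m in self.members})


@dataclass
class MoRNACall:
    """A named moRNA with its reference isomoR and per-library expression."""

    name: str
    hairpin_name: str
    arm: str
    ref_seq: str
    ref_locus: GenomicInterval
    raw_count: dict = field(default_factory=dict)  # library -> int
    rpm: dict = field(default_factory=dict)  # library -> float
    n_unique_isomors: int = 0
    five_prime_consistency: float = 0.0
    length_histogram: dict = field(default_factory=dict)  # length -> multiplicity

    def pooled_count(self) -> int:
        return sum(self.raw_count.values())

    def detected(self, library: str) -> bool:
        return self.raw_count.get(library, 0) >= 1


@dataclass
class LibraryStats:
    """Pipeline-stage totals and moRNA arm usage for one library."""

    library: str
    n_raw: int = 0
    n_clean: int = 0
    n_genome_mapped: int = 0
    n_exact_mapped: int = 0
    n_hairpin_mapped: int = 0
    n_mor5p: int = 0
    n_mor3p: int = 0

    @property
    def arm_fraction_5p(self) -> Optional[float]:
        total = self.n_mor5p + self.n_mor3p
        return self.n_mor5p / total if total else None


def collect_offset_reads(
    alignments: Iterable,
    ext_hairpins: Iterable[ExtendedHairpin],
    cfg: PipelineConfig,
    library: str = "lib",
) -> dict:
    """Assign flank reads to (hairpin, arm) candidate sets.

    ``alignments`` yields ``(Alignment, multiplicity)``.  A read joins the
    5p candidate set of a hairpin iff its interval lies within the
    extended locus, is not fully contained in the hairpin locus, is
    strand-concordant, and overlaps the 5' flank by more nucleotides than
    it overlaps the hairpin; symmetric for 3p.  Reads overhanging the
    mature miRNA by a nucleotide or two therefore remain eligible.
    """
    by_chrom: dict[str, list] = defaultdict(list)
    for eh in ext_hairpins:
        by_chrom[eh.extended_locus.chrom].append(eh)
    out: dict[tuple, list] = defaultdict(list)
    for aln, mult in alignments:
        for eh in by_chrom.get(aln.locus.chrom, ()):
            hp_locus = eh.hairpin.locus
            if aln.locus.strand != hp_locus.strand:
                continue
            if not eh.extended_locus.contains(aln.locus):
                continue
            if hp_locus.contains(aln.locus):
                continue
            oh = aln.locus.overlap(hp_locus)
            o5 = aln.locus.overlap(eh.regions.moR5p)
            o3 = aln.locus.overlap(eh.regions.moR3p)
            if o5 > oh and o5 >= o3:
                out[(eh.name, "5p")].append(IsoMember(aln, mult, library))
            elif o3 > oh:
                out[(eh.name, "3p")].append(IsoMember(aln, mult, library))
    return dict(out)


def group_isoforms(
    candidates: Iterable[IsoMember], hairpin_name: str, arm: str, strand: str
) -> Optional[IsoGroup]:
    """Build an IsoGroup and select its modal (most abundant) sequence.

    Ties on multiplicity break deterministically: longer sequence first,
    then 5'-most start in transcript orientation, then lexicographic.
    """
    members = list(candidates)
    if not members:
        return None
    tally: Counter = Counter()
    locus_of: dict = {}
    for m in members:
        key = (m.alignment.read_seq, m.alignment.locus)
        tally[key] += m.multiplicity
        locus_of[key] = m.alignment.locus

    def rank(key):
        seq, locus = key
        five_most = locus.start if strand == "+" else -locus.end
        return (tally[key], len(seq), -five_most, _lex_inverse(seq))

    best = max(tally, key=rank)
    return IsoGroup(
        hairpin_name=hairpin_name,
        arm=arm,
        strand=strand,
        members=members,
        modal_seq=best[0],
        modal_locus=locus_of[best],
    )


def _lex_inverse(seq: str) -> tuple:
    # max() with lexicographically *smallest* sequence winning the last tie
    return tuple(-ord(c) for c in seq)


def five_prime_consistency(group: IsoGroup) -> float:
    """Fraction of read multiplicity sharing the modal 5' end position.

    Weighted by read multiplicity (not by unique sequence); the 5' end is
    taken in transcript orientation.
    """
    tally: Counter = Counter()
    for m in group.members:
        tally[m.alignment.locus.five_prime_pos()] += m.multiplicity
    total = sum(tally.values())
    if total == 0:
        raise ValueError("empty isoform group")
    return max(tally.values()) / total


def quantify_morna(
    group: IsoGroup,
    lib_candidates: Mapping[str, Iterable[IsoMember]],
    cfg: PipelineConfig,
    totals: Mapping[str, int],
) -> MoRNACall:
    """Quantify a moRNA against its reference isomoR locus.

    Per library, ``raw_count`` is the multiplicity of reads whose interval
    is contained in the modal locus widened by ``cfg.locus_extension`` per
    side, same strand, with at most ``cfg.quant_mismatches`` mismatches.
    RPM uses the per-library denominators in ``totals``.
    """
    if group.modal_locus is None:
        raise ValueError("group has no modal locus")
    widened = group.modal_locus.widened(cfg.locus_extension)
    call = MoRNACall(
        name=morna_name(group.hairpin_name, group.arm),
        hairpin_name=group.hairpin_name,
        arm=group.arm,
        ref_seq=group.modal_seq,
        ref_locus=group.modal_locus,
    )
    for lib, members in lib_candidates.items():
        count = 0
        for m in members:
            loc = m.alignment.locus
            if (
                loc.strand == group.strand
                and widened.contains(loc)
                and m.alignment.mismatches <= cfg.quant_mismatches
            ):
                count += m.multiplicity
        call.raw_count[lib] = count
        denom = totals.get(lib, 0)
        call.rpm[lib] = count * 1e6 / denom if denom else float("nan")
    call.n_unique_isomors = group.n_unique_seqs()
    call.five_prime_consistency = five_prime_consistency(group)
    hist: Counter = Counter()
    for m in group.members:
        hist[len(m.alignment.read_seq)] += m.multiplicity
    call.length_histogram = dict(sorted(hist.items()))
    return call


def morna_stats(
    calls: Iterable[MoRNACall], cfg: PipelineConfig, library: Optional[str] = None
) -> dict:
    """Arm-wise length distributions over calls passing the size filters.

    A call enters the histogram when its raw count is at least
    ``cfg.sizedist_min_reads`` and its RPM at least ``cfg.sizedist_min_rpm``
    in the given library (any library when ``library`` is None).  Member
    read lengths are pooled with their multiplicities.
    """
    hists = {"5p": Counter(), "3p": Counter()}
    for call in calls:
        libs = [library] if library else list(call.raw_count)
        ok = any(
            call.raw_count.get(lib, 0) >= cfg.sizedist_min_reads
            and call.rpm.get(lib, 0.0) >= cfg.sizedist_min_rpm
            for lib in libs
        )
        if ok:
            hists[call.arm].update(call.length_histogram)
    return {arm: dict(sorted(h.items())) for arm, h in hists.items()}


def length_mode(hist: Mapping[int, int]) -> Optional[int]:
    if not hist:
        return None
    return max(sorted(hist), key=lambda k: hist[k])


def mir_mor_correlation(
    mir_rpm: Mapping, mor_rpm: Mapping, cfg: PipelineConfig
) -> tuple:
    """Spearman correlation between miRNA and moRNA expression per arm.

    Pairs share a (hairpin, arm) key; pairs where either RPM is at or
    below ``cfg.corr_min_rpm`` are excluded.  Returns ``(rho, n_pairs)``;
    rho is None with fewer than 3 surviving pairs.
    """
    keys = sorted(set(mir_rpm) & set(mor_rpm))
    pairs = [
        (mir_rpm[k], mor_rpm[k])
        for k in keys
        if mir_rpm[k] > cfg.corr_min_rpm and mor_rpm[k] > cfg.corr_min_rpm
    ]
    if len(pairs) < 3:
        return None, len(pairs)
    x, y = zip(*pairs)
    rho = _scistats.spearmanr(x, y).statistic
    return float(rho), len(pairs)


def export_count_matrix(
    counts: pd.DataFrame, rpm: pd.DataFrame, cfg: PipelineConfig
) -> pd.DataFrame:
    """Raw-count matrix restricted to features expressed at >=1 RPM somewhere.

    Feeds an external differential-expression tool; row order is stable
    (input order preserved).
    """
    keep = (rpm >= cfg.de_min_rpm).any(axis=1)
    return counts.loc[keep]


def calls_to_frame(calls: Iterable[MoRNACall]) -> pd.DataFrame:
    """Long-format export of calls (one row per call)."""
    rows = []
    for c in calls:
        row = {
            "name": c.name,
            "hairpin": c.hairpin_name,
            "arm": c.arm,
            "chrom": c.ref_locus.chrom,
            "start": c.ref_locus.start,
            "end": c.ref_locus.end,
            "strand": c.ref_locus.strand,
            "ref_seq": c.ref_seq,
            "n_unique_isomors": c.n_unique_isomors,
            "five_prime_consistency": c.five_prime_consistency,
        }
        for lib, v in c.raw_count.items():
            row[f"count_{lib}"] = v
        for lib, v in c.rpm.items():
            row[f"rpm_{lib}"] = round(v, 3)
        rows.append(row)
    return pd.DataFrame(rows)
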