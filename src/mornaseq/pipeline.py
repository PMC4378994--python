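"""End-to-end orchestration: clean reads -> alignment -> annotation ->
mature counting -> moRNA calling -> descriptive statistics.

The pipeline object is built once from a reference bundle (genome, hairpin
annotations, cascade class references) and then run over one or more
libraries; the result object carries every intermediate table the
downstream analyses need.
"""

from __future__ import annotations

from collections import Counter, OrderedDict, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .align_annotate import (
    Alignment,
    UngappedAligner,
    annotate_cascade,
    count_mature_mirna,
    rpm_normalize,
)
from .morna_caller import (
    IsoMember,
    LibraryStats,
    MoRNACall,
    collect_offset_reads,
    group_isoforms,
    morna_stats,
    quantify_morna,
)
from .novel_mirna import ConservationTrack, call_minor_arm, conservation_class
from .preprocess import SmallRead, preprocess_library
from .refmodel import (
    ExtendedHairpin,
    HairpinRecord,
    PipelineConfig,
    build_extended_hairpin,
)


@dataclass
class ReferenceBundle:
    """Everything the pipeline aligns and annotates against."""

    genome: Mapping[str, str]
    hairpins: list
    class_refs: "OrderedDict[str, Mapping[str, str]]"
    conservation: Optional[ConservationTrack] = None


@dataclass
class PipelineResult:
    """All per-library and pooled outputs of one pipeline run."""

    cfg: PipelineConfig
    summaries: dict = field(default_factory=dict)  # lib -> PreprocessSummary
    class_counts: dict = field(default_factory=dict)  # lib -> Counter(label)
    library_stats: dict = field(default_factory=dict)  # lib -> LibraryStats
    mature_counts: Optional[pd.DataFrame] = None
    mature_rpm: Optional[pd.DataFrame] = None
    morna_calls: list = field(default_factory=list)
    minor_arm_candidates: list = field(default_factory=list)
    mapping_totals: dict = field(default_factory=dict)  # lib -> denominator

    def calls_by_key(self) -> dict:
        return {(c.hairpin_name, c.arm): c for c in self.morna_calls}

    def length_distributions(self, library: Optional[str] = None) -> dict:
        return morna_stats(self.morna_calls, self.cfg, library)

    def summary(self) -> str:
        lines = ["moRNA pipeline summary", "======================"]
        for lib, s in self.summaries.items():
            st = self.library_stats[lib]
            lines.append(
                f"{lib}: raw {s.n_raw}, clean {s.n_clean}, "
                f"genome-mapped {st.n_genome_mapped}, "
                f"hairpin {st.n_hairpin_mapped}, "
                f"moR-5p {st.n_mor5p}, moR-3p {st.n_mor3p}"
            )
            if st.arm_fraction_5p is not None:
                lines.append(
                    f"    arm fraction 5p: {st.arm_fraction_5p:.2%}"
                )
        n_det = sum(1 for c in self.morna_calls if c.pooled_count() >= 1)
        lines.append(f"moRNA calls: {len(self.morna_calls)} ({n_det} detected)")
        return "\n".join(lines)


class MoRNAPipeline:
    """The full small-RNA analysis over a fixed reference."""

    def __init__(self, reference: ReferenceBundle, cfg: Optional[PipelineConfig] = None):
        self.ref = reference
        self.cfg = cfg or PipelineConfig()
        self.ext_hairpins: list = [
            build_extended_hairpin(hp, self.cfg, len(reference.genome[hp.locus.chrom]))
            for hp in reference.hairpins
        ]
        self._aligner = UngappedAligner(reference.genome, self.cfg.max_mismatches)

    # -- per-library stages -------------------------------------------------

    def _align_unique(self, seq_counts: Mapping[str, int]):
        """Align unique sequences; returns (placements, totals) where
        ``placements`` maps seq -> list[Alignment] (multimapper overflow and
        unaligned sequences are dropped) and ``totals`` holds the mapped-read
        denominators."""
        placements: dict = {}
        n_mapped = n_exact = 0
        for seq in sorted(seq_counts):
            hits = self._aligner.align(seq)
            if not hits:
                continue
            if len(hits) > self.cfg.max_loci:
                continue
            placements[seq] = [Alignment(seq, loc, mm, seq) for loc, mm in hits]
            n_mapped += seq_counts[seq]
            if any(mm == 0 for _, mm in hits):
                n_exact += seq_counts[seq]
        return placements, {"genome": n_mapped, "exact": n_exact}

    def run(
        self,
        libraries: Mapping[str, Iterable[SmallRead]],
        adapter: str,
    ) -> PipelineResult:
        cfg = self.cfg
        res = PipelineResult(cfg=cfg)
        lib_aln_pairs: dict = {}  # lib -> list[(Alignment, mult)]
        lib_candidates: dict = {}  # lib -> {(hairpin, arm): [IsoMember]}

        for lib, reads in libraries.items():
            clean, summary = preprocess_library(reads, adapter, cfg)
            res.summaries[lib] = summary

            seq_counts: Counter = Counter(r.seq for r in clean)
            placements, totals = self._align_unique(seq_counts)
            pairs = [
                (aln, seq_counts[seq])
                for seq in sorted(placements)
                for aln in placements[seq]
            ]
            lib_aln_pairs[lib] = pairs
            res.mapping_totals[lib] = totals[cfg.rpm_denominator]

            labels = annotate_cascade(
                ((seq, seq) for seq in sorted(placements)),
                self.ref.class_refs,
                cfg,
            )
            cc: Counter = Counter()
            for seq, label in labels.items():
                cc[label] += seq_counts[seq]
            res.class_counts[lib] = cc

            cands = collect_offset_reads(
                ((aln, mult) for aln, mult in pairs),
                self.ext_hairpins,
                cfg,
                library=lib,
            )
            lib_candidates[lib] = cands

            stats = LibraryStats(
                library=lib,
                n_raw=summary.n_raw,
                n_clean=summary.n_clean,
                n_genome_mapped=totals["genome"],
                n_exact_mapped=totals["exact"],
                n_hairpin_mapped=cc.get("mirna_hairpin", 0),
            )
            for (hp, arm), members in cands.items():
                mult = sum(m.multiplicity for m in members)
                if arm == "5p":
                    stats.n_mor5p += mult
                else:
                    stats.n_mor3p += mult
            res.library_stats[lib] = stats

        # mature miRNA counting with the +-2 nt extension rule
        res.mature_counts = count_mature_mirna(lib_aln_pairs, self.ref.hairpins, cfg)
        res.mature_rpm = rpm_normalize(res.mature_counts, res.mapping_totals)

        # pooled isoform groups define each moRNA's reference isomoR;
        # quantification is per library against that shared reference
        strands = {hp.name: hp.locus.strand for hp in self.ref.hairpins}
        pooled: dict = defaultdict(list)
        for lib, cands in lib_candidates.items():
            for key, members in cands.items():
                pooled[key].extend(members)
        for (hp_name, arm) in sorted(pooled):
            group = group_isoforms(pooled[(hp_name, arm)], hp_name, arm, strands[hp_name])
            if group is None:
                continue
            per_lib = {
                lib: lib_candidates[lib].get((hp_name, arm), [])
                for lib in libraries
            }
            call = quantify_morna(group, per_lib, cfg, res.mapping_totals)
            res.morna_calls.append(call)

        # minor-arm miRNA candidates from single-mature hairpins
        by_chrom: dict = defaultdict(list)
        for lib, pairs in lib_aln_pairs.items():
            for aln, mult in pairs:
                by_chrom[aln.locus.chrom].append((aln, mult))
        for hp in self.ref.hairpins:
            if hp.n_matures() != 1:
                continue
            cand = call_minor_arm(hp, by_chrom.get(hp.locus.chrom, ()), cfg)
            if cand is not None:
                res.minor_arm_candidates.append(cand)
        return res

    # -- locus-level annotations --------------------------------------------

    def conservation_calls(self, extended: bool = False) -> dict:
        """Conserved flag and mean score per hairpin (or extended hairpin)."""
        if self.ref.conservation is None:
            raise ValueError("reference bundle has no conservation track")
        out = {}
        for eh in self.ext_hairpins:
            iv = eh.extended_locus if extended else eh.hairpin.locus
            out[eh.name] = conservation_class(iv, self.ref.conservation, self.cfg)
        return out
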