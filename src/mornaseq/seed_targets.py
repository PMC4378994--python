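"""7-mer seed target analysis in 3'UTRs and gene-set cross-tabulation.

A gene counts as a putative target of a small RNA when its 3'UTR carries
at least one occurrence of the reverse complement of the RNA's seed
(nucleotides 2-8 from the 5' end).  Genes without an annotated 3'UTR are
excluded from all counts.  ``best_duplex_site`` is a complementarity
maximizer standing in for a thermodynamic site predictor: it reports the
ungapped antiparallel site with the most paired bases (a complementarity
score, not a free energy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO

from .novel_mirna import _pairs
from .refmodel import PipelineConfig, revcomp

GENE_SETS = ("down_both", "down_mir_only", "down_mor_only", "other")


@dataclass(frozen=True)
class GeneRecord:
    gene_name: str
    utr3_seq: Optional[str]  # None when no annotated 3'UTR
    set_membership: str = "other"

    def __post_init__(self):
        if self.set_membership not in GENE_SETS:
            raise ValueError(f"unknown gene set {self.set_membership!r}")


@dataclass
class SeedReport:
    per_gene: pd.DataFrame  # gene, set, miR matches, moR matches
    per_set: pd.DataFrame  # set-level tallies


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def seed7(small_rna: str, cfg: Optional[PipelineConfig] = None) -> str:
    """The 7-mer seed: positions 2-8 (1-based) from the 5' end."""
    lo, hi = cfg.seed_span if cfg is not None else (2, 8)
    seq = _norm(small_rna)
    if len(seq) < hi:
        raise ValueError(f"sequence shorter than {hi} nt has no seed")
    return seq[lo - 1 : hi]


def count_seed_matches(utr: str, seed: str) -> int:
    """Overlapping occurrences of the seed's reverse complement in the UTR."""
    if len(seed) != 7:
        raise ValueError("seed must be 7 nt")
    utr = _norm(utr)
    target = revcomp(_norm(seed))
    n = 0
    pos = utr.find(target)
    while pos != -1:
        n += 1
        pos = utr.find(target, pos + 1)
    return n


def crosstab_gene_sets(
    genes: Iterable[GeneRecord],
    mir_seq: str,
    mor_seq: str,
    cfg: Optional[PipelineConfig] = None,
) -> SeedReport:
    """Per-gene seed-match counts and per-set target tallies.

    A gene is miR-matched (resp. moR-matched) when its 3'UTR has >=1 seed
    match for that RNA; set-level counts also report genes matched by
    both.  Genes lacking a UTR contribute to no tally.
    """
    mir_seed = seed7(mir_seq, cfg)
    mor_seed = seed7(mor_seq, cfg)
    rows = []
    for g in genes:
        if g.utr3_seq is None:
            continue
        rows.append(
            {
                "gene": g.gene_name,
                "set": g.set_membership,
                "mir_seed_matches": count_seed_matches(g.utr3_seq, mir_seed),
                "mor_seed_matches": count_seed_matches(g.utr3_seq, mor_seed),
            }
        )
    per_gene = pd.DataFrame(
        rows, columns=["gene", "set", "mir_seed_matches", "mor_seed_matches"]
    )
    set_rows = []
    for s in GENE_SETS:
        sub = per_gene[per_gene["set"] == s]
        mirhit = sub["mir_seed_matches"] >= 1
        morhit = sub["mor_seed_matches"] >= 1
        set_rows.append(
            {
                "set": s,
                "n_genes_with_utr": len(sub),
                "n_miR_matched": int(mirhit.sum()),
                "n_moR_matched": int(morhit.sum()),
                "n_both_matched": int((mirhit & morhit).sum()),
            }
        )
    return SeedReport(per_gene=per_gene, per_set=pd.DataFrame(set_rows))


@dataclass
class DuplexSite:
    position: int  # 0-based start of the site in the UTR
    paired: int
    schematic: str


def best_duplex_site(
    small_rna: str, utr: str, cfg: Optional[PipelineConfig] = None
) -> DuplexSite:
    """Maximal-complementarity ungapped antiparallel site of an RNA in a UTR.

    Scores Watson-Crick pairs plus (by default) G:U wobble; ties resolve
    to the 5'-most UTR position.  The schematic shows the site 5'->3' on
    top and the small RNA 3'->5' below, '|' marking paired positions.
    """
    rna = _norm(small_rna)
    u = _norm(utr)
    L = len(rna)
    if len(u) < L:
        raise ValueError("UTR shorter than the small RNA")
    wobble = cfg.wobble_pairs if cfg is not None else True
    rna_rev = rna[::-1]  # 3'->5' against the site read 5'->3'
    best_pos, best_score = 0, -1
    for j in range(len(u) - L + 1):
        site = u[j : j + L]
        score = sum(_pairs(site[i], rna_rev[i], wobble) for i in range(L))
        if score > best_score:
            best_pos, best_score = j, score
    site = u[best_pos : best_pos + L]
    marks = "".join(
        "|" if _pairs(site[i], rna_rev[i], wobble) else " " for i in range(L)
    )
    schematic = (
        f"utr 5' {site} 3' (pos {best_pos})\n"
        f"       {marks}\n"
        f"rna 3' {rna_rev} 5'"
    )
    return DuplexSite(position=best_pos, paired=best_score, schematic=schematic)


def read_utr_fasta(source) -> dict:
    """3'UTR FASTA keyed by gene name (record id)."""
    return {rec.id: _norm(str(rec.seq)) for rec in SeqIO.parse(source, "fasta")}


def read_gene_sets(source) -> dict:
    """Gene-set TSV (gene <tab> set label [<tab> fold change]) -> mapping."""
    df = pd.read_csv(source, sep="\t", header=None, comment="#")
    return dict(zip(df[0].astype(str), df[1].astype(str)))


def build_gene_records(
    utrs: Mapping[str, str], sets: Mapping[str, str]
) -> list:
    """Join UTR sequences and set labels into GeneRecords (all genes kept)."""
    genes = sorted(set(utrs) | set(sets))
    return [
        GeneRecord(g, utrs.get(g), sets.get(g, "other")) for g in genes
    ]
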