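# mornaseq

Discovery and quantification of **microRNA-offset RNAs (moRNAs)** from
small RNA-seq reads.

moRNAs are ~20 nt RNAs that map immediately adjacent to miRNA precursor
(pre-miRNA) hairpins, 5' (moR-5p) or 3' (moR-3p) of the hairpin, and are
thought to arise as by-products of Drosha/DGCR8 cleavage. They are
expressed as families of overlapping length variants (*isomoRs*), show a
strong arm bias, and — for 3p moRNAs — keep highly consistent 5' ends.
`mornaseq` is for small-RNA bioinformaticians who want a tested,
reusable implementation of the classic moRNA discovery workflow:

1. **Preprocess** raw FASTQ reads: drop reads with mean Phred < Q20, trim
   low-quality 3' ends, remove the 3' adapter (minimum 5 nt overlap, at
   most one mismatch per 7 adapter bases), discard adapter dimers,
   homopolymers and inserts < 14 nt.
2. **Align** end-to-end and ungapped to the genome, allowing at most 2
   mismatches and at most 10 placements per read (multimapper overflow is
   discarded), on both strands. The aligner is exhaustive — it provably
   reports the same placement set as an all-offsets Hamming scan.
3. **Annotate** reads through a first-match-wins ncRNA cascade
   (miRNA hairpins at ≤2 mismatches, then snRNA / snoRNA / rRNA /
   mt-tRNA / miscRNA / piRNA / tRNA / repeats at exact match).
4. **Count mature miRNAs**: a read counts for a mature locus when its
   placement lies within the annotated locus extended by ±2 nt, same
   strand; paralogous loci sharing a sequence receive identical counts.
5. **Call moRNAs**: gather strand-concordant reads from the 30 nt flanks
   of each hairpin (reads fully inside the hairpin are excluded; boundary
   spanners are assigned by majority overlap), group isomoRs, take the
   most abundant isomoR as the reference, and quantify each library as
   the reads contained in the reference locus ±2 nt (0 or 2 mismatches,
   a mode switch). Expression is reported as RPM (reads per million
   mapped reads; genome-mapped or exactly-mapped denominator).
6. **Post-analyses**: arm-usage fractions, 5'-end consistency, length
   distributions (calls with ≥5 reads and ≥0.5 RPM), miR–moR Spearman
   correlation (pairs with both RPM > 0.5), count-matrix export for
   differential expression (features ≥1 RPM), novel minor-arm miRNA
   calling (≥10 exact reads on the arm opposite a single known mature,
   ≥14 paired bases within the candidate's first 20 nt against the known
   mature), novel-hairpin post-filters (≥10 exact reads, ≤10 genomic
   copies, GC within 15–90%), and conservation calls (mean per-base
   score > 0.5).

A first-class synthetic-data module generates genomes, hairpin
annotations (miRBase-dialect GFF3), decoy ncRNA classes, conservation
tracks and FASTQ libraries with planted moRNA populations and complete
ground truth, so the whole pipeline is testable without any downloads.

## Worked example

```python
import mornaseq as m

cfg = m.SimConfig(seed=11, library_size=8000, n_hairpins=10, n_planted_mornas=6)
ref = m.simulate_reference(cfg)
reads, truth = m.simulate_library(ref, cfg)

bundle = m.ReferenceBundle(ref.genome, ref.hairpins, ref.class_refs, ref.conservation)
pipe = m.MoRNAPipeline(bundle, m.PipelineConfig())
res = pipe.run({"demo": reads}, cfg.adapter)
print(res.summary())

rep = m.evaluate_recovery(res.morna_calls, truth, m.PipelineConfig())
print(f"recall={rep.recall:.2f} precision={rep.precision:.2f}")
```

prints

```
moRNA pipeline summary
======================
demo: raw 8000, clean 7680, genome-mapped 7680, hairpin 3969, moR-5p 633, moR-3p 458
    arm fraction 5p: 58.02%
moRNA calls: 6 (6 detected)
recall=1.00 precision=1.00
```

Reading the numbers: of 8 000 raw reads, 7 680 survive cleaning and all
of them map to the synthetic genome; 3 969 match hairpin precursors and
1 091 fall in hairpin flanks (633 on the 5' arm — 58% arm bias, as
planted). The pipeline emits one call per planted moRNA; every call's
reference sequence equals the planted modal isomoR (recall 1.0) and no
call appears at a moRNA-free hairpin (precision 1.0). Individual calls
carry per-library counts, RPM, isomoR counts and 5'-end consistency —
note the ~0.97–0.99 consistency of the 3p calls against ~0.4–0.7 for 5p
calls, matching the planted end-variation model.

The same workflow is available from the shell:

```sh
morna simulate --seed 11 --out simdir
morna run --genome simdir/genome.fa --gff simdir/hairpins.gff3 \
    --fastq demo simdir/sim.fastq --class-fasta tRNA simdir/tRNA.fa \
    --conservation simdir/conservation.bedgraph --out results/
```

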