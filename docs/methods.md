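# Methods

## The moRNA model

A miRNA precursor (hairpin) occupying `[S, E)` on one genome strand is
extended by a fixed flank `F = 30` nt on each side. In transcript
orientation the extended locus splits into five regions

    moR-5p | miR-5p | loop | miR-3p | moR-3p

where the moR regions are exactly the flanks measured from the precursor
boundaries. moRNAs are populations of reads in the flanks; mature
miRNAs and their isomiRs live inside the hairpin. All internal
coordinates are 0-based half-open; GFF3 input/output converts from/to
1-based inclusive. On the minus strand the moR-5p region lies at the
higher genome coordinates.

Mature annotations in real data sit strictly inside the precursor, which
leaves slivers of interior sequence that belong to neither a mature
locus nor a single contiguous loop. So that the five regions always
partition the extended locus, each miR region is extended to the
precursor boundary on its outer (flank-facing) side; the exact mature
intervals are kept separately on the hairpin record and are what the
±2 nt mature counter uses. This choice affects only region bookkeeping,
never counting.

## Pipeline stages and their parameters

All thresholds live in `PipelineConfig`; defaults below.

* **Quality filter** — drop reads with arithmetic mean Phred < 20
  (`min_mean_quality`). 3' bases below the same threshold are trimmed.
  The 5' end is never trimmed: for small RNAs it defines the molecule
  boundary, and trimming it would corrupt the isoform-end statistics
  this pipeline exists to measure.
* **Adapter removal** — leftmost occurrence of an adapter prefix with
  overlap ≥ 5 nt (`adapter_min_overlap`) and at most one mismatch per
  7 matched bases (`adapter_mismatch_per`). Zero-length inserts are
  adapter dimers; inserts that are ≥ 90% one nucleotide
  (`homopolymer_frac`) are homopolymer artifacts (a strict 100% rule
  would miss one-error homopolymers); inserts < 14 nt
  (`min_read_len`) are discarded. Inserts longer than the nominal size
  selection are kept — size selection happens on the gel, not in
  software.
* **Alignment** — ungapped, end-to-end, ≤ 2 mismatches
  (`max_mismatches`), ≤ 10 placements (`max_loci`), both strands. N
  bases mismatch every reference base (conservative and deterministic).
  Implementation: pigeonhole seed-and-verify — a read within k
  mismatches of a window must match one of k+1 disjoint segments
  exactly, so exact segment hits enumerate all candidates and a bounded
  Hamming comparison verifies each. Exhaustiveness is tested against a
  brute-force all-offsets scan. Reads are counted at every locus they
  map to, never fractionally: paralogous loci that share one sequence
  (e.g. clustered precursor families) must report identical values.
* **Annotation cascade** — first match wins, in the order: miRNA
  hairpins (≤ 2 mismatches), then snRNA, snoRNA, rRNA, mt-tRNA,
  miscRNA, piRNA, tRNA, repeats (exact containment). Everything else is
  unannotated. The order of the exact-match classes is a convention;
  only the hairpin-first rule affects moRNA results.
* **Mature counting** — a read counts for a mature miRNA iff its
  placement is contained in the mature locus widened by 2 nt per side
  (`locus_extension`), same strand.
* **moRNA calling** — a flank read is a (hairpin, arm) candidate iff it
  lies within the extended locus, is not fully contained in the
  hairpin, is strand-concordant, and overlaps that flank by more bases
  than it overlaps the hairpin. The majority-overlap rule (rather than
  any-overlap exclusion) is deliberate: observed moRNAs overhang the
  mature miRNA by one or two nucleotides, and a strict exclusion would
  reject them. Reads in the shared gap of hairpins closer than 60 nt
  join every eligible hairpin's candidate set. The reference isomoR is
  the candidate sequence with maximal read multiplicity, ties broken by
  longer sequence, then 5'-most start (transcript orientation), then
  lexicographic order — fully deterministic. Per library, the raw count
  is the multiplicity of reads contained in the reference locus ± 2 nt
  with at most `quant_mismatches` mismatches (0 for exact-match
  reporting, 2 for differential-expression-style tables; the relaxed
  mode is provably a superset of the exact mode). RPM divides by the
  library's genome-mapped read total, or by its exactly-mapped total
  (`rpm_denominator`), both ×10⁶.
* **Statistics** — 5'-end consistency is the fraction of a group's read
  multiplicity sharing the modal 5' position (multiplicity-weighted,
  not unique-sequence-weighted; flagged in output). Length histograms
  pool member read lengths of calls with ≥ 5 reads
  (`sizedist_min_reads`) and ≥ 0.5 RPM (`sizedist_min_rpm`). The
  miR–moR Spearman correlation (average ranks for ties, via
  scipy) uses pairs sharing a (hairpin, arm) key with both RPM > 0.5
  (`corr_min_rpm`) and is reported absent below 3 pairs. The exported
  count matrix keeps features reaching ≥ 1 RPM (`de_min_rpm`) in at
  least one library; the negative-binomial test itself is out of scope
  and expected to run in a dedicated DE package.
* **Novel miRNAs** — a minor-arm candidate (precursors with exactly one
  annotated mature) is the modal zero-mismatch read on the opposite
  arm; accepted iff support ≥ 10 (`minor_arm_min_reads`) and ≥ 14
  paired bases (`minor_arm_min_pairs`) within the candidate's first
  20 nt (`minor_arm_window`) against the known mature over all ungapped
  antiparallel registrations. G:U wobble counts as a pair by default
  (`wobble_pairs`; biological duplexes allow it) and is switchable. The
  window is anchored on the candidate — an alternative reading anchors
  it on the duplex; the candidate anchor is implemented and flagged.
  Predicted novel hairpins pass three post-filters: ≥ 10 exact reads on
  the main product (`novel_min_reads`), ≤ 10 genomic copies at ≤ 2
  mismatches (`novel_max_copies`, `novel_copy_mismatches`; an
  exact-copy mode exists), GC within 15–90% (`gc_bounds`). The
  upstream hairpin predictor is out of scope — candidates come from an
  external tool or the simulator.
* **Conservation** — mean per-base score over the locus, conserved iff
  mean > 0.5 (`conservation_threshold`, strict). Missing track
  positions score 0 and are logged. The extended-hairpin call reuses
  the same rule on the flanked interval.
* **Seed targets** — the 7-mer seed is positions 2–8 (1-based) of the
  small RNA (`seed_span`); a gene is a putative target when its 3'UTR
  contains ≥ 1 occurrence of the seed's reverse complement (overlapping
  occurrences all count; set-level tallies only distinguish 0 vs ≥ 1).
  Genes without an annotated UTR enter no tally. U→T normalization on
  input. `best_duplex_site` is a complementarity maximizer (ties to the
  5'-most UTR position) standing in for a thermodynamic site predictor;
  its output is labelled a complementarity score, not a free energy.

## The synthetic-data generator

`SimConfig` defaults define the validation conditions:

* **Reference** — 20 stem-loop precursors (5p arm + loop + reverse
  complement of the 5p arm with 3 mutations, so the arms form a strong
  but imperfect duplex), 22 nt matures at the precursor boundaries,
  40% on the minus strand, embedded in a random genome with ≥ 100 nt
  between extended loci (a clustered mode places pairs < 60 nt apart to
  exercise shared flanks). Two precursors are annotated on one arm only
  and carry a planted 30-read opposite-arm product for the minor-arm
  caller. Decoy ncRNA classes (tRNA, rRNA, snoRNA, snRNA, piRNA) are
  embedded in the genome and exported as class FASTAs. Conservation
  tracks draw per-base scores from a high band (0.55–1.0) for planted
  conserved hairpins and a low band (0.0–0.45) otherwise.
* **Planted moRNAs** — 12 loci on hairpins with both arms annotated;
  per-locus reads 20–400, rescaled so the 5' arm carries 58% of moRNA
  reads (the observed arm bias in pluripotent cells; fibroblast-like
  libraries can be emulated by setting `arm_bias_5p=0.96`).
  moR-5p: reference lengths drawn from a peaked distribution (mode
  19 nt, support 16–26), hairpin-side 3' end fixed (5% of reads
  overhang the hairpin by 1–2 nt), free 5' end varying around the
  reference (55% keep the reference length). moR-3p: reference lengths
  uniform on 16–29, 5' end consistent with probability 0.97 (else ±1–2
  nt), 3' end varying (70% keep the reference length). These mirror
  the field's observations: homogeneous 5p lengths peaking at 19 nt,
  scattered 3p lengths, near-perfect 3p 5'-end consistency.
* **miRNA reads** — arm weights drawn lognormally, isomiR ends
  canonical with probability 0.82 (else ±1–2 nt per end).
* **Library** — 50k reads; 0.1%/base substitution errors; 3' adapter
  appended and reads cut to a 36 nt machine length; two-state quality
  model (good Q38 / bad Q8 — enough to exercise the Q<20 rules without
  modelling real error profiles); planted artifact rates: 2% low
  quality, 1% adapter dimers, 0.5% homopolymers, 0.5% short inserts;
  background: 20% decoy-class reads, 8% reads from intergenic genome.
  Reference and reads use independent RNG streams spawned from the
  master seed, so changing the library size never perturbs the
  reference; identical configuration gives byte-identical files.

Ground truth records every read's origin and error positions, and per
planted moRNA the number of emitted reads that are *compatible* with the
quantification rule (contained in the reference locus ± 2 nt and inside
the 30 nt flank), with and without sequencing errors. Abundance
recovery compares the pipeline's raw count against that compatible-read
count; since truth and pipeline share the RPM denominator, the relative
error is identical on either scale.

**What the generator does not model** — and hence what passing tests do
not establish about real data: realistic Illumina error profiles and
quality gradients, PCR duplication, ligation bias, structured background
in hairpin flanks (intergenic background is drawn away from extended
hairpin loci, so false-call rates under flank-adjacent degradation
products are untested), repeat-dense genomes (multimapping beyond
paralogous hairpins is rare in the synthetic genome), and
secondary-structure-dependent read sampling.

## Validation scenario sizes

Chosen as the package's own desk-scale conditions:

* **Standard scenario** (recall, precision, abundance, 3p 5'-end
  consistency, conservation agreement): the generator defaults above.
* **Arm-bias scenario**: 20k planted moRNA reads in a 26k-read library;
  at that depth the binomial standard error of the arm fraction is
  ~0.004, far inside the ±0.05 acceptance band.
* **Length-distribution scenario**: the 19 nt moR-5p peak is a pooled
  phenomenon — each moRNA has its own reference length, and the
  pooled histogram reflects the length model only across many loci. A
  direct Monte-Carlo of the planted model puts the chance of the
  pooled mode landing off 19 nt at ~12% with 13 5' loci but < 0.5%
  with ~50, so this scenario plants 100 moRNAs over 120 hairpins
  (~50 on the 5' arm) with evened-out per-locus counts (80–120 before
  rescaling to 12k moRNA reads).
* **Aligner oracle**: 200 random 16–26 nt reads (70% genome-derived
  with up to 3 mutations) against a 10 kb random genome, compared
  placement-for-placement with the brute-force scan.
* **Minor-arm grid**: supports 9/10/11 × duplex pair counts 13/14/15,
  using frozen sequence pairs whose pair counts were fixed by an
  independent registration scan.

## Numerical and degenerate-input choices

* Ties in the modal-isomoR and minor-arm selectors are broken
  deterministically (multiplicity, length, 5'-most, lexicographic).
* Fully quality-trimmed reads become zero-length inserts and fall into
  the short-read bucket; empty candidate sets yield no group; fewer
  than 3 correlation pairs yield an absent coefficient rather than a
  number.
* Flank truncation at chromosome edges is silent but flagged on the
  extended hairpin and logged.
* Palindromic reads report placements on both strands, matching the
  brute-force definition.
* Config YAML round-trips tuples as lists; unknown keys are rejected.

## Known limitations

* The aligner targets desk-scale references (tens of kilobases to a few
  megabases); there is no FM-index, gapped alignment, or SAM/BAM
  emission (BED/TSV export only).
* The annotation cascade resolves multi-class exact matches purely by
  order; no evidence weighting.
* Differential expression, GO enrichment and thermodynamic folding are
  intentionally out of scope; the pipeline exports count matrices and
  complementarity scores for external tools.
* 5'-end consistency is multiplicity-weighted; a unique-sequence
  weighting would give different values for highly duplicated groups.
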