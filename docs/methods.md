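# Methods

## Scope and model

`kovalid` validates CRISPR knockouts from alignment files in four steps:

1. **Indel genotyping** (`indel_caller`). Amplicon/Sanger-clone reads aligned
   to the reference are walked via their CIGAR strings; every `I`/`D`
   operation whose reference footprint overlaps a defined target window is
   reported as an indel call. Reference consumption follows the SAM
   convention (`M/=/X` consume reference and query, `D/N` reference only,
   `I/S` query only, `H/P` neither); calls are anchored VCF-style at the base
   before the event. A read is *genotypable* only if its aligned span covers
   the target window plus `min_flank` (default 5 bp) on both sides —
   otherwise a clipped-off indel would silently vote wild type. Per
   individual, genotyped reads are collapsed into an allele table (reads with
   no overlapping indel are WT; multiple indels on one read form one
   composite allele key) and the mosaicism statistic is the mutant-read
   fraction `1 − n_WT/n_total`, undefined (flagged) at zero genotyped reads.

2. **Consequence classification** (`effect_classifier`). Each indel is
   assigned one of three mutually exclusive categories against a transcript
   model, with precedence **SS > LOF > IF**:
   - *SS* when the footprint (for insertions: the anchor base) touches a
     splice window — `intronic_bp` (default 8) bases into the intron and
     `exonic_bp` (default 3) into the exon around every donor/acceptor
     junction, with the canonical 2-bp GT/AG dinucleotides always included.
     The defaults mirror the convention of widely used variant annotators.
   - *LOF* when the net coding-length change is not a multiple of 3
     (frameshift), or a deletion removes more than 50% of the coding
     sequence. `net_frame_shift` is reported as |Δ| mod 3.
   - *IF* otherwise; an indel entirely outside exons and splice windows is
     reported IF with a `noncoding` flag rather than guessed at.
   Composite alleles can be classified from their *net* length change
   (`classify_allele`); per-site summaries count unique indels, deduplicated
   by (position, kind, length, inserted sequence).

3. **Exon retention (PIR)** (`splice_quant`). For an internal exon of
   interest (Eoi), spliced reads are matched against the two flanking
   introns and their fused skip gap. Matching is exact (0 bp tolerance):
   spliced aligners emit annotated junction coordinates, and exactness keeps
   the inclusion/exclusion classes mutually exclusive. A read supports a
   junction only with ≥ `min_anchor` (default 8) aligned bases on each side
   of the gap; a read spanning both Eoi junctions supports both inclusion
   categories. Then

       inclusion = (n_up→Eoi + n_Eoi→down) / 2
       PIR       = 100 · inclusion / (inclusion + exclusion)

   reported as NA when no informative read exists. Counting is per
   alignment record; duplicate-marked, secondary and supplementary records
   are skipped. The upstream/downstream labelling of the flanking exons is
   symmetric in this arithmetic, so the naming convention cannot change a
   result.

4. **Expression floor** (`expression_filter`). CPM uses raw library sizes
   (column sums); a gene passes when CPM ≥ `min_cpm` (default 1) in at least
   `ceil(min_sample_frac · n_samples)` samples (default 0.25). A `strict`
   flag switches to "strictly more than the fraction" for pipelines that
   read the floor that way; the two differ only when the fraction lands on
   an integer. Filtering happens before any between-sample normalisation,
   which belongs to the downstream differential-expression stage.

## Synthetic data: what it emulates, and what it does not

`synthetic_data` fabricates a toy locus (default: 8 exons × 120 bp,
300 bp introns, GT/AG written at intron ends, CDS spanning all exons and
trimmed to a multiple of 3) and two read sets:

- **Mosaic amplicon reads**: each clone read is WT with probability
  `1 − mutant_fraction`, else carries one indel drawn from a configurable
  spectrum at the target site, with the CIGAR constructed to match. The
  default design (8 clones per individual, mutant fraction 0.625) mirrors a
  typical F0 founder-screening depth.
- **Spliced reads**: `skip_fraction` s is the fraction of transcript
  *molecules* lacking the Eoi. Fragments are assigned to isoforms with
  probability proportional to molar fraction × effective isoform length
  (number of valid read start positions), as in real RNA-seq where longer
  transcripts yield more fragments; this length weighting is what makes raw
  junction counts, and hence PIR, converge to the molecular retention
  100·(1−s). Read starts are uniform over the chosen isoform, so junction
  anchors cover the whole 1..read_length−1 range and the 8 bp anchor filter
  is genuinely exercised. Default depth is 4 000 fragments per individual,
  giving roughly 700–800 informative junction reads on the default
  geometry; at that depth the PIR estimate is unbiased with a sampling SD
  of about 1–2 percentage points depending on s.

All generators are deterministic given `SimConfig.seed` (byte-identical
outputs). Not emulated: sequencing errors and base qualities, PCR
duplicates, paired-end insert sizes, mapping ambiguity, and partial or
novel splice junctions. Passing tests therefore demonstrate the counting
and classification logic, not robustness to alignment artefacts in real
libraries.

## Numerical and design choices

- Internal coordinates are 0-based half-open everywhere; GFF3/GTF I/O
  converts from 1-based inclusive exactly once.
- Indels are left-normalised (shifted left while the flanking base matches,
  VCF-style) when the reference sequence is available, so the same physical
  allele yields one key across reads. Target-window membership is judged on
  the *as-aligned* placement before normalisation: normalisation may
  legitimately move the anchor a few bases out of the window while the
  physical edit still hits the site.
- Frame arithmetic uses CDS interval lengths only; GFF3 phase attributes
  are not required.
- `inclusion` may be half-integral (it is an average of two counts); it is
  kept as a float rather than rounded.
- Unmapped, secondary, and supplementary alignments are excluded wherever
  flags are available — one vote per clone, one vote per fragment.
- Exon ordinals are 1-based in transcript orientation, so minus-strand
  transcripts number their exons from the genomic right; all operations
  take an explicit transcript id rather than guessing a canonical isoform.

## Problem sizes used in the shipped checks

The test-suite and `scripts/acceptance.py` run entirely on generated data:
amplicon designs of 8–400 reads, spliced designs of 4 000 fragments per
condition (skip fractions 0, 0.1, 0.5, 0.9), an exhaustive deletion scan
(lengths 1–9 at every position of the toy locus, ~27 000 classifications),
and a 58-sample count matrix with boundary probes at exactly 14 and 15
samples of CPM 1. These sizes keep every check well inside a minute while
leaving the stochastic recoveries statistically meaningful.

## Known limitations

- The PIR stage quantifies a single Eoi per call against exact annotated
  junctions; alternative donors/acceptors, intron retention proper, and
  multi-exon skips other than the immediate-neighbour fusion are out of
  scope.
- The classifier condenses consequences to three categories; it does not
  produce HGVS notation or distinguish start/stop-specific effects.
- Mosaicism is a read-level fraction; with 8 clones per individual its
  confidence interval is wide, and no KO/WT threshold is imposed — the
  fraction is reported and thresholds are left to the caller.
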