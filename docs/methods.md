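# Methods

## Problem and scope

`editscan` identifies G-to-A RNA-editing events — sites where a genomically
encoded G is read as A on the transcript strand — from bulk RNA-seq, and
tests how editing levels change between experimental groups (the motivating
design is a chronic-social-defeat-stress mouse study: control vs stressed
animals, with an emotional-stress and a physical-stress arm, plus a larger
independent reference cohort from the same brain region). The pipeline
deliberately starts at per-sample `samtools mpileup` text: read QC,
alignment, duplicate marking and base-quality recalibration are upstream
concerns, and nothing in the method depends on read-level information
beyond what a pileup records.

## Variant calling

Each pileup record is tokenized into per-observation (base, strand,
quality) triples; indel observations attach to their anchor read. A site
summary counts observations with base quality ≥ `q_min` (default 25,
Phred). A non-reference base allele is called when the quality-filtered
depth is ≥ 10, its supporting depth is ≥ 2, and its allele frequency (AAF)
is ≥ 1%. All three cuts are inclusive. The AAF denominator is the
quality-filtered base depth — the same quantity later reported as the
site's editing level — rather than the raw pileup depth; deletion
placeholders (`*`) and reference skips contribute to raw depth only.
Indels are called under the same thresholds, with deletions anchored at
the base preceding the deleted run (mpileup convention).

A false-positive screen then drops calls with either of the two
pileup-computable signatures of alignment error:

* **strand bias** — all alternative observations on one strand while
  reference observations occur on both, with at least `strand_min_alt`
  (default 4) alternative reads;
* **quality deficit** — mean alternative base quality more than
  `max_qual_deficit` (default 10) below the mean reference base quality.

Read-position and mapping-quality criteria used by BAM-level screens need
information a pileup does not carry; both implemented thresholds are
configurable, and the summary's mean-read-position slot stays `None` until
such tags are available.

## Filter cascade and admission

Candidates are the union of post-screen SNV calls across discovery
samples. Six flags are computed independently of one another, so
evaluation order can never change the surviving set:

1. **repeat_or_homopolymer** — the site lies in the repeat mask, or in /
   immediately abutting (±1 nt, configurable) a single-base run of ≥ 5 nt.
   The adjacency extension exists because substitution artifacts cluster
   at run edges.
2. **mitochondrial** — the contig is mitochondrial (`chrM`/`MT` by default).
3. **near_splice** — within ≤ 6 nt of a splice junction, junctions being
   the internal exon boundaries of multi-exon gene models.
4. **near_indel** — an indel call within ≤ 1 nt in any sample that also
   detected the site.
5. **dbsnp_known** — exact (contig, position, ref, alt) match in the
   known-variant set. Allele identity is required: a known A>C SNP should
   not disqualify a G>A candidate at the same position.
6. **germline_pattern** — more than 90% of callable discovery samples show
   an AAF of exactly 1.00 or within [0.40, 0.60], the signature of a
   homozygous or heterozygous genotype. "Callable" means quality-filtered
   depth ≥ 10; samples without coverage carry no genotype evidence and are
   excluded from the denominator (an all-samples mode is available).

A site present in the known-editing table (REDIportal-style, matched by
position only, since such tables are strand-reported) is *rescued*: all six
flags are voided. Admission then requires the candidate to be genic
(within a gene's exonic span, introns included), to read G-to-A on the
transcript strand (genomic G>A in plus-strand genes, C>T in minus-strand
genes; sites inside overlapping opposite-strand genes are set aside as
strand-ambiguous), and to be either detected in ≥ 2 discovery samples or
replicated in ≥ 1 reference-cohort sample at a level ≥ 1%. Detection is
sample-level (a qualifying post-screen call exists), while flags are
site-level; a site's editing level is recorded in every callable discovery
sample whether or not that sample called it.

Coding consequence is classified by splicing the gene's CDS, substituting
the affected codon (reverse-complemented for minus-strand genes) and
translating with the standard genetic code: missense, synonymous,
stop-gain, stop-lost, 5'/3'UTR by strand-aware position relative to the
CDS, non-coding-exon for CDS-less genes, intron otherwise. One transcript
per gene model; multi-gene overlaps report all genes but attribute the
event to the alphabetically first gene_id for per-gene counting, a
deterministic tie-break.

## Statistics

Editing levels of admitted events form an events × samples matrix with
explicit missingness. Per-event group differences use the classic
pooled-variance Student's t-test, two-sided, significant at p < 0.05 with
no multiple-testing correction by default (a Benjamini–Hochberg option
exists; Welch's test is available by flag). Events with fewer than two
non-missing values in a group are reported untestable. When both groups
are numerically constant the test is degenerate; the implementation
reports p = 1 (t = 0) for equal means and p = 0 otherwise, with a
`degenerate` flag — a documented, deterministic convention for tiny-n
data. Constancy is detected with a relative tolerance of 1e-12 because
the sample variance of identical floats is not exactly zero.

PCA of (a subset of) the matrix imputes missing entries with the
event-wise mean, centers but does not scale, and reports variance
fractions from the singular values. Spearman correlation uses average
ranks for ties and returns NaN for constant vectors.

The multi-event enrichment test crosses differential status (a gene has
≥ 1 significant event) with event count (= 1 vs > 1) in a 2×2 table. The
two-sided Fisher p sums hypergeometric probabilities of all tables with
the observed margins that are no more probable than the observed one,
computed in exact integer arithmetic (`math.comb`) with a single final
division — exact ties therefore behave exactly, with no floating-point
tie tolerance. The association measure is the sample odds ratio
(a·d)/(b·c) with a Woolf log-method interval
exp(ln OR ± z·√(1/a+1/b+1/c+1/d)); any zero cell triggers the
Haldane–Anscombe +0.5 correction, flagged in the output.

Gene expression uses TPM (counts divided by length in kb, scaled to sum to
10⁶ per sample) and the same t-test machinery on log2(TPM+1).

## Synthetic study generator

The generator emulates the study design rather than any particular
dataset: a random genome with ten three-exon genes (300 nt exons, 150 nt
introns, 60 nt UTRs, CDS trimmed to a codon multiple) alternating strands
on `chr1`, one single-exon gene on `chrM`, a 3/3/3 control/ES/PS discovery
design and a configurable reference cohort (dataclass default 44,
matching the reference dataset it emulates; tests and the acceptance run
use 8 so the admission logic — which is size-agnostic — is exercised at
desk scale). Depth is negative-binomial (mean 50, dispersion 8), edited
reads binomial in the group's true level, base-call errors uniform over
the other three bases at 0.1%, qualities normal(35, 4) clipped to [2, 40],
strands fair except at strand-biased artifacts.

Planted features and their rationale:

* **Editing sites** are always transcript-strand G-to-A, planted on both
  strands so complementation is exercised. Differential sites sit at
  0.10 → 0.30 (Δ = 0.20) in both stress arms. Non-differential site levels
  are drawn U(0.02, 0.35) when unlisted and U(0.02, 0.90) when listed as
  known editing. The upper bound for unlisted sites stays below the
  heterozygote band deliberately: with near-constant levels across
  samples, a site at ~0.5 is *by design of filter 6* indistinguishable
  from a het SNP, and real editing-level distributions are skewed low;
  listed sites probe the full range because rescue voids the band filter.
* **Germline SNPs** (het at 0.5, hom at 1.0, identical genotype in all
  samples) are planted as transcript-strand G-to-A so that removal is a
  real test, and all of them are in the known-variant VCF, so the dbSNP
  flag guarantees removal; the band filter is their second, statistical
  line of defence. At 50× depth the band captures a het sample with
  probability ≈ 0.88, so the band criterion alone (which needs >90% of
  samples in band) is only near-certain in deep-coverage data — the
  band-only property is therefore tested at 200× where it holds, and the
  pipeline-level guarantee rests on the exact-match flag.
* **Artifacts**: homopolymer-adjacent sites (next to a written 5-nt run,
  with strand-biased alternative reads, so either the false-positive
  screen or flag 1 catches them), near-junction sites (≤ 6 nt from a
  junction, strand-balanced so flag 3 — not the screen — must catch
  them), and mitochondrial sites inside the `chrM` gene.

All randomness flows from one integer seed; identical configurations
produce byte-identical files. The generator writes FASTA/GTF/BED/VCF/TSV
plus per-sample pileups, a sample sheet, a counts table and a JSON
manifest.

What the generator does **not** model: read-level effects (soft-clipping,
duplicates, mapping ambiguity), sample-to-sample level variability beyond
binomial noise, linked sites, expression-coupled coverage, or real repeat
structure (the mask is synthetic intervals). Passing recovery tests
therefore demonstrates that the pipeline's logic is correct under its own
stated model, not that the thresholds are optimal for any real library
preparation.

## Problem sizes and numerical choices

The default synthetic study (17 samples × ~12,500 genic positions,
60 editing sites, 30 SNPs, 12 artifacts) runs the full pipeline in under
ten seconds; the exhaustive Fisher validation sweeps every 2×2 table with
N ≤ 60 (~6×10⁵ tables) against an independent integer-recurrence
enumeration. Band membership in filter 6 uses a 1e-9 absolute tolerance so
that levels computed as count ratios compare exactly at the printed
boundaries (0.40, 0.60, 1.00). Interval indexes are `intervaltree`-based;
all public coordinates are 1-based closed (VCF/GTF/pileup convention) and
BED input is converted on load.

## Known limitations

* Only the G-to-A admission mode is wired, although the calling and
  cascade machinery is substitution-agnostic.
* One transcript per gene; no splice-region or NMD annotation.
* The false-positive screen is a two-rule approximation of read-level
  screens, as discussed above.
* Published confidence intervals for this kind of 2×2 table are sometimes
  computed by other methods; the Woolf interval reproduces the odds ratios
  themselves but can differ in the last digit of the bounds.
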