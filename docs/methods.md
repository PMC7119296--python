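# Methods

This note documents the models and procedures `synreg` implements, the
conventions and parameter choices that matter, what the synthetic
generator does and does not emulate, and the package's known
limitations.

## Cohort model and stratification

The unit of analysis is a somatic synonymous single-nucleotide variant
with a precomputed pathogenicity score in [0, 1] (FATHMM-style) and a
sample-recurrence count. Classification uses strict inequalities:

* **pathogenic** — score > 0.7 *and* observed in ≥ 2 distinct samples;
* **neutral** — score < 0.5 *and* observed in exactly 1 sample;
* **excluded** — everything else, including unscored records and scores
  exactly at a threshold.

The recurrence filters trade size for reliability: requiring ≥ 2
samples suppresses pathogenic false positives; requiring exactly 1
keeps the neutral set conservative. Sample recurrence is counted per
unique (chromosome, position, ref, alt) record. The substitution
spectrum is tabulated over the 12 ordered base changes on the genomic
plus strand by default (the convention under which UV-exposed melanoma
cohorts show the characteristic C→T/G→A excess); a switch counts on
the coding strand instead.

### Coordinates and strand

Mutation tables are 1-based (COSMIC/VCF convention); interval tracks
and exon models are 0-based half-open (BED convention); conversion
happens exactly once at the I/O boundary. Alleles, sequence contexts
and CDS sequences are stored in coding-strand orientation because motif
scanning is defined on the mRNA sense sequence; VCF REF/ALT (plus
strand) are converted at load. Each mutation carries a context of
2W + 1 bases centred on the variant; the default W = 10 covers both the
6-bp and 7-bp scan windows. Contexts truncated at CDS ends are padded
with `N`, and windows containing non-ACGT characters are omitted rather
than fabricated; a mutation whose every window is lost is flagged
scan-ineligible, not dropped. Per gene, only the transcript with the
longest CDS is analysed; ties break on the lexicographically smallest
transcript id (deterministic).

## Splice-regulation annotation

The distance to the nearest splice site counts exonic bases with the
intron-adjacent base at distance 1, over internal exon/intron
boundaries only — transcript termini are not splice sites, and
single-exon transcripts have no distance. A mutation within 30 bp
(default, configurable) is *near-splice*.

ESE/ESS hexamer sets are loaded from plain-text lists (U→T and case
normalised) and combined by set union, mirroring the construction of a
402-ESE / 316-ESS reference from two resources each. For each allele,
the k = 6 windows covering the mutated base (start offsets −5 … 0) are
looked up in both sets; a membership difference in any window raises
the corresponding event (ESE gain/loss, ESS gain/loss — several can
co-occur). This windowed scan is provably equivalent to diffing the
positioned motif occurrences that overlap the variant between the full
reference and alternate sequences, and the test suite enforces that
equivalence against an independent brute-force oracle. The
enrichment-relevant composite feature is *ESR change at a near-splice
mutation* (the mutation's own distance is what is thresholded).

## miRNA target sites

Seeds follow the A-anchor rule: when the first base of the mature
miRNA is adenine, positions 2–7 form a 6-nt seed whose complementary
site is followed by a target-side adenine; otherwise positions 2–8 form
a 7-nt seed. The mRNA-side target motif is the reverse complement of
the seed in DNA alphabet, always 7 nt (the anchored case appends the
A). Scanning reuses the window machinery with k = 7 and exact matching
(no G:U wobble), recording gains, losses and the contributing miRNA
ids. A `direct` mode matches the seed itself on the sense strand
instead of its reverse complement; the canonical target-site definition
is the default because the anchor rationale presupposes a complementary
site. Coding-sequence scanning is used throughout (all studied
mutations are exonic).

## Codon optimality, chromatin, intolerance, conservation

Reference and alternate codons are read directly from the CDS at frame
(cds_pos − 1) mod 3, with a consistency check that the CDS base matches
the reference allele; replacing a designated optimal codon with a
non-optimal synonym is an *optimal loss* (the mechanism feature), the
reverse an optimal gain. The packaged
`data/optimal_codons_synthetic.tsv` is a synthetic illustrative default
(one commonly preferred codon per degenerate family) so the pipeline
runs out of the box; real analyses should supply their own table, and
every test generates its own.

DHS/TF overlap is strict containment of the mutated base in a track
interval — proximity never counts. DHS peak intervals are the intended
input; footprint intervals can simply be included in the BED if
desired. RVIS percentiles flag genes in the top 25 % most intolerant
(percentile < 25, configurable); mutations in genes without an RVIS
entry carry an absent flag and are excluded from that comparison rather
than counted either way. phyloP conservation scores attach per site and
feed a one-sided rank-sum comparison (exact for small samples without
ties, tie-corrected normal approximation otherwise); the package makes
no claim about which rank test the original analyses of this kind used.

## Enrichment statistics

Each mechanism feature yields a 2×2 table (feature ± × pathogenic/
neutral). The two-sided Fisher p sums hypergeometric point
probabilities no larger than the observed table's — the common
exact-test convention, stated here because the doubling convention
differs. The odds ratio is the sample OR (a·d)/(b·c), reported as
infinite when b·c = 0 with a·d > 0 and always accompanied by a
Haldane–Anscombe-corrected companion (+0.5 to every cell). Exact 95 %
confidence intervals come from the conditional (noncentral
hypergeometric) distribution. Distance-binned enrichment defaults to
bins [1–30], [31–70], [≥ 71] bp (configurable); degenerate bins report
an absent result instead of a fabricated p. Over-representation of a
gene list against named sets uses the hypergeometric upper tail with
Benjamini–Hochberg adjustment; terms with ≤ 5 hits in the query are
removed by default (`min_hits = 6`), a filter the caller can relax.

## Functional flag and gene recurrence

A mutation is *potentially functional* iff it is pathogenic and shows
at least one of: ESR change at a near-splice position, DHS containment,
or optimal-codon loss. Per gene, the observed functional count k is
scored with the Poisson **point** probability P(X=k) = λ^k e^{−λ}/k!
at λ = 2·R·S (R: per-gene background rate per sample per allele copy;
S: samples, default 341; the factor 2 counts both allele copies). The
point probability — not the tail — is the statistic, confirmed by exact
reproduction of the published per-gene values from their printed (k, λ)
pairs; a tail option P(X ≥ k) exists but is off by default. Evaluation
is in log space with a log-gamma routine for ln k! (naive factorials
overflow at k ≈ 171). Genes with P below 10⁻⁶ are called recurrent; a
genome-wide threshold of 2.74 × 10⁻⁶ is available by flag, and the
p-values are deliberately not adjusted for multiple comparisons. R is
treated as a per-gene aggregate rate (so λ is the per-gene expected
count); gene length is reported in CDS nucleotides. Genes carrying
functional mutations but lacking a rate entry are reported in a side
table with an absent p rather than silently dropped.

## Synthetic data generator

The generator emulates the statistical structure of a melanoma
synonymous-mutation cohort, not its biology:

* multi-exon genes (default 60 genes, 2–8 exons of ≥ 60 nt, CDS 0.9–6
  kb, introns 0.2–2 kb, random strand, one chromosome per gene), with
  CDS sequences drawn from sense codons (ATG start, no internal stops);
  exon boundaries are codon-aligned for construction simplicity;
* candidate mutations enumerated from the degenerate codon positions of
  the generated CDS, so synonymy holds by construction and every
  emitted record re-translates identically;
* a substitution-type 12-vector (default: C→T and G→A at 0.38 each,
  emulating the UV signature); per-class type counts are drawn
  multinomially from it, making the realized spectrum exact up to
  sampling noise;
* a two-population score mixture (pathogenic mass strictly above 0.7,
  neutral strictly below 0.5, Beta-shaped), sample counts of 1 for
  neutral and 2 + Poisson(0.7) for pathogenic;
* ESE/ESS sets sampled without replacement from the 4096 hexamers
  (defaults 402/316), random 22-nt miRNAs (default 50), DHS/TF tracks
  covering a configurable fraction of exonic bases to the base
  (defaults 15 %/10 %), per-gene rates R proportional to CDS length
  (default 5 × 10⁻⁹ per nt per sample per allele copy, giving λ values
  of order 10⁻²–10⁻³ at S = 341, the magnitude real per-gene tables
  show);
* **planted effects**: within each substitution type, pathogenic
  mutations sample candidate sites with their weight multiplied by a
  configurable odds multiplier for every mechanism feature the site
  carries, while neutral mutations sample from the baseline — so the
  population odds ratio of each feature equals its multiplier (up to
  negligible non-collapsibility across types) and enrichment-parameter
  recovery is a closed loop. Per-gene rate boosts multiply a gene's
  sampling weight in both classes. phyloP scores are N(0, 1) with a
  +0.5 shift at sites with a miRNA-site change, so the conservation
  comparison has signal.

One root seed feeds named substreams (genome, motifs, mirna, tracks,
rates, codon; sites and scores per cohort); identical (config, seed)
pairs emit byte-identical files. A preset reproduces the study scale:
S = 341, exactly 1,080 pathogenic + 4,953 neutral mutations,
multipliers (1.76, 1.5, 1.3) for the three mechanisms, one gene boosted
ten-fold.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: real genome sequence and its motif
composition biases, mutational-signature structure beyond the 12-type
vector, inter-sample correlation, transcript isoform complexity,
3'UTR-specific miRNA biology, and any dependence between pathogenicity
scores and sequence context. Passing recovery tests demonstrate that
the *estimators* are unbiased and calibrated at the study's sample
sizes, not that the biological effects exist.

## Numerical and design choices

* Fisher tests, rank-sum tests, hypergeometric tails and B–H
  adjustment are delegated to scipy/statsmodels; the test suite checks
  the Fisher path against an exhaustive integer-arithmetic enumeration
  of every table with row sums ≤ 30, and the Poisson statistic against
  exact rational arithmetic and an independent pmf implementation.
* Window scans omit (never pad) windows that leave the context, and
  every call is oracle-checked against full-sequence occurrence diffs
  on random fixtures.
* Problem sizes in the recovery tests match the study scale (cohorts of
  6,033; 100 replicates for CI coverage, 200 for null uniformity and
  recurrence recovery), with one reference reused across cohort draws
  since the cohort is the replicate unit.
* Degenerate inputs are surfaced, not patched: empty margins raise,
  degenerate bins report absent results, missing scores/rates flow to
  explicit "absent" states.

## Limitations

* FATHMM scoring, splicing-efficiency prediction (SPANR-like), RNA
  secondary-structure prediction and the DAVID annotation service are
  out of scope; their outputs enter as precomputed columns and
  pass through the same enrichment machinery.
* No liftover, indels, multi-allelic records, or transcript inference
  beyond exon/CDS extraction from BED12/GFF3.
* The recurrence model is a plain Poisson with a user-supplied per-gene
  rate; no covariate-adjusted background (expression, replication
  timing, trinucleotide context) is fitted.
* Exact reproduction of cohort-level counts from the original study
  (total mutation counts, class sizes from real data, GO p-values)
  depends on external database versions and is intentionally not a
  target; the study-scale preset mirrors those conditions
  qualitatively.
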