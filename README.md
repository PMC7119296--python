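# synreg

Regulatory annotation and recurrence analysis of somatic **synonymous**
mutations.

Synonymous (silent) substitutions do not change the encoded protein, yet
they can drive disease by disrupting the regulatory information carried
by the coding sequence itself: exonic splicing enhancers and silencers
(ESE/ESS hexamers) near splice sites, miRNA target sites, codon
optimality, and open-chromatin (DNase-I-hypersensitive, DHS) or
transcription-factor-bound regions. `synreg` implements the full
analysis a cancer-genomics study of such mutations needs, for cohorts
like TCGA melanoma:

1. **Stratify** mutations by a FATHMM-style pathogenicity score:
   pathogenic (score > 0.7, recurrent in ≥ 2 samples) vs neutral
   (score < 0.5, exactly 1 sample), plus the 12-type substitution
   spectrum.
2. **Annotate** five regulatory mechanisms per mutation: distance to
   the nearest splice site with ESE/ESS gain–loss scanning in the six
   6-bp windows covering the mutated base; miRNA target-site gain/loss
   in the seven 7-bp windows (seed = positions 2–7 with an A anchor, or
   2–8); codon-optimality change; DHS and TF interval overlap; RVIS
   gene-intolerance and phyloP conservation attachment.
3. **Test enrichment** of each mechanism in pathogenic vs neutral
   mutations with two-sided Fisher exact tests and odds ratios
   (OR = a·d / b·c), distance-binned enrichment and cumulative distance
   curves, a rank-sum conservation comparison, and hypergeometric
   over-representation with Benjamini–Hochberg adjustment.
4. **Score per-gene recurrence** of *potentially functional* mutations
   (pathogenic with near-splice ESR change, DHS overlap, or optimal-codon
   loss) with the Poisson point probability

   $$P(X=k) = \frac{\lambda^k}{k!}\,e^{-\lambda},\qquad \lambda = 2RS,$$

   where *R* is the gene's background synonymous mutation rate per
   sample per allele copy and *S* the number of samples; genes with
   *P* < 10⁻⁶ are called recurrent (no multiplicity adjustment).
5. **Simulate**: a synthetic-cohort generator with planted effect sizes
   (odds multipliers per mechanism, per-gene rate boosts, configurable
   substitution spectrum and DHS coverage) makes every stage testable
   offline and turns parameter recovery into a closed loop.

## Worked example

Generate a study-scale cohort (1,080 pathogenic + 4,953 neutral
mutations) with the near-splice-ESR odds multiplied by 1.76 in the
pathogenic class, annotate it and test enrichment
(`examples/enrichment_analysis.py`):

```text
        feature   a   b    c    d  odds_ratio  odds_ratio_corrected      p
    near_splice 106 974  328 4625      1.5346                1.5388 0.0004
esr_near_splice  96 984  288 4665      1.5803                1.5851 0.0003
   optimal_loss 344 736 1624 3329      0.9581                0.9587 0.5667
         in_dhs 160 920  787 4166      0.9206                0.9225 0.4060
```

Each row is the 2×2 table (a/b: feature present/absent in pathogenic,
c/d: in neutral) with the sample odds ratio, its Haldane–Anscombe
companion, and the two-sided Fisher p. The planted `esr_near_splice`
effect is recovered (OR 1.58 in this draw, exact 95 % CI covering the
true 1.76), while unplanted mechanisms sit near OR = 1. The published
near-splice contingency (310/1,080 vs 921/4,953) gives

```text
OR = 1.76,  p = 5.885e-13
```

and the published per-gene recurrence inputs reproduce their point
probabilities, e.g. k = 13 with λ = 0.037106647 → P = 3.913 × 10⁻²⁹
(`examples/gene_recurrence.py`). The other examples cover stratification
and the substitution spectrum, single-mutation splice/ESR annotation,
miRNA seeds and target-site scanning, and the end-to-end file pipeline.

## Layout

- `src/synreg/` — library: `model`/`io` (types, formats), `stratify`,
  `splice`, `mirna`, `features`, `annotate`, `stats`, `recurrence`,
  `simulate`, `pipeline`, `cli`
- `examples/` — one short narrative script per capability
- `docs/methods.md` — models, conventions, parameter choices and
  limitations
- `tests/` — pytest suite (unit, property-based and acceptance tests)
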