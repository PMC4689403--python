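# Methods

## Gene model

A gene is represented as a single locus sequence plus a set of exons shared
between transcripts, per-transcript CDS bounds, genomic band intervals
(Z/I/A/M), and a PSI value per exon. All file coordinates are 1-based
inclusive; the same convention is used in memory, and JSON+FASTA bundles
round-trip byte-identically.

Design choices where the design was genuinely open:

* **Bespoke JSON bundle, not GFF3.** PSI values and sarcomere band intervals
  have no standard home in GFF3; a self-contained JSON schema (exons,
  transcripts, bands, psi, sidecar FASTA) keeps desk-scale models portable.
* **Bands are genomic intervals, not residue ranges.** Truncations are
  assigned to bands by genomic position, which makes the banding of intronic
  (splice) variants well defined without residue arithmetic. Band intervals
  must tile the CDS span of the longest transcript exactly.
* **Transcripts are fully coding between `cds_start` and `cds_end`**
  (titin-like); UTR modelling is out of scope. An exon outside the coding
  span (the synthetic novex-like terminal exon) yields `noncoding` calls.
* **"All transcripts" means every transcript listed in the model file.**
  Which isoforms belong in that set is the model author's decision. The
  synthetic gene therefore gives the novex-like transcript all main exons
  plus its unique terminal exon outside the coding span: a truncated
  novex-like isoform would make every downstream exon "isoform-specific" and
  the transcript filter would remove nearly everything, which is not how the
  filter is meant to behave. Isoform-specific main exons instead come from a
  separate "short" transcript that skips designated exons.
* **`psi_threshold` defaults to 0.15** (configurable). Low-PSI
  classification takes precedence over isoform-specificity.

## Consequence calling

Variants are classified on a designated reference transcript — the longest
CDS, configurable — with severity precedence nonsense > frameshift >
essential_splice > splice_region > inframe_indel > missense > synonymous >
intronic > noncoding. If the reference transcript yields no coding or splice
context (the variant lies in an exon it does not contain), the most severe
per-transcript call wins. Splice distances are signed in transcription order:
+d into the intron past a donor, −d before an acceptor; 1–2 bp is essential,
3–6 bp splice region, deeper is plain intronic. An indel overlapping an
exon/intron boundary is classified by its exonic portion if any changed base
is exonic, otherwise by the splice distance of its leftmost changed base.
Stop-loss and start-loss fold into the missense bucket (not analysed
further). Truncating (TTNtv) = {nonsense, frameshift, essential_splice}.

Allele normalisation is the standard minimal-representation rule (trim shared
suffix, extend left when an allele empties, trim shared prefix), implemented
in-package because no installed library exposes an in-memory primitive for
it; tests check idempotence, haplotype preservation, and agreement with an
exhaustive enumeration of equivalent representations.

## Filtering workflow

Stage order: quality → normalise/annotate → truncating → transcript →
concordance → coverage. Each stage emits a trace (n in, n out, removed keys),
so removed-variant accounting is exact and the pipeline is auditable.
Numerical/policy choices:

* `min_mean_depth` defaults to 15×. A coverage threshold is required but its
  value is a judgment call; 15× is a conservative floor for site-level
  calls, and the value is configurable.
* The concordance stage removes subset-unique variants outright (a
  `flag_only` mode retains them for sensitivity analysis). Variants shared by
  two subset call sets are kept whatever the superset contains, and the
  overlap is reported.
* Calls at positions missing from the coverage table are flagged
  "uncovered" and removed rather than silently kept.
* Variants are counted once per variant, not once per transcript hit.

## Statistics

* **Carriers**: k = Σ(AC − hom) over qualifying variants; heterozygotes and
  homozygotes each count once. Compound carriers of two distinct variants are
  ignored; at the allele frequencies involved the overcount is below
  k²/(2n).
* **Prevalence**: 100·k/n percent; confidence intervals are Wilson score
  (default) or Clopper–Pearson exact via statsmodels, at 95 % unless
  configured. The two methods are not strictly nested bound-by-bound;
  Clopper–Pearson is at least as wide away from the boundary.
* **One-in-N**: round(100/prevalence%); display rounding (nearest 50) is a
  formatting option and never applied to stored values.
* **Group tests**: chi-square homogeneity on the carriers × group table for
  multi-group comparisons; Fisher's exact (default) for 2×2 pairwise
  comparisons, because expected cells are small at desk scale. No
  multiple-testing correction anywhere; all p-values are nominal.
* **Codon-position bias**: chi-square goodness of fit of nonsense counts per
  codon position against a uniform null (default) or an opportunity-weighted
  null (9/23, 7/23, 7/23 — the number of stop-gain patterns available per
  position).
* **CpG hotspots**: a transition is a CpG-deamination event iff C→T with G
  following, or G→A with C preceding, on the coding strand. Context is taken
  from the spliced CDS by default (cross-exon codon neighbours are the
  spliced neighbours); a `genomic` mode uses the unspliced locus.
* **Allele-frequency classes**: private = dataset-wide singleton (AC = 1);
  low-frequency = AF < 0.5 % (the conventional boundary); common otherwise.
  Both thresholds are configurable and recorded in results.
* **Hardy–Weinberg het:hom ratio**: 2(1−q)/q with q = √(h/n) when derived
  from an observed homozygote count. For one homozygote in 60 706 individuals
  this gives ≈ 491 heterozygotes per homozygote.

## Synthetic data

The generator's defaults are the study conditions: a 40-exon gene (50-codon
exons on average, every exon length a multiple of three so each exon
contributes whole codons in every transcript), three transcripts (full, a
short one skipping every third internal exon, a novex-like one with a unique
terminal exon), band fractions 5/45/40/10 % of the CDS span, PSI values of
1.0 with a low-PSI minority below 0.15, four populations of 5 000 individuals
with carrier-rate multipliers (AFR 1.3, EUR 0.8, EAS 1.0, SAS 1.5), a
singleton fraction of 0.6 with a 5 % common tail, 95 % PASS rate, mean depth
60× with 10 % of positions below the 15× filter, one superset and two subset
datasets with planted subset-only false positives.

Variants are *planted*, not mutated at random: candidate sites are chosen so
the intended class is guaranteed (stop-gain codons for nonsense, interior
1–2 bp deletions for frameshift — re-normalised and rejected if left-alignment
escapes the exon interior —, exact intron distances for splice classes), so
truth labels are exact by construction and independent of the classifier
under test. Everything is reproducible: one configuration yields
byte-identical bundles.

What the synthetic cohorts do **not** emulate: linkage and haplotype
structure, mutation-rate heterogeneity along the gene, genotype-level data
(only site-level summary counts), sequencing-error processes (false positives
are planted, not emergent), and real TTN coordinates. Passing tests therefore
demonstrate the correctness of the analysis logic under clean, labelled
conditions, not robustness to messy real-world call sets.

### Worked-example fixtures

Three deterministic fixtures reproduce published aggregate margins for
end-to-end report tests: a three-dataset cohort whose filtering margins match
the reference-population summary table (470→173 variants with the
247-variant transcript-filter and 50-variant coverage-filter attrition, band
split 19/39/90/25, carrier counts 219/10/19, three splice variants shared
between the two subset call sets), a nonsense-spectrum cohort (21 A-band
Cga/Tga among 23 A-band R/\*, 34 CpG-hotspot nonsense in total), and a
373-variant splice cohort (49 essential of which 41 private; 197 A-band of
which 175 non-essential). Where the published table is internally
inconsistent (cells vs margins), the fixtures prioritise dataset totals, band
margins and the A-band subtype cells; the report footnotes record the known
29-vs-33 raw-count discrepancy of the smallest cohort. These fixtures are
synthetic constructions matching printed margins, not the original variant
lists.

## Problem sizes and tolerances

Test and acceptance runs use desk-scale sizes chosen to exercise every code
path quickly: 1000 planted variants for classifier/truth concordance, 500
random indels for normalisation, exhaustive Fisher-vs-hypergeometric
comparison on all 2×2 tables with N ≤ 40 plus 500 random tables with
N ≤ 200, Wilson-vs-score-inversion agreement to 1e-6 relative, CI coverage
over 1000 simulated cohorts of 5 000 individuals (≥ 93 % required at the
95 % level), and population-rate recovery within 3 multinomial standard
errors pooled over 20 seeds.

## Known limitations

* Site-level only: no genotype matrices, BCF, tabix, or structural variants.
* Consequences are reported against one reference transcript; per-transcript
  HGVS-style annotation is out of scope.
* Carrier counting assumes at most one qualifying variant per individual.
* The concordance rule treats subset∩subset variants as validated even when
  the superset lacks them; whether that matches every upstream workflow is a
  policy choice exposed via configuration.
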