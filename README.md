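# ttnpop

Gene-centric analysis of **titin (TTN) truncating variants** (TTNtv) in
reference populations: consequence calling, expression- and concordance-based
filtering, nonsense-mutation spectrum analysis, splice-distance
allele-frequency spectra, and carrier-prevalence statistics — exercised
end-to-end on synthetic cohorts generated in-repo.

## The scientific problem

Truncating TTN variants — nonsense, frameshift and essential splice-site
changes, especially in the A-band of the sarcomere — are the most common
genetic cause of dilated cardiomyopathy, yet they also appear in healthy
reference populations. Interpreting a TTNtv found in a patient therefore
requires an accurate estimate of how often such variants occur in people
without disease, after removing likely artefacts and variants confined to
minor isoforms. This package implements that workflow for anyone who needs to
reproduce or stress-test it: site-level variant call sets (ExAC-style summary
counts) are annotated against a multi-transcript gene model carrying sarcomere
band intervals and per-exon proportion-spliced-in (PSI) values, then filtered
in the order

1. **quality** — keep `FILTER == PASS`;
2. **normalise + annotate** — left-align alleles to minimal representation,
   call consequences on the longest-CDS transcript;
3. **truncating** — keep nonsense, frameshift and essential splice
   (intronic positions 1–2 bp from an exon boundary); splice-region variants
   (3–6 bp) are *not* truncating;
4. **transcript** — drop variants in isoform-specific or low-PSI exons
   (PSI < 0.15 by default);
5. **concordance** — drop variants unique to a subset call set (1000 Genomes
   or ESP roles) and absent from the superset (ExAC role);
6. **coverage** — drop variants at positions with mean depth below 15×.

Carrier prevalence is estimated as `100·k/n` with `k = Σ(AC − hom)` carriers
over `n` individuals, with Wilson-score (default) or Clopper–Pearson binomial
confidence intervals. The nonsense spectrum module enumerates all 23
single-substitution codon→stop changes (9/7/7 by codon position) and flags
CpG-deamination hotspots (`Cga/Tga`, arginine→stop). The splice module bins
splice variants by intron distance (1–2, 3–4, 5–6 bp) and compares
private/low-frequency/common composition between bins with Fisher's exact
test.

Because no external databases are downloaded, a first-class synthetic-data
module generates titin-like gene models (three transcripts, one novex-like
isoform with a unique terminal exon, low-PSI exons) and multi-population
cohorts with exact per-variant truth labels, so every pipeline stage is tested
against known ground truth.

## Worked example

```bash
ttnpop report --out out/
```

builds the bundled reference-cohort fixture, runs the full pipeline and prints
the population summary table (`count (prevalence %)`; prevalence is
carrier-based):

```
                      row       ExAC       1KG        ESP
          Population size      60706      2504       6504
      Total TTNtv variant        173         9         16
              Individuals        219        10         19
Population prevalence (%)      0.361     0.399      0.292
               Frameshift 63 (0.110) 1 (0.080)  3 (0.092)
                 Nonsense 72 (0.160) 7 (0.280) 11 (0.169)
              Splice site 38 (0.091) 1 (0.040)  2 (0.031)
                   Z-band 19 (0.038)         -  1 (0.015)
                   I-band 39 (0.072) 1 (0.040)  7 (0.108)
                   A-band 90 (0.196) 7 (0.319)  4 (0.062)
                   M-band 25 (0.054) 1 (0.040)  4 (0.108)
...
```

Reading the ExAC column: after all filters, 173 distinct truncating variants
remain, carried by 219 of 60 706 individuals (0.36 % prevalence), 90 of them
(52 %) in the A band — i.e. roughly **one person in 500 carries an A-band
truncation** even in a reference population. A typical library session:

```python
from ttnpop import load_gene_model, read_vcf, run_pipeline, PipelineConfig
from ttnpop.popstats import prevalence_estimate

model = load_gene_model("bundle/model.json")
records = {"EXAC": read_vcf("bundle/cohort_EXAC.vcf", dataset="EXAC")}
result = run_pipeline(records, model, PipelineConfig())
est = prevalence_estimate(k=219, n=60706)
print(f"{est.prevalence:.3f}% ({est.ci_low:.3f}–{est.ci_high:.3f}%)")
# 0.361% (0.316–0.412%)
```

Other subcommands: `ttnpop simulate` (deterministic synthetic bundles with
truth tables), `annotate`, `filter`, `spectrum`, `splice`, `prevalence`,
`compare`.

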