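# lavagemut

Somatic mutation analysis for uterine-lavage liquid-biopsy cohorts.

Endometrial cancer sheds cells and cell-free DNA (cfDNA) into the uterine
cavity. Ultra-deep (~5,000X) targeted amplicon sequencing of a uterine
lavage — separated into a cell pellet and a cfDNA fraction, with a matched
germline blood sample — can detect cancer-associated somatic mutations at
allele fractions (AF = alt reads / depth) down to 1%. `lavagemut` implements
the downstream analysis for such trios, for researchers studying
early-detection genomics of endometrial cancer:

* **Ingestion and somatic filtering** — per-caller VCFs are merged under a
  ≥2-caller concordance rule, restricted to the amplicon panel,
  germline-subtracted against the matched normal, and thresholded at the
  assay's 1% reporting floor.
* **Sample identity** — a high-MAF SNP spike-in panel (~200X) genotypes each
  fraction; pairwise genotype concordance flags sample swaps.
* **Consequence classification** — short protein-change strings (`R130G`,
  `W111*`, `L318fs`, `Y463_L466del`, `T576delT`) are parsed and rolled up
  into missense / nonsense (stop, frameshift, in-frame) / silent buckets.
* **Driver nomination** — each mutation is labelled **driver** (hotspot of a
  major endometrial driver gene, or truncating in a major tumor-suppressor),
  **potential driver** (predicted-functional missense in a major gene, with
  a provenance sub-flag: recurrent in other cancers / endometrial-only /
  novel), or **passenger** (everything else; silent always), against a
  bundled 12-gene knowledge base (PTEN, PIK3CA, TP53, CTNNB1, KRAS, FGFR2,
  FBXW7, RB1, ATM, APC, ARID1A, PIK3R1).
* **Cohort statistics** — AF binning (≤5%, 5–10%, >10%), per-gene
  pellet/cfDNA concordance (Pearson r²), cancer enrichment at high AF
  (Fisher exact), and univariate clinical association scans (one-tailed
  Mann-Whitney-Wilcoxon, Benjamini-Hochberg adjustment, one-sided bootstrap
  CIs), exposed as a `CohortAnalysis(...).fit() -> CohortResults` pair.
* **Validation planning** — stratified 30% selection for orthogonal
  confirmation (Sanger at AF ≥ 10%, ddPCR below), ddPCR reflex testing of
  the paired fraction, and a spiked-control artifact screen.
* **Synthetic cohorts** — a seeded generator reproducing the cohort
  structure the analysis assumes (107 patients, 7 cancers, truncated
  log-normal AFs on 1–30.4%, +7.61 y age shift for driver carriers), so the
  whole pipeline is testable end to end with no external data.

## Worked example

Simulate a small cohort, render trio VCFs for three patients, and run the
pipeline:

```
lavagemut simulate --seed 3 --render 3 --out demo/
lavagemut ingest   --vcf-dir demo/vcf --out demo/calls.tsv
lavagemut identity --vcf-dir demo/vcf --report demo/identity.tsv
lavagemut nominate --calls demo/calls.tsv --out demo/nominated.tsv
lavagemut stats    --nominated demo/nominated.tsv --clinical demo/clinical.csv --out demo/report
```

`ingest` reports `wrote 20 somatic calls to demo/calls.tsv`: twenty
mutation-in-fraction observations survived caller concordance, panel,
germline and 1%-AF filters. The nominated table begins

```
patient_id  gene    protein_change  consequence  label             evidence                   fractions           max_allele_fraction
PT002       PTEN    R173C           missense     driver            hotspot                    cell_pellet         0.0209
PT002       ATM     L1420F          missense     potential_driver  functional_missense,novel  cell_pellet,cfdna   0.0151
PT002       PIK3R1  E558fs          frameshift   driver            hotspot,truncating_tsg     cfdna               0.0321
```

— PTEN R173C sits at a registered hotspot (driver); ATM L1420F is a
predicted-functional missense never reported in cancer (potential driver,
novel); PIK3R1 E558fs is truncating in a tumor suppressor (driver). The
identity report shows every fraction pair at concordance 1.0 over 24
callable SNPs (`verdict: match`), and `stats` prints the per-gene
pellet/cfDNA correlation, the cancer-by-AF-bin table and the clinical
association scan for the simulated cohort.

The same analyses run programmatically:

```python
from lavagemut import CohortAnalysis, default_knowledge_base, nominate

kb = default_knowledge_base()
nominate("PT001", "KRAS", "G12D", kb).label      # Label.DRIVER
results = CohortAnalysis.from_files("demo/nominated.tsv", "demo/clinical.csv").fit(seed=0)
print(results.summary())
```

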