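# Methods

## The analysis model

A patient contributes a *trio*: germline PBMC DNA, the lavage cell pellet,
and lavage cfDNA (a tumor sample is optional and not required by any step).
Somatic callers run upstream (the package consumes their VCFs; alignment and
raw calling are out of scope). The somatic filtering contract is:

1. **Caller concordance.** A variant keyed by (chrom, pos, ref, alt) is
   retained iff reported by ≥ `min_callers` callers (default 2). The merged
   record takes depth and allelic depths from the caller reporting the
   greatest depth — deterministic and conservative — and the caller set is
   the union. Multi-allelic records are decomposed per ALT; indels are used
   as given (no re-normalisation).
2. **Panel restriction.** VCF positions are 1-based; panel regions 0-based
   half-open (BED), so region (c, s, e) contains pos iff s < pos ≤ e.
   Calls on chromosomes absent from the panel are logged and dropped, not
   errors. Coordinates are GRCh37 throughout.
3. **Germline subtraction.** Any lavage call whose key appears in the
   germline call set is removed, with *no* AF gate on the normal: a
   low-AF germline observation still counts as germline-present. SNP
   fingerprint loci are identity markers and are never emitted as somatic.
4. **Reporting floor.** Calls with AF ≥ 1% are reported (inclusive: 1.0%
   exactly is reportable). The threshold applies after caller merging.

Steps 2 and 4 are pure subset filters and commute; step 3 is idempotent.

## Identity checking

The panel carries a spike-in of 24 high-MAF autosomal SNPs sequenced to
~200X. Genotypes are assigned by AF cuts (< 0.10 → 0/0, 0.10–0.90 → 0/1,
> 0.90 → 1/1) with loci under 50X left missing; at 200X the three genotype
clouds are separated by > 9 binomial standard deviations, so the generous
cuts are robust. A trio **matches** when every fraction pair shows
concordance ≥ 0.90 over ≥ 10 jointly callable loci; pairs with fewer
callable loci give an *insufficient* verdict rather than a mismatch. Two
unrelated individuals agree at a high-MAF locus with probability
Σ p(g)² ≈ 0.37–0.40, far below the threshold, which is why a single swap is
flagged essentially always. The cut points, depth gate, and thresholds are
configurable; kinship and contamination estimation are out of scope.

## Consequence classes and nomination

Short protein-change notation is parsed by an explicit grammar: `X###Y`
(missense, or silent when Y = X), `X###*` (stop gain), `X###fs`
(frameshift), `X###del[X]` and `X###_Y###del` (in-frame deletion),
`X###_Y###fs` and the compound anchor `X###Y###fs` (frameshift). Unknown
spellings — including insertions — classify as *other*, are excluded from
roll-ups, and never abort a run. *Truncating* means stop gain or frameshift;
the report-level *nonsense* bucket additionally includes in-frame deletions.

Nomination applies, in order of precedence:

* **driver** — the protein position lies in a knowledge-base hotspot of a
  major endometrial driver gene, or the mutation is truncating in a
  tumor-suppressor among the major drivers. Hotspot matching is at the
  protein-position level (any substitution at KRAS G12 matches); where
  several registry entries share a position, an exact protein-change match
  wins.
* **potential driver** — otherwise, missense with functional impact ≥
  *medium* (Mutation-Assessor-style scale: neutral < low < medium < high;
  the *medium* cutoff is the conventional functional threshold and is
  configurable) in a major driver gene. Exactly one provenance sub-flag is
  attached: recurrent-in-other-cancers, endometrial-only, or novel.
* **passenger** — everything else; silent mutations unconditionally.

All 12 panel genes default to `major_ec_driver = true` (the panel was built
from the highest-frequency endometrial driver genes); the flag is per-gene
configurable, which also answers whether truncating mutations in panel
tumor-suppressors outside a narrower "major" set qualify — by default they
do. Upgrading an impact annotation can only move a missense mutation toward
potential driver, never demote it (monotonicity, property-tested).

The bundled knowledge base stores the hotspot registry with endometrial and
pan-cancer recurrence counts. Hotspots that are novel relative to the
endometrial registry carry a pan-cancer recurrence of 1 so that every
registry entry has non-zero total recurrence. The gene-level lavage hotspot
count in the registry-comparison table is defined as the sum of its
per-hotspot counts, novel entries included.

## Cohort statistics

AF bins are (0, 0.05], (0.05, 0.10], (0.10, 1] — left-open/right-closed so
that 5.00% falls in the first bin and 10.00% in the second, matching the
"≤5.00% / 5.01–10.00% / ≥10.01%" reporting convention. Per-gene bin counts
sum exactly to per-gene fraction totals by construction. The pellet/cfDNA
concordance statistic is the Pearson correlation of per-gene totals
(r² displayed at 2 decimals; full precision retained internally); it is
undefined (NaN) when either vector has zero variance.

A patient belongs to a bin for a fraction if she has ≥ 1 mutation in that
bin in that fraction, so a patient can occupy several bins; cancer
percentages per bin are integer-rounded and empty bins report NA. The
high-AF enrichment test is a 2×2 Fisher exact of cancer status against
membership-in-the->10%-bin versus mutations-only-in-lower-bins; this 2×2
construction is a package choice (several constructions are defensible) and
is therefore configurable and not treated as a reference-valued output.

Inference wrappers: Fisher 2×2 via the exact hypergeometric distribution
(two-sided = sum of tables with probability ≤ observed); r×c tables (race)
via a seeded Monte-Carlo conditional-exact test that samples tables with the
observed margins and compares conditional probabilities — used because no
installed library provides an exact r×c test. The one-tailed
Mann-Whitney-Wilcoxon (alternative: the mutated group is stochastically
larger) uses exact enumeration for groups of ≤ 20 without ties, and the
tie-corrected normal approximation otherwise. Benjamini-Hochberg adjustment
is step-up, capped at 1, applied across the 7-covariate clinical family;
per-gene scans form their own families. The one-sided 95% confidence bound
on the location difference is a bootstrap percentile bound on the
difference of means (10,000 resamples, seeded); the method choice is the
package's own, as is the smoking coding (never < former < current) and the
0/1 coding of menopausal status and diabetes.

Calibration of the wrappers is checked by null simulation: 1,000 replicates
with two groups of 30 normal deviates (Mann-Whitney) and two groups of 100
Bernoulli(½) draws (Fisher). The Fisher null uses margins of 100 because
the exact test is intrinsically conservative on small tables, where its
attainable size falls visibly below the nominal 5%; at these margins
discreteness is mild and the empirical size of both tests falls within the
95% binomial interval around 0.05.

## Orthogonal validation

30% of reported mutations are selected for confirmation, stratified across
the three AF bins with proportional largest-remainder allocation
(stratified rather than simple sampling so low-AF calls are represented).
Method assignment is a pure function of the NGS AF: Sanger at ≥ 10%
(boundary inclusive), ddPCR below. Every ddPCR entry triggers a reflex test
of the same variant in the paired lavage fraction; reflex detections below
the 1% floor are recorded as sub-threshold confirmations rather than
discordances. The artifact screen compares control-replicate calls with the
reference truth set: any non-truth call is novel (pass criterion: zero),
truth calls are recovered with their AF deviation (deviations beyond ±20%
relative are flagged but still count as recovered). ddPCR droplet-level
modelling (Poisson occupancy) is not implemented; measured AFs are inputs.

## The synthetic-data generator

The generator emulates the cohort structure the analysis assumes, with
defaults fixed at the study conditions: 107 patients, QC pass rate 102/107,
58/102 mutated among QC-passed, cancer prevalence 7/107 (cancer patients are
drawn among mutated patients and always carry ≥ 1 driver), mean target
depth 5,000X (SNP spike-in 200X).

* **Allele fractions**: ln AF ~ N(−4.3, 1.0) truncated to (0.01, 0.304],
  giving an implied mean of ~0.032 with a realistic high-AF tail; the family
  and parameters are a modelling choice constrained by the reported range
  and mean. Cancer patients additionally receive, with probability 0.75,
  one mutation resampled uniformly above 10% AF (the high-AF enrichment).
* **Mutation content**: per-patient counts follow a zero-truncated negative
  binomial (mean ≈ 2.2, shape 1.2, capped at 20 — the count distribution is
  a stand-in; only the extremes are constrained by the study). Mutations
  are drawn without replacement from the bundled 126-entry catalogue with
  gene weights proportional to the published per-gene lavage counts, which
  induces the correlated per-gene pellet/cfDNA burdens. Each mutation lands
  in both lavage fractions with probability 0.6, else in one at random.
* **Ages**: non-carriers ~ N(50.35, 11); carriers of ≥ 1 driver or
  potential driver are shifted by +7.61 y. The shift attaches to carrier
  status — the grouping the association analysis uses — not to the broader
  any-mutation status, so the planted effect is exactly the estimated
  contrast. The 11 y standard deviation is a cohort-realistic choice (ages
  spanning roughly 29–85). Menopausal status is logistic in age (centre
  51 y, scale 5 y), so the age and menopause associations co-occur.
* **Reads**: depth ~ Poisson(5000), alt reads ~ Binomial(depth, AF);
  germline variants (per-patient random subset of 40 candidate panel sites,
  het 0.5 / hom 1.0) and SNP-fingerprint genotypes (HWE at each locus's
  MAF) are shared across the three fractions. Per-caller VCF copies drop
  each somatic variant independently with probability 0.05 — the simplest
  mechanism exercising the ≥2-caller merge. Control replicates render the
  reference truth set at 12,000–26,000X, with an optional Poisson artifact
  injection (stress mode).

All randomness flows from the config seed through per-patient seed
sequences: identical configs give byte-identical outputs, including VCFs.

What the generator does **not** emulate: sequence context and
instrument-specific error profiles (no FASTQ-level simulation), caller
disagreement beyond independent dropout, UMI/duplex error correction,
CNVs/SVs, tumor-in-normal contamination, or between-fraction AF divergence
beyond binomial noise. Passing tests therefore demonstrate the correctness
of the filtering, nomination and statistical machinery under the assumed
structure, not robustness to real-world artifact processes.

## Numerical and scale choices

Percentages are integer-rounded and r² is shown at 2 decimals only in
human-readable reports. Bootstrap and Monte-Carlo procedures are seeded;
the Monte-Carlo r×c p-value uses (hits + 1)/(n + 1). The acceptance script
uses 100 synthetic cohorts for the parameter-recovery estimates and the
test suite 200 — sizes chosen so Monte-Carlo error is small relative to the
±1 y recovery criterion (the per-cohort shift estimate has SD ≈ 2.2 y, so
the 200-cohort mean has SD ≈ 0.16 y). Degenerate inputs (empty groups,
all-mutated cohorts, single-patient bins, zero-variance vectors) return NA
or raise typed errors as documented per function, never silently.

## Known limitations

* The bundled amplicon coordinates and SNP loci are synthetic stand-ins
  placed inside the true GRCh37 gene spans (the study's exact loci are not
  public); panel-dependent results are structural, not locus-accurate.
* The bundled mutation catalogue's potential-driver and passenger entries
  are constructed to match the published partition sizes, not a deposited
  list; per-mutation annotations (impact, provenance) are stand-ins
  consistent with the classification rules.
* The enrichment 2×2 construction and the CI method are package choices;
  published p-values that depend on unrecoverable constructions are not
  asserted anywhere.
* No multivariable modelling, survival analysis, transcript-aware
  annotation, or genome-build liftover.
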