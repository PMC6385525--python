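# Methods

## Study design the package models

A case/control cohort genotyped by pooled targeted sequencing: diploid
individuals are pooled `pool_size` at a time (default 10, so each pool is a
sample of ploidy 20), sequenced on a multi-gene capture panel (default 69
genes) at a requested depth of ~250X, and variant calls are made per pool
with the pool's chromosome count. The default cohort is 830 cases and 40
controls — 83 case pools and 4 control pools. Because pooling destroys
individual genotypes, association is tested by comparing aggregate
alternate-allele counts in cases against public allele-frequency panels:
a global exome panel (N = 60,706), its non-Finnish European subset
(N = 33,370), and a smaller population-matched panel (N = 1,579). The panel
cohort sizes are configurable; the number of control pools is not stated
anywhere upstream, so 40 controls at 10 per pool (4 pools) is the default.

## Synthetic cohort generator

The generator is first-class, tested code; it defines the conditions every
statistical claim in the test suite is made under.

* **Allele frequencies.** Per-variant generating frequencies are drawn
  log-uniform on [2·10⁻⁴, 0.05]. Rationale: the burden analysis considers
  variants below panel MAF 0.1, and capture-panel variants are dominated by
  low-frequency sites spread over several orders of magnitude; a log-uniform
  law puts mass across that range without a cluster at common frequencies.
  All panels share a variant's generating frequency (one ancestral
  population); panel AC is drawn binomially from AN = 2N (an `expected`
  mode rounds AF·AN deterministically for arithmetic tests). A configurable
  fraction of variants (default 10%) is absent from the Spanish-like panel
  to exercise the described-in-panel restriction.
* **Genotypes.** Hardy–Weinberg binomial(2, AF) per individual. Nothing
  upstream specifies the cohort's genotype law; HW is the neutral default
  and is verified by a genotype-frequency test. Enriched genes multiply the
  case AF by a configured factor ≥ 1; an inflated AF above 1 raises an
  error rather than clamping, because clamping would silently change the
  effect size being simulated.
* **Pool calling.** The called alternate count per pool is the exact sum of
  member genotypes — the only caller noise is read-level: depth is
  negative-binomial around `mean_depth` (dispersion k = 10; capture data
  are overdispersed relative to Poisson), alternate reads are
  binomial(depth, f·(1−e) + (1−f)·e) at pool allele fraction f with
  per-read error e = 10⁻³, and alternate reads split binomial(0.5) across
  strands. GQ is 99 at clean sites. Only variants called in at least one
  pool are emitted, as in a real call set.
* **Artifacts.** Disjoint site classes injected at configurable rates among
  variants carried by at least one case: `single_strand` (all alternate
  reads moved to the forward strand), `low_depth` (depth redrawn uniform in
  [1, 9]), `low_gq` (GQ redrawn uniform in [0, 19]). Each class is
  constructed to fail exactly one filter stage and pass the others.
* **Determinism.** All stages draw from independent substreams spawned from
  one seed, so e.g. the panels are bit-identical whatever is simulated
  afterwards.

What the generator does **not** emulate: linkage disequilibrium between
sites, population stratification between cases and panels, caller-specific
genotyping error, reference bias, batch effects between pools. Passing
tests therefore demonstrate correctness of the pipeline's logic and
calibration under its stated sampling model, not robustness to those
real-data phenomena.

## Filter cascade

Canonical order: site quality → strand bias → recurrence →
control exclusion → functional class → MAF threshold. Every stage records
(n_in, n_out, removed keys, thresholds) in a ledger whose chain invariant
(counts non-increasing, consecutive stages linked) is validated on every
append.

Decisions where the upstream description was ambiguous:

* **Quality boundary.** "RD < 10 and GQ < 20 excluded" is implemented as
  exclude when depth < 10 **or** GQ < 20. The conjunctive reading would
  retain a depth-5/GQ-60 call, contradicting hard-filtering intent. Both
  thresholds are exclusive (`depth 10, GQ 20` passes) and configurable.
* **Observation semantics.** "Observed in a pool" means called alternate
  count > 0 in a QC-passing observation. In particular, control evidence
  that itself failed QC does not exclude a variant — QC runs before control
  exclusion.
* **Variant removal at QC.** A variant is dropped when no QC-passing case
  observation with alternate support remains; variants seen only in control
  pools therefore fall at this stage by design.
* **Strand filter.** Alternate reads are summed over QC-passing case pools;
  removal when either strand has fewer than `min_alt_reads_per_strand`
  (default 1, i.e. single-strand support) reads. Sites with no alternate
  reads at all are removed and logged separately as no-support.
* **MAF filter.** "MAF" is the unfolded alternate-allele frequency AC/AN.
  Variants absent from the panel count as frequency 0: kept and flagged
  novel-in-panel.

### Workflow branching

The two analysis branches share the QC front end (site quality + strand
bias) and then diverge:

* rare-variant branch: recurrence (≥ 2 pools) → control exclusion → exonic
  class → panel MAF < 0.001 → CADD-ranked prioritisation;
* burden branch: exonic class → panel MAF < 0.1 → per-gene burden test.

The burden branch deliberately omits recurrence and control exclusion: the
upstream workflow's burden input (957 exonic variants) is larger than its
post-control-exclusion rare-variant set (392), which is only possible if
those filters apply to the rare branch alone.

## Association statistics

* **One-sided Fisher test** in the case-enrichment direction:
  p = P(X ≥ a) for X hypergeometric with the table's margins, computed via
  the survival function (log-space internals; exact and overflow-free for
  cell totals beyond 10⁶). The test suite checks it against an independent
  oracle that literally enumerates integer binomial-coefficient products —
  exhaustively for every 2×2 table with grand total ≤ 60 (~6.4·10⁵ tables)
  plus seeded random tables with totals up to 200. The exhaustive bound of
  60 is the package's problem-size choice; coverage above it is sampled.
* **Odds ratio.** Sample cross-product OR with Woolf log-normal 95% CI,
  matching the spreadsheet convention the printed `OR (low–high)` format
  implies, not the conditional-MLE OR. Zero cells: Haldane–Anscombe 0.5
  added to all four cells for OR/CI only, never for the Fisher p. A table
  with no alternate allele in either group has an undefined OR, returned as
  NaN with a reason (p = 1 in the enrichment direction).
* **Bonferroni.** p_corr = min(1, m·p) where m is the variant count of the
  gene *in the analysis actually run* (the restricted analysis corrects by
  its own retained m). No cross-gene correction is applied.
* **Gene aggregation.** Cell-wise sums over variants; each variant
  contributes 2·N_cases case alleles, so a + b = m·2·N_cases. Variants
  missing from a panel contribute AC = 0 with the panel's full AN
  (comparable margins across panels); `drop_missing` excludes them instead.
* **Secondary analysis.** Restriction to missense variants with a present,
  non-zero entry in the Spanish-like panel; `percent_retained` is
  100·m_retained/m_unrestricted.
* **Prioritisation.** Rare variants (all available panel frequencies below
  the cut, default 0.001; absent from all panels = novel, kept) ranked by
  descending CADD phred, missing CADD last, ties broken by (chrom, pos,
  alt). No default CADD cutoff is applied — published prioritisations
  include scores spanning 0.02–35, so no single threshold is defensible;
  the cutoff is exposed as a parameter.
* **Per-variant ORs** use allele counts (not carrier counts), consistent
  with the allele-count definition of the gene-level tables.

## Calibration experiments

`poolburden.experiments` packages the validation studies:

* **Power / type-I** (`burden_power_experiment`): 100 replicates of the full
  simulate → QC → burden pipeline with 830 cases, 40 controls, six 5-variant
  genes of which three have 5× case allele-frequency inflation, fully
  described panels (no Spanish-missing variants, so the case-vs-panel
  comparison is calibrated — the same reason the restricted analysis exists)
  and artifacts off. Measured on the Spanish-sized panel (N = 1,579):
  enriched genes reach corrected p < 0.05 in ≈ 99–100% of tests, null genes
  in ≈ 1–3% (the Fisher test's discreteness keeps the null rate below the
  nominal 5%). Ascertainment — a variant enters the call set only if seen in
  some pool — slightly inflates case counts at the rarest frequencies; at
  these panel sizes the effect stays well inside the null band.
* **Artifact targeting** (`artifact_targeting_experiment`): with all three
  artifact classes injected at 8%, every injected site is removed by exactly
  its intended stage (single-strand → strand filter; low-depth and low-GQ →
  quality filter) and no case-supported clean site is removed by either.

Problem sizes throughout (replicate counts, enumeration bounds, cohort sizes
in unit tests) are chosen so the whole suite runs in about a minute on one
CPU while keeping every statistical band at its stated width.

## Known limitations

* Left-alignment of indels against a reference genome is not implemented —
  only shared suffix/prefix trimming; keys are minimal but not guaranteed
  left-shifted without flanking sequence.
* The pooled caller does not model caller-specific errors (allele dropout,
  pool-size misestimation); alternate counts are exact.
* Reference panels are treated as fixed external counts; panel sampling
  noise is simulated, but panel versioning/coverage differences are not.
* The burden comparison inherits the usual caveat of external-control
  designs: coverage or population mismatch between cohort and panel is not
  detectable from within the statistic.
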