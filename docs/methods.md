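# Methods

## Data model and allele orientation

A corpus row is one case-control study of one biallelic SNP: genotype count
triples (AA, AB, BB) per arm plus metadata (country, ethnicity label,
genotyping method, Newcastle-Ottawa score, and the published control
minor-allele frequency and HWE p-value where available). Orientation is
fixed per variant — AA is always the homozygote of the globally designated
major allele (T for rs3731217, C for rs3731249) — and is **not** flipped for
populations where the globally minor allele is locally the common one
(two studies in the bundled corpus have control minor-allele frequencies of
0.600 and 0.535). Pooling across studies is only meaningful on a single
orientation; the price is that stratified results on such data can disagree
with analyses that reorient per stratum, which is why the report flags any
stratum whose pooled OR falls on the opposite side of 1 from the overall
estimate.

Published genotype tables are redundant: allele counts, MAF and HWE p can
all be recomputed from the genotype triples. `validate_record` enforces that
redundancy (MAF within ±0.0005, HWE p within ±0.005), so a mis-transcribed
digit cannot load silently. In the bundled corpus every genotype count
cross-checks exactly; one published HWE cell (Kreile 2016) repeats that
row's MAF digit-for-digit and matches no recomputation (Pearson, Yates or
exact), so it is stored blank as a source-table typesetting defect rather
than propagated.

## Per-study statistics

* **HWE**: Pearson χ² against (p², 2pq, q²) at the sample allele frequency,
  1 df, no Yates correction — the variant that reproduces the per-study
  p-values printed alongside such corpora (e.g. 0.943, 0.222); monomorphic
  samples return χ² = 0, p = 1, flagged. Controls failing HWE at α = 0.05
  are removed in the sensitivity rerun (a no-op on the bundled corpus, where
  all 22 control arms pass).
* **Effect size**: log odds ratio with Woolf SE √(1/a+1/b+1/c+1/d). Any
  study with a zero cell gets 0.5 added to all four of its cells (per-study,
  not corpus-wide); studies with an exposure column empty in *both* arms are
  degenerate — they carry no information about the contrast — and are
  excluded from that contrast's pooling, with the exclusion recorded on the
  result.

## Pooling and model selection

Fixed-effect pooling defaults to inverse variance on the per-study log ORs.
That choice is deliberate: it is the "fixed effect" of the mainstream
commercial meta-analysis packages whose output conventions published genetic
meta-analyses follow (frequently under the label "Mantel-Haenszel"), and it
is what reproduces the bundled corpus's published pooled estimates to all
three printed decimals. A true Mantel-Haenszel estimator — pooled cross
products on raw counts, Robins-Breslow-Greenland variance, tolerant of zero
cells without correction — is implemented as `pool_mh` and selectable via
`MetaConfig(fixed_method="mh")`; the two agree closely except under very
sparse contrasts (homozygote/recessive with handfuls of events), where they
can differ by several percent.

Random effects is DerSimonian-Laird: τ² = max(0, (Q−df)/C) with
C = Σw − Σw²/Σw on inverse-variance weights, random weights 1/(se²+τ²).
With τ² = 0 it reduces exactly to inverse-variance fixed pooling.
Heterogeneity is Cochran's Q (inverse-variance weights about the fixed
pool), P_H from χ²(k−1), I² = max(0,(Q−df)/Q)·100.

The selection rule is *random iff I² > 50% or P_H < 0.05*. The I²-only rule
often quoted in methods sections does not explain published model labels for
rows with I² in the 40s and significant Q; the disjunctive rule reproduces
every effect-model label in the bundled corpus's source analysis. Both
thresholds are `MetaConfig` fields. CIs use the normal 1.96 multiplier; all
p-values are two-sided; no multiple-testing adjustment is applied across
contrasts or strata (per-model p-values are reported unadjusted, as is
conventional in this literature). Report TSVs round OR/CI/Z/p to 3 decimals
and I² to 2; JSON keeps full precision.

## Sensitivity and subgroups

Leave-one-out refits the pool k times with the same selection rule and
summarizes the OR range, any crossing of OR = 1, and whether significance
held. Stratification is supported on ethnicity, genotyping method and source
of controls (the last is carried in the schema but unpopulated in the
bundled corpus, so stratifying on it raises a clear error). Single-study
strata are reported as that study's own OR and flagged `single_study`.

## Publication bias

* **Begg**: Kendall score between variance-standardized deviations from the
  fixed pool (deviation variance v_i − 1/Σw) and the per-study variances;
  normal approximation with continuity correction and the tau-b style
  tie-adjusted score variance.
* **Egger**: OLS of logOR/se on 1/se; two-sided t test of the intercept on
  k−2 df.
* **Trim-and-fill**: Duval-Tweedie with the L0 estimator, iterated to
  convergence (cap 50; k0 capped at k−2). Interim pooling inside the trim
  loop is fixed inverse-variance; the final augmented set is pooled under
  the usual selection rule. The imputation side defaults to `auto`: the side
  opposite the asymmetry indicated by the Egger intercept sign. The
  correction is triggered when *either* Begg or Egger is significant at
  α = 0.05 (configurable); which single test an original analysis keyed on
  is rarely stated, and triggering on either is the conservative reading.
  On exact mirror-symmetric inputs the estimator returns k0 = 0 and leaves
  the pooling untouched. A known discreteness of the iterative L0 rank
  estimator: deleting m studies from a perfectly paired symmetric set tends
  to recover m−1 (the biased first-pass center flips the within-pair rank
  order); on realistic, non-paired funnels it recovers the deletion count,
  which is what the tests exercise.

## Synthetic corpora

`simulate_corpus` draws control genotypes from HWE proportions at frequency
`maf` and case genotypes from the same proportions tilted by ψ^(minor-allele
count), normalized — the log-additive model under which the population
allelic OR equals ψ exactly, giving closed-form truth for recovery tests.
Per-study effects are log ψ_i ~ N(log ψ, τ²); each study runs on its own
seeded stream, so corpora are bit-reproducible. Funnel asymmetry is induced
by deleting the `suppress` smallest studies whose realized allelic effect
lies on the weak side of the truth. Defaults (14 studies, maf 0.13, ψ 0.75,
sizes 50–1500 cases / 50–5200 controls) mirror the composition of the
bundled corpus.

What the generator does **not** emulate: linkage between variants, covariate
confounding, genotyping error, non-HWE control populations, and
selection-on-significance mechanisms more subtle than one-sided truncation.
Passing recovery tests therefore demonstrates estimator correctness under
the model's own assumptions, not robustness to those violations.

## Validation problem sizes

Calibration tests use 500-replicate Monte-Carlo batches: allelic-OR recovery
and 95% CI coverage at k = 10 (band 0.92–0.98 around nominal), Egger type-I
error at k = 15 (band 0.02–0.08), and τ² recovery at k = 50 (mean within
0.02 of the truth, absorbing the moment estimator's mild attenuation).
Pooling arithmetic is checked to 1e-6 against an independent spreadsheet-style
recomputation on 2- and 3-study toy corpora, and against
`statsmodels.stats.contingency_tables.StratifiedTable` (Mantel-Haenszel/RBG)
and `statsmodels.stats.meta_analysis.combine_effects` (Q, DL τ²) on the
bundled corpus.

## Known limitations

* Subgroup estimates inherit the global allele orientation (see above);
  analyses that flip alleles per stratum will disagree on strata containing
  locally-common "minor" alleles.
* Exact (enumeration-based) HWE testing, Peto pooling, REML/Paule-Mandel
  τ², Hartung-Knapp adjustment and meta-regression are out of scope.
* Begg's test is underpowered below k ≈ 10 and Egger's power is modest at
  typical corpus sizes; a non-significant bias test is weak evidence of
  absence.
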