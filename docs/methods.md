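# Methods

This note documents the statistical and sequence models behind
`mirmint`, the choices made where the design was genuinely open, and
what the synthetic validation does and does not demonstrate.

## Differential expression

Each cohort is a features × samples matrix of log2 expression with
tumor/normal labels; normalisation (e.g. GCRMA for arrays, count
transformation for sequencing) is assumed done upstream, and the reader
accepts any log2-scale matrix without asking which transformation
produced it. Per feature we test tumor vs normal with a two-sample
*t*-test and report log2FC = mean(tumor) − mean(normal).

* **Pooled variance by default, Welch behind a flag.** The screen this
  package reproduces names Student's *t*-test; real cohorts are
  heteroscedastic, so the Welch form is available
  (`equal_variance=False`) but is not the default.
* **Thresholds.** A direction is called iff p < α (default 0.05) and
  |log2FC| strictly exceeds the class cutoff: 1.0 for mRNAs, 0.0 for
  miRNAs. The miRNA cutoff of "±0" is read as *strictly* nonzero
  log2FC — an inclusive zero bound would pass every feature — which
  makes miRNA calling significance-driven. The overexpression contrast
  uses |log2FC| ≥ 0.5849 (= log2 1.5 at the conventional printed
  precision) with *inclusive* bounds, as a single-sample filter with no
  replicate statistics.
* **Degenerate features.** Zero within-group variance with equal means
  gives (t = 0, p = 1); with unequal means the p → 0 limit is reported
  and the record flagged. Both conventions are exercised in tests.
* **No multiple-testing correction by default.** Raw p < 0.05 mirrors
  the per-cohort screens this funnel models; Benjamini–Hochberg is an
  opt-in flag at both the DE and pairing stages.

## Cross-cohort consensus

A miRNA is retained iff called with the *same* direction in at least
`min_datasets` (default 3) cohorts and never called in the opposite
direction; any direction conflict drops the feature with a logged
warning. Direction consistency is a deliberate strengthening — presence
in three DE lists alone would admit sign-flipping features. Features
consistent in exactly `min_datasets − 1` cohorts go to a near-miss
sidecar for audit. Array mRNA cohorts are pooled (column concatenation
on the common feature set, origin kept as sample metadata) before DE,
then intersected with the sequencing cohort, because the modelled
studies report a single array-wide DE list; a per-cohort-vote
alternative can be assembled from the same primitives.

## Target-site prediction

Three deliberately small, fully documented predictors score each
seed-matched site, one per decision axis of the classic tool trio
(alignment / duplex energy / site accessibility). They are stand-ins
with the same roles, not reimplementations; every constant ships as a
module-level table so tests can verify scores by hand.

* **Seed scanner.** Canonical site classes on the target strand,
  5′→3′: 8mer = rc(seed7)+A, 7mer-m8 = rc(seed7), 7mer-A1 = rc(seed6)+A,
  6mer = rc(seed6), where seed7/seed6 are miRNA positions 2–8/2–7 and
  rc is reverse complement. Each seed-match occurrence is reported once
  at its highest class. Coordinates are 0-based half-open; only the
  sense strand is scanned (3′UTRs are single-stranded). Site lists are
  invariant under case and T/U representation.
* **Duplex MFE** (RNAhybrid axis). Minimum free energy over antiparallel
  intermolecular alignments without intramolecular structure. Adjacent
  pairs contribute a stack energy −(s₁ + s₂) from per-pair half-stack
  strengths (GC 1.65, AU 0.55, GU 0.25 kcal/mol), giving
  literature-scale magnitudes (GC/GC −3.3, AU/AU −1.1); internal
  unpaired stretches cost 3.0 + 0.5·k kcal/mol; dangling ends are free.
  The dynamic program is exact (verified against exhaustive enumeration
  of all pairings for short inputs); windows are capped at 40 nt to
  keep exhaustive testing feasible. "No pairable position" returns a
  sentinel rather than 0.
* **Alignment score** (miRanda axis). Gotoh local alignment of the miRNA
  against the reversed window: Watson–Crick +5, GU +2, mismatch −3, gap
  open −8, extend −2, with substitution scores doubled opposite miRNA
  positions 2–8. A perfect seed-only 7mer scores 70; the default
  pass threshold of 80 therefore demands pairing beyond the seed, and
  random 20-mers score below it >99% of the time.
* **Accessibility ΔΔG** (PITA axis). ΔΔG = duplex MFE of the miRNA:site
  hybrid + 1.0 kcal/mol per base pair that a maximum-base-pairing
  (Nussinov, minimum loop 3, GU allowed) fold of the site ± 17 nt flanks
  would have to open. Maximum base pairing overestimates real structure,
  which makes the opening cost conservative; the 1.0 kcal/mol per pair
  is a deliberate simplification of a free-energy difference. The
  definition needs the miRNA to evaluate the hybrid term, so the
  function takes it as its first argument.
* **Consensus.** A site is reported iff its seed class reaches
  `min_seed_class` (default 6mer) and all three predictors pass
  (`all3`), or any one does (`union`, mirroring a multi-tool union
  stage). Defaults (align ≥ 80, MFE ≤ −14, ΔΔG ≤ −5 kcal/mol) were
  chosen so that fully paired planted sites pass with wide margins
  while chance 6mer matches with no 3′-supplementary pairing fail; they
  live in `PredictorThresholds`, not in code paths.

## Inverse-correlation pairing

Pairs require (a) strictly opposite consensus directions, (b) Pearson
r < 0 with p < 0.05 on the matched-sample cohort, (c) ≥ 1 consensus
site. Correlation uses **tumor samples only** by default: pooling tumor
and normal mixes the group-mean shift into the correlation and inflates
|r| for any pair of DE features, negatively coupled or not. The pooled
mode exists behind a flag for comparability. The r-threshold default of
0 (any significantly negative correlation) reflects that the modelled
analyses print no r cutoff.

## Candidate nomination and ΔΔCt

The funnel for one focus miRNA is two explicit set operations:
predicted-target ∩ overexpression-down, then an annotation filter
keeping candidates in ≥ 1 user-required GMT term (term ids or names; a
required term missing from the GMT is an error, so a typo cannot
silently empty the list). A literature-screening step is out of scope
and replaced by the explicit `required_terms` list plus an optional
exclusion file of already-known (miRNA, gene) interactions.

Validation readouts use the comparative-Ct model: ΔCt = mean Ct(target)
− mean Ct(reference) per condition, ΔΔCt = ΔCt(case) − ΔCt(calibrator),
RQ = 2^−ΔΔCt, with per-triplicate standard deviations reported.

## Enrichment

Hypergeometric upper tail P(X ≥ k) per term (k hits in an n-gene list
against a K-member set in an N-gene background), evaluated through the
survival function in log space and verified against exact rational
arithmetic for all N ≤ 25. The EASE variant computes the tail with one
hit removed (equal to 1 when k = 1) and is never smaller than the plain
p. The background defaults to the union of all GMT members and is
overridable; enrichment p-values are only comparable across runs with
the same background.

## Synthetic cohorts and planted truth

The generator emulates the *working assumptions* of the analysis rather
than platform physics — both "array" and "sequencing" cohorts are
Gaussian in log2 space, because the downstream t-test/log2FC lens treats
them identically.

* Non-DE feature: value ~ Normal(baseline, σ) in both groups, baseline
  ~ Normal(7, 1.5) per feature (log2 scale). DE feature: tumor mean
  shifted by ±δ. Defaults δ = 1.5, σ = 0.5 (δ = 3σ), 20 samples per
  group, 4 miRNA cohorts (3 array + 1 matched sequencing), 2 mRNA
  cohorts (1 array + 1 matched), 300 miRNAs / 600 mRNAs with 40% / 30%
  DE split evenly between directions.
* Planted pair (m, g), default 50 per study: m is DE-down, g is DE-up,
  and on the matched cohort g = baseline + dir·δ·tumor − β·(centered m)
  + Normal(0, σ/2) with β = 0.8 — encoding miRNA-mediated repression
  directly. Within tumor samples this gives an expected r ≈ −0.85 at
  the defaults.
* 3′UTRs (600 nt default): each planted target carries one embedded
  site — the complement of miRNA positions 2..L with the 3′-terminal
  base selecting the seed class (A opposite position 1 for the default
  8mer) — so planted sites include full 3′-supplementary pairing and
  clear the predictor defaults with margin. All background sequence is
  generated free of 6mer-or-better matches for every DE miRNA, so any
  site-level false positive downstream is the predictor's, not the
  generator's. Whole-sequence rejection against ~10² forbidden hexamers
  is astronomically unlikely to succeed at 600 nt, so backgrounds are
  sampled left-to-right with per-base exclusion of any base that would
  complete a forbidden 6mer, then verified globally, with bounded
  retries (dead ends restart the UTR; junctions around an embedded site
  are re-drawn until clean). Chance hexamer matches for *other* miRNAs
  inside an embedded site are possible (the embedded text is fixed) and
  are left for the predictors to reject. miRNA seeds are drawn pairwise
  distinct, and a miRNA's own seed never recurs inside positions 2..L,
  so the recorded planted interval is provably the only seed match for
  its miRNA in that UTR.
* Overexpression profile: planted targets of the focus miRNA drop by at
  least 0.5849 + 0.5 (margin) log2 units; 40 random bystander genes get
  uniform fold changes in [−2, 2] (some of which pass the down filter,
  exercising the intersection); everything else stays near zero.
* Determinism: every stage derives an independent stream from
  `SeedSequence([rng_seed, stage])`; identical config + seed gives
  byte-identical files.

**What passing tests show — and do not.** Planted-truth recovery
(precision/recall ≥ 0.9, in practice 1.0 at the defaults) demonstrates
that the pipeline's logic composes correctly and that its filters are
calibrated relative to the generator's assumptions: Gaussian noise,
homoscedastic groups, direction-consistent cohorts, site-free
backgrounds, a single strong site per target. Real cohorts violate all
of these — batch effects, probe/gene mapping noise, partially matched
samples, weak or multiple sites, correlated confounders — so recovery
on synthetic data bounds implementation error, not biological accuracy.
Genome-scale headline counts from real cohort studies depend on
external downloads and third-party tool versions and are deliberately
not reproduction targets; the bundled published worked example (the
nine-miRNA three-cohort consensus in `mirmint.data`) is.

## Problem sizes and numerical choices

The default synthetic study (4+2 cohorts, 300/600 features, 50 pairs)
runs the whole funnel in a few seconds; the acceptance script and test
suite finish in well under a minute on one CPU. The duplex DP uses an
exact rectangle-minimum reduction of the affine loop penalty (O(nm)
instead of O(n²m²)); ties in all dynamic programs resolve toward the
smallest indices by iteration order, and all scores are plain floats —
equality comparisons in tests allow 1e-9 absolute slack. Expression
values are printed with six decimals, bounding file round-trip error at
5e-7. Empty-report conventions: precision = 1.0 when nothing is
reported, recall = 1.0 when nothing is planted, F1 = 0 when both
precision and recall are 0.

## Known limitations

* Predictors model only canonical 3′UTR seed sites; no CDS/5′UTR sites,
  no conservation, no partition-function accessibility.
* The consensus stage has no meta-analytic p-combination (Fisher,
  Stouffer) and no cross-platform probe mapping; feature ids must agree
  across cohorts.
* Pairing offers no partial correlation or network deconvolution; a
  miRNA and mRNA co-regulated by a third factor can pass the screen.
* The Gaussian generator does not emulate count overdispersion, batch
  structure or missing values.
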