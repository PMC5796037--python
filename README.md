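# mirmint

Integrated miRNA–mRNA expression analysis for tumor/normal cohorts.

Bulk expression studies of cancers such as gastric adenocarcinoma
typically produce several independent tumor-versus-normal cohorts —
a handful of microarray series plus a sequencing cohort with matched
miRNA and mRNA profiles per patient. `mirmint` implements the classic
multistep funnel used to turn those cohorts into a short list of
experimentally testable miRNA targets:

1. **Differential expression** per cohort: two-sample Student's *t*-test
   (pooled variance; Welch optional) with log2 fold-change cutoffs —
   |log2FC| > 1 for mRNAs, any nonzero log2FC for miRNAs, both at
   p < 0.05.
2. **Cross-cohort consensus**: a miRNA survives if called with the same
   direction in ≥ 3 cohorts; mRNAs must agree between the pooled array
   source and the sequencing source.
3. **Target-site prediction consensus**: three independent in-package
   predictors score every seed-matched site — a seed-weighted local
   complementarity alignment, the nearest-neighbor minimum free energy
   of the miRNA:target duplex, and an accessibility ΔΔG that discounts
   the cost of opening target secondary structure. A site counts only
   if all three pass (a union mode is available).
4. **Inverse-correlation pairing**: since miRNAs repress their targets,
   a (miRNA, mRNA) pair is kept only when the two features are
   oppositely dysregulated, significantly negatively correlated
   (Pearson, tumor samples of the matched cohort), and linked by a
   consensus-predicted 3′UTR site.
5. **Candidate nomination**: the predicted targets of one miRNA are
   intersected with the genes down-regulated after overexpressing it
   (|log2FC| ≥ log2 1.5 = 0.5849 against a scrambled control), screened
   against known interactions and filtered by functional annotation.
6. **Enrichment**: hypergeometric over-representation (with the
   conservative EASE variant) of gene lists against user GMT sets,
   Benjamini–Hochberg adjusted.

Because the real cohorts behind such studies are download-scale,
`mirmint` ships a first-class synthetic-cohort generator that emulates
their statistical structure with *planted truth*: known differentially
expressed features and known miRNA→mRNA regulatory pairs that are
oppositely shifted, negatively coupled across matched samples, and
linked by a seed site embedded in the target's 3′UTR. Every stage of the
pipeline can therefore be scored for precision and recall against ground
truth.

## Worked example

```python
from mirmint import (SimulationConfig, simulate_cohorts, simulate_utrs, call_de,
                     consensus_mirna, consensus_mrna, MatureMirna, predict_targets,
                     build_pairs, summarize_pairs, evaluate_recovery)

cfg = SimulationConfig(n_mirnas=120, n_mrnas=240, n_planted_pairs=20, rng_seed=7)
mirna_ds, mrna_ds, (mm, mg), truth = simulate_cohorts(cfg)
utrs = simulate_utrs(cfg, truth)

mirna_cons = consensus_mirna([call_de(d, feature_class="mirna") for d in mirna_ds],
                             min_datasets=3)
mrna_cons = consensus_mrna(call_de(mrna_ds[0], feature_class="mrna"),
                           call_de(mrna_ds[-1], feature_class="mrna"))
mirnas = [MatureMirna(f.feature_id, truth.mirna_sequences[f.feature_id])
          for f in mirna_cons]
sites = predict_targets(mirnas, {f.feature_id: utrs[f.feature_id]
                                 for f in mrna_cons if f.feature_id in utrs})
pairs = build_pairs(mirna_cons, mrna_cons, mm, mg, sites)

print("consensus miRNAs:", len(mirna_cons), " consensus mRNAs:", len(mrna_cons))
print("consensus-predicted sites:", len(sites))
print("pair summary:", summarize_pairs(pairs))
precision, recall, f1 = evaluate_recovery(pairs, truth)
print(f"recovery vs planted truth: precision={precision:.2f} recall={recall:.2f}")
```

prints

```
consensus miRNAs: 48  consensus mRNAs: 72
consensus-predicted sites: 20
pair summary: {'n_pairs': 20, 'n_mirnas': 20, 'n_mrnas': 20, 'n_up_mirna_down_mrna': 0, 'n_down_mirna_up_mrna': 20}
recovery vs planted truth: precision=1.00 recall=1.00
```

Of 48 consensus miRNAs and 72 consensus mRNAs (the generator planted 48
DE miRNAs and 72 DE mRNAs in this configuration), the full funnel keeps
exactly the 20 planted regulatory pairs — every one a down-regulated
miRNA paired with an up-regulated mRNA through a negative tumor-sample
correlation (e.g. `miR-syn-0000 -> GENE0045, r = -0.81, p = 1.5e-05`)
and an all-three-predictor 8mer site.

The same flow is available from the shell:

```sh
mirmint simulate --outdir data --seed 7
mirmint de --dataset data/MIR-ARRAY1.tsv --feature-class mirna --out de1.tsv
mirmint predict --mirnas data/mirnas.fa --utrs data/utrs.fa --out sites.tsv
mirmint run-all --config config.yaml --outdir run --seed 7
```

`run-all` writes every intermediate table plus a `manifest.json` with
the funnel counts; reruns with the same config and seed are
byte-identical.

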