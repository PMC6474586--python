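# sigreverse

Connectivity-map style **signature-reversal screening** for drug
repositioning, plus the standard **DSS-colitis preclinical quantifications**
— as a tested, fully synthetic-data-driven pipeline.

## The problem

Given transcriptional profiles of compound-treated cells and a disease
signature (the most up- and down-regulated genes in diseased vs. normal
tissue), connectivity mapping asks: which compounds push the transcriptome
*against* the disease state? A compound whose profile shows a strong inverse
correlation with a disease signature — disease-up genes driven down,
disease-down genes driven up — is a candidate reverser worth testing in vivo.
This package implements that screen end to end, and the quantifications used
to follow hits up in the dextran-sodium-sulfate (DSS) mouse colitis model:
the Disease Activity Index (DAI), its area under the time course, a 0–40
histopathology composite, MPO per gram of tissue, and ΔΔCp qPCR fold changes.

Because real compound screens and patient cohorts are proprietary, every
input is generated by the package's own simulators with known ground truth
(which compounds reverse which signatures, and by how much), so the whole
pipeline is testable on a laptop.

## The statistic

Compound profiles are reduced to ranked gene lists (array path: quantile
normalization → batch-mean centering → treatment-minus-vehicle-control;
L1000-style path: per-gene robust z-scores). For a gene set of size *t* at
ascending ranks V(1) ≤ … ≤ V(t) in a ranked list of *n* genes, the enrichment
score is the classic Kolmogorov–Smirnov connectivity form

```
a  = max_j ( j/t − V(j)/n )
b  = max_j ( V(j)/n − (j−1)/t )
ES = a  if a > b  else  −b          ∈ [−1, 1]
```

With `es_up`/`es_down` the ES of the signature's up/down lists, the combined
score is 0 when they share a sign and `(es_up − es_down)/2` otherwise; −1 is
a perfect reverser. Replicates are averaged into the *mean CMAP score*; a
two-sided permutation p-value (default **10,000** random gene-set pairs, floor
1/10,001) and a specificity (fraction of other signatures matching at least
as strongly; lower = more unique) complete each hit-table row. Disease
signatures are the **250** most up- and **250** most down-regulated genes by
fold change, from cohorts with at least **3** disease and **3** normal
samples. See `docs/methods.md` for every formula and design choice.

## Worked example

Run the bundled demo (1,000 genes; 8 compounds in triplicate of which
compound `cmpd_000` is an embedded exact reverser of a simulated ulcerative
colitis epithelium signature; a 4-arm simulated animal study):

```bash
sigreverse run-all --seed 7 --out demo/
```

`demo/report.md` then contains (actual output):

```
## Top signature reversers

| instance | signature | mean CMAP score | p-value | specificity |
|---|---|---|---|---|
| cmpd_000@10.0uM:MCF7 | uc_epithelium | -0.2607 | 0.0001 | 0.000 |
| cmpd_003@10.0uM:MCF7 | uc_epithelium | -0.0582 | 0.116 | 0.000 |
| cmpd_005@10.0uM:MCF7 | uc_epithelium | -0.0247 | 0.194 | 0.000 |
```

The embedded reverser is recovered first with a strongly negative mean CMAP
score and a permutation p-value at the attainable floor (1/10,001 ≈ 0.0001);
the null compounds hover near 0. The preclinical arm of the report summarizes
the simulated colitis study — per-group DAI AUC (actual output):

```
group,n,mean,sd,se
CsA,6,4.972,0.287,0.117
DSS,12,8.444,1.554,0.449
EPHX2i,6,2.806,1.916,0.782
sham,6,0.0,0.0,0.0
```

i.e. untreated DSS animals accumulate the largest disease burden, both
treatments protect (lower AUC), and sham animals stay at zero — the pattern
the scoring formulas should reproduce given those group trajectories.

Each stage is also available separately (`simulate`, `process`, `signatures`,
`score`, `preclinical`, `report`), reading and writing plain TSV/CSV/GMT/JSON;
`run-all` writes a `manifest.json` with the seed and SHA-256 checksums of
every artifact, and reruns with the same config reproduce identical checksums.

Library use mirrors the CLI:

```python
import sigreverse as sr

cohort = sr.generate_disease_cohort(2000, n_disease=6, n_normal=11, seed=11)
signature = sr.build_signature(cohort.matrix, cohort.design, signature_id="uc")
config = sr.SimConfig(n_genes=2000, n_compounds=21, seed=5)
matrix, metadata, truth = sr.generate_compound_experiment(
    config, [sr.EmbeddedEffect("uc", strength=-1.0)], {"uc": cohort.effect})
profiles = sr.treatment_to_control(
    sr.batch_correct(sr.quantile_normalize(matrix), metadata), metadata)
results = sr.score_screen(profiles, [signature], seed=0)
table = sr.build_hit_table(results)
```

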