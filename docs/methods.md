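# Methods

`sigreverse` implements a connectivity-map style signature-reversal screen and
the standard quantifications of the DSS-colitis mouse model, exercised end to
end on synthetic data with known ground truth. This note records the models,
the formulas, the defaults and why, and what the synthetic data does and does
not establish.

## Differential profile construction

Two platform paths convert a raw genes × samples matrix into per-instance
differential profiles.

**Array path.** Log2 intensity matrices are (1) quantile normalized: each
column's values are replaced, in rank order, by the across-column means of the
column-sorted values, so all samples share one distribution; (2) batch
corrected: per gene, each batch's mean is shifted onto the gene's grand mean,
which removes additive batch offsets while leaving every within-batch contrast
untouched and preserving per-gene grand means exactly; (3) converted to
treatment-to-control values: the mean of all vehicle (DMSO) samples in the
same batch and cell line is subtracted from each treatment sample.

Numerical choices: tied values within a column receive the mean of the rank
means their tie run spans (the standard convention; it makes the operation
idempotent, at the cost that columns with different tie patterns no longer
share an exactly identical multiset). Batch correction is plain per-gene
batch-mean centering — no covariates are modeled, because the generative model
being corrected is an additive per-(batch, gene) offset. Single-sample batches
are corrected like any other but flagged in the log, since their shift absorbs
sample noise.

**L1000-style path.** High-throughput platforms report differential expression
as robust z-scores. Per plate grouping (from a `plate` metadata column; absent
that, the whole matrix), each gene is scored as
`(x − median) / (1.4826 · MAD)` across samples. The constant 1.4826 makes the
scaled MAD a consistent estimator of a Gaussian standard deviation. Genes with
zero MAD get z = 0 and a log warning rather than an infinity. Z-scores are
computed against the plate population, not against vehicle wells only — a
choice, documented here, that matches the population-referenced convention of
robust z-scoring pipelines. At least 3 samples per grouping are required.

## Disease signatures

A signature is built from a disease/normal cohort with at least 3 samples per
group (cohorts below the gate are rejected, naming the failing group). The
per-gene fold change is the difference of group means on the log2 scale —
i.e. a log fold change; the inputs are log-scale intensities, so differencing
means is the natural reading. The 250 most up-regulated and 250 most
down-regulated genes (configurable `size_per_direction`) form the ordered up
and down lists. Ties break lexicographically by gene ID for determinism, and
the down list is drawn from the genes the up list did not take, so the two
lists are disjoint even when a tie run straddles both selection cuts.
Signatures serialize as a two-record GMT file (`<id>_UP`, `<id>_DN`) with a
JSON sidecar for tissue/disease/species metadata.

## Connectivity scoring

For a gene set of size t occupying ascending ranks V(1) ≤ … ≤ V(t) in a
ranked profile of n genes (most up-regulated first, ties broken by gene ID):

    a  = max_j ( j/t − V(j)/n )
    b  = max_j ( V(j)/n − (j−1)/t )
    ES = a  if a > b  else  −b

ES ∈ [−1, 1]; sets concentrated at the top score positive. This is the
classic connectivity-map form of the Kolmogorov–Smirnov statistic. Note its
grid asymmetry: reversing the ranked list maps (a, b) to (b − 1/n, a + 1/n),
so reversal negates ES only up to −1/n generically, and a set whose two
deviations nearly tie scores −b from both orientations. The test suite checks
the statistic against an independent brute-force prefix-walk implementation
exhaustively for all sets of size ≤ 4 in universes of size ≤ 12, and asserts
the exact reversal characterization above.

**Combined score.** `es_up` and `es_down` are the ES of the signature's up and
down lists. If they share a sign the instance does not discriminate the two
directions and the combined score is 0; otherwise it is
`(es_up − es_down)/2 ∈ [−1, 1]`. Strongly negative combined scores mean the
compound drives disease-up genes down and disease-down genes up — a signature
reverser. The fixed /2 normalization keeps scores comparable across runs; the
original connectivity-map publication instead rescales by the collection-wide
maximum, which makes scores dataset-relative.

**Replicates.** Profiles are grouped into instances by (perturbagen, dose,
cell line). Per-replicate combined scores are reported verbatim (the "score
distribution" column) and averaged into the mean CMAP score, by which the hit
table is sorted (most negative first). The enrichment score, permutation
p-value and specificity are computed once per instance on the replicate-mean
profile, not per replicate: the mean profile is the better-estimated ranking,
and averaging p-values would have no calibration guarantee.

**Permutation p-value.** The null is generated by drawing `n_permutations`
(default 10,000) random disjoint gene-set pairs of the signature's sizes on
the instance's ranked universe and computing their combined scores; random
sets rather than profile shuffles, because the null hypothesis is "this
signature is no more connected to the profile than an arbitrary gene-set pair
of the same size". Since the null depends on the universe only through its
size, sets are sampled directly as ranks, vectorized in blocks of 2,000
permutations. Two-sided:

    p = (1 + #{ |s_perm| ≥ |s_obs| }) / (1 + n_permutations)

so p ∈ (0, 1] with floor 1/(n_permutations + 1). One calibration property is
worth stating explicitly: the same-sign rule puts a point mass (≈ 1/2 under
the null) at combined = 0, and an observed 0 maps to p = 1. Null p-values are
therefore *sub*-uniform — uniform below ≈ 0.5 with a conservative atom at 1 —
which preserves validity (P(p ≤ α) ≤ α for all α) but means a two-sided
uniformity test would reject by construction. The calibration test
accordingly checks the anti-conservative direction (the empirical CDF of null
p-values must not exceed the uniform CDF; one-sided Kolmogorov test) plus
binomial checks of the lower tail.

**Specificity.** The fraction of the other signatures in the scored
collection whose absolute combined score with the instance is at least the
target's. 0 = no other signature matches as strongly (most unique); 1 = all
do. It is an exceedance fraction, so duplicating a non-target signature's
metadata does not change it, and adding strictly weaker signatures can only
lower it.

## Preclinical quantifications

**Disease Activity Index.** DAI = (body-weight score + stool-consistency
score + fecal-blood score) / 3, each component 0–4. Weight-loss bands (loss
as percent of day-0 weight): <1% → 0, ≥1% and <5% → 1, ≥5% and <10% → 2,
≥10% and <15% → 3, ≥15% → 4. The grading scheme leaves exactly-15% loss
unassigned (band 3 is "<15%", band 4 ">15%"); it is assigned to score 4, the
conservative (more severe) reading. Stool maps normal → 0, loose → 2,
diarrhea → 4; blood maps none → 0, visible → 2, rectal → 4. The scheme leaves
intermediate grades 1 and 3 for these two components undefined, so the
three-category mapping is the default, with numeric override fields for
scorers who use intermediate grades.

**DAI AUC.** Trapezoidal area under the (day, DAI) curve over the observed
days, no extrapolation, strictly increasing days required. Additive over
adjacent intervals and linear in uniform DAI scaling.

**Histopathology composite (0–40).** Three features — inflammation (severity
0–3), extent of damage (0–3), crypt damage (0–4) — each graded with an area
score 1–4 for the fraction of section involved (severity 0 forces area 0).
The composite is the sum of severity × area per feature; per-feature
severity × area summed is the only combination consistent with the scale's
stated maximum of 3·4 + 3·4 + 4·4 = 40.

**MPO.** Myeloperoxidase activity divided by colon tissue mass (units per
gram); the assay chemistry itself is out of scope.

**ΔΔCp.** ΔCp = Cp(GAPDH) − Cp(sample); ΔΔCp = ΔCp(treated) − ΔCp(sham);
fold change = 2^ΔΔCp, so fold change 1 means sham-level expression. Note the
GAPDH-minus-sample orientation: larger ΔCp means higher expression.

**Group summaries** report n, mean, sd and SE = sd/√n per group (ddof = 1;
single-animal groups get NaN spread).

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes, with the ground
truth recorded alongside.

*Disease cohorts*: per-gene log2 baselines ~ N(7, 1); a random
`round(affected_fraction · n_genes)` subset carries zero-centered Gaussian
effects (sd `effect_sd`, sign random, so both signature directions are
populated) added to the disease group; i.i.d. Gaussian noise (sd `noise_sd`)
on every sample. The returned effect vector is the exact expected
disease-minus-normal difference — the truth a signature should recover.

*Compound experiments*: shared baselines, additive per-(batch, gene) offsets
drawn once per batch (sd `batch_sd`), vehicle controls in every
batch × cell-line stratum, and i.i.d. Gaussian noise. A compound carrying an
embedded effect adds `strength ×` (a registered disease effect) on a random
`affected_gene_fraction` of genes; strength −1 is an exact reverser, the
ground truth connectivity scoring must recover. The additive batch/noise
structure is the simplest that makes quantile normalization and batch
correction non-trivial; defaults noise_sd = 0.2 and batch_sd = 0.5 log2 units
are in the range of routine array replicate scatter and batch offsets, and
are exposed in `SimConfig` since real platform magnitudes vary.

*Animal studies*: each group follows a requested mean-DAI trajectory on a
common day grid. A latent severity per animal-day — the trajectory value
times a mean-one lognormal factor combining an animal random effect (log-sd
`dispersion`) and day-level noise (log-sd `dispersion/2`) — is thresholded
into the weight/stool/blood components, so the three components co-vary as
they do biologically and impossible combinations (maximal bleeding with no
weight loss) are rare. The multiplicative form keeps disease-free days at
exactly zero severity. Because components are quantized onto {0,…,4} and
{0,2,4} grids, group mean DAI tracks the requested trajectory only
approximately (within ~0.5 at the defaults).

Not simulated: probe-level microarray artifacts, plate spatial effects,
landmark-to-transcript imputation, non-Gaussian noise, or correlated gene
modules. Passing tests therefore demonstrate that the pipeline's statistics
recover the embedded structure under additive Gaussian conditions; they say
nothing about robustness to heavy-tailed noise or gene–gene correlation in
real data.

## Problem sizes used in the test suite

The recovery check runs a screen of 2,000 genes with 20 null compounds plus
one embedded strength −1 reverser in triplicate, scored at 10,000
permutations; the null-calibration check uses 200 independent null compounds
at 999 permutations each. These sizes make the full suite run in well under a
minute while keeping the permutation floor (1/10,001) and the calibration
tail estimates meaningful.

## Known limitations

- The combined-score same-sign rule discards instances that move both
  signature halves the same way; such instances are genuinely ambiguous, but
  the resulting score atom at 0 makes null p-values conservative (see above).
- Specificity is relative to the scored signature collection; with few
  signatures it is coarse (steps of 1/(collection − 1)).
- Batch correction assumes additive batch effects; multiplicative or
  gene-specific-scale batch artifacts are out of model.
- The statistical inference of the original animal studies (mixed models,
  multiple-comparison procedures) is out of scope; only the descriptive
  scoring formulas are implemented.
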