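"""KS-enrichment connectivity scoring of compound profiles against disease signatures.

The enrichment score (ES) is the classic connectivity-map form of the
Kolmogorov-Smirnov statistic on a ranked gene list. For a gene set of size t
whose members occupy ascending ranks V(1) <= ... <= V(t) in a ranked universe
of n genes::

    a = max_j ( j/t - V(j)/n )
    b = max_j ( V(j)/n - (j-1)/t )
    ES = a  if a > b  else  -b

ES is positive when the set concentrates at the top of the ranking and
negative at the bottom, and lies in [-1, 1].

A compound instance is scored against a signature by computing ES for the
signature's up and down gene lists on the instance's ranked profile and
combining them: if the two ES values share a sign the combined score is 0,
otherwise it is (es_up - es_down) / 2, which lies in [-1, 1]. A combined
score near -1 means the compound pushes disease-up genes down and
disease-down genes up -- a signature reverser.

Permutation p-values are two-sided on |combined|, estimated against random
disjoint gene-set pairs of the same sizes drawn on the fixed ranked profile,
with the +1/(n+1) correction so p is never exactly zero. Specificity is the
fraction of other signatures in a collection that score at least as strongly
(in absolute value) as the target -- lower is more unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sigreverse.processing import TreatmentProfile
from sigreverse.signatures import DiseaseSignature

DEFAULT_N_PERMUTATIONS = 10_000
_PERM_CHUNK = 2_000  # permutations per vectorized block (bounds memory)

HIT_TABLE_COLUMNS = [
    "signature_name",
    "dose",
    "mean_cmap_score",
    "enrichment_score",
    "p_value",
    "specificity",
    "score_distribution",
    "platform",
    "cell_line",
    "disease",
    "tissue",
    "species",
]


@dataclass(frozen=True)
class RankedProfile:
    """A profile's genes ordered most up-regulated first."""

    instance_id: str
    ranked_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ranked_genes)) != len(self.ranked_genes):
            raise ValueError(f"ranked profile {self.instance_id!r} has duplicate genes")

    @property
    def n_genes(self) -> int:
        return len(self.ranked_genes)


@dataclass
class ConnectivityResult:
    """Scores of one compound instance (replicate group) against one signature."""

    instance_id: str
    signature_id: str
    es_up: float
    es_down: float
    combined_score: float
    replicate_scores: list[float]
    mean_cmap_score: float
    p_value: float
    specificity: float
    n_permutations: int
    perturbagen: str = ""
    dose: float = float("nan")
    cell_line: str = ""
    platform: str = ""


def rank_profile(profile: TreatmentProfile) -> RankedProfile:
    """Sort a profile's genes by descending differential value, ties by gene ID."""
    return rank_values(profile.values, instance_id=profile.instance_id)


def rank_values(values: pd.Series, instance_id: str = "") -> RankedProfile:
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError(f"profile {instance_id!r} has non-finite values")
    gene_ids = values.index.to_numpy(dtype=object)
    order = np.lexsort((gene_ids, -arr))
    return RankedProfile(instance_id=instance_id, ranked_genes=tuple(gene_ids[order]))


def _es_from_sorted_ranks(V: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES from ascending 1-based set ranks; V has shape (..., t)."""
    t = V.shape[-1]
    j = np.arange(1, t + 1, dtype=float)
    a = (j / t - V / n).max(axis=-1)
    b = (V / n - (j - 1) / t).max(axis=-1)
    return np.where(a > b, a, -b)


def ks_enrichment(ranked: RankedProfile, gene_set) -> float:
    """KS enrichment score of a gene set on a ranked profile; in [-1, 1]."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene set is empty")
    if len(set(gene_set)) != len(gene_set):
        raise ValueError("gene set contains duplicates")
    position = {g: i + 1 for i, g in enumerate(ranked.ranked_genes)}
    try:
        ranks = np.sort([position[g] for g in gene_set])
    except KeyError as exc:
        raise KeyError(f"gene {exc.args[0]!r} not present in ranked profile "
                       f"{ranked.instance_id!r}") from None
    return float(_es_from_sorted_ranks(ranks.astype(float), ranked.n_genes))


def combine_scores(es_up: float, es_down: float) -> float:
    """Combined connectivity score: 0 when signs agree, else (es_up - es_down)/2."""
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    return (es_up - es_down) / 2.0


def connectivity_score(ranked: RankedProfile, signature: DiseaseSignature) -> tuple[float, float, float]:
    """(es_up, es_down, combined) of a ranked profile against a signature."""
    es_up = ks_enrichment(ranked, signature.up_genes)
    es_down = ks_enrichment(ranked, signature.down_genes)
    return es_up, es_down, combine_scores(es_up, es_down)


def mean_cmap_score(replicate_combined_scores) -> float:
    """Arithmetic mean of the replicate combined scores."""
    scores = list(replicate_combined_scores)
    if not scores:
        raise ValueError("no replicate scores to average")
    return float(np.mean(scores))


def permutation_null_scores(
    n_genes: int,
    t_up: int,
    t_down: int,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Combined scores of random disjoint gene-set pairs on a ranked universe.

    Draws ``n_permutations`` disjoint (up, down) rank-set pairs of sizes
    (t_up, t_down) uniformly from an n-gene universe and returns their
    combined connectivity scores. Because the null depends on the universe
    only through its size, sets are sampled directly as ranks.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    t = t_up + t_down
    if t > n_genes:
        raise ValueError(f"set sizes {t_up}+{t_down} exceed universe size {n_genes}")
    if t_up < 1 or t_down < 1:
        raise ValueError("both set sizes must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    out = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        block = min(_PERM_CHUNK, n_permutations - done)
        keys = rng.random((block, n_genes))
        picks = np.argpartition(keys, t - 1, axis=1)[:, :t] + 1  # 1-based ranks
        # argpartition leaves the chosen ranks in index-biased order; shuffle
        # so the up/down split is uniform over the chosen set
        shuffle = np.argsort(rng.random(picks.shape), axis=1)
        picks = np.take_along_axis(picks, shuffle, axis=1)
        up_ranks = np.sort(picks[:, :t_up], axis=1).astype(float)
        down_ranks = np.sort(picks[:, t_up:], axis=1).astype(float)
        es_up = _es_from_sorted_ranks(up_ranks, n_genes)
        es_down = _es_from_sorted_ranks(down_ranks, n_genes)
        combined = np.where(np.sign(es_up) == np.sign(es_down), 0.0, (es_up - es_down) / 2.0)
        out[done:done + block] = combined
        done += block
    return out


def permutation_pvalue(
    ranked: RankedProfile,
    signature_sizes: tuple[int, int],
    observed_combined: float,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p-value of an observed combined score.

    p = (1 + #{|s_perm| >= |s_obs|}) / (1 + n_permutations), over random
    disjoint gene-set pairs of the signature's sizes on the profile's
    universe; always in (0, 1], floor 1/(n_permutations + 1).
    """
    t_up, t_down = signature_sizes
    null = permutation_null_scores(
        ranked.n_genes, t_up, t_down, n_permutations=n_permutations, rng=rng, seed=seed
    )
    exceed = int(np.sum(np.abs(null) >= abs(observed_combined)))
    return (1 + exceed) / (1 + len(null))


def specificity(
    instance: RankedProfile,
    target: DiseaseSignature,
    collection,
) -> float:
    """Fraction of non-target signatures scoring at least as strongly as the target.

    0 means no other signature in the collection matches the instance as
    strongly (most unique association); 1 means all do.
    """
    collection = list(collection)
    if not collection:
        raise ValueError("signature collection is empty")
    if not any(s.signature_id == target.signature_id for s in collection):
        raise ValueError(f"target {target.signature_id!r} not in collection")
    target_abs = abs(connectivity_score(instance, target)[2])
    others = [s for s in collection if s.signature_id != target.signature_id]
    if not others:
        return 0.0
    n_at_least = sum(
        abs(connectivity_score(instance, s)[2]) >= target_abs for s in others
    )
    return n_at_least / len(others)


def score_screen(
    profiles: list[TreatmentProfile],
    signatures: list[DiseaseSignature],
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    platform: str = "",
    compute_specificity: bool = True,
) -> list[ConnectivityResult]:
    """Score every compound instance against every signature.

    Profiles are grouped into instances by (perturbagen, dose, cell line);
    per-replicate combined scores are reported and averaged into the mean
    CMAP score, while the enrichment scores, permutation p-value and
    specificity are computed on the replicate-mean profile. The permutation
    seed for each (instance, signature) pair is derived deterministically
    from ``seed``.
    """
    if not profiles:
        raise ValueError("no profiles to score")
    if not signatures:
        raise ValueError("no signatures to score against")

    groups: dict[tuple, list[TreatmentProfile]] = {}
    for p in profiles:
        groups.setdefault((p.perturbagen, p.dose, p.cell_line), []).append(p)

    results: list[ConnectivityResult] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.spawn(len(groups) * len(signatures)))
    for (perturbagen, dose, cell_line), reps in sorted(groups.items()):
        reps = sorted(reps, key=lambda p: p.replicate_index)
        instance_id = f"{perturbagen}@{dose}uM:{cell_line}"
        mean_values = pd.concat([p.values for p in reps], axis=1).mean(axis=1)
        mean_ranked = rank_values(mean_values, instance_id=instance_id)
        rep_ranked = [rank_profile(p) for p in reps]
        for sig in signatures:
            rng = np.random.default_rng(next(child_seeds))
            rep_scores = [connectivity_score(r, sig)[2] for r in rep_ranked]
            es_up, es_down, combined = connectivity_score(mean_ranked, sig)
            p_value = permutation_pvalue(
                mean_ranked, (len(sig.up_genes), len(sig.down_genes)), combined,
                n_permutations=n_permutations, rng=rng,
            )
            spec = (
                specificity(mean_ranked, sig, signatures)
                if compute_specificity and len(signatures) > 1
                else 0.0
            )
            results.append(
                ConnectivityResult(
                    instance_id=instance_id,
                    signature_id=sig.signature_id,
                    es_up=es_up,
                    es_down=es_down,
                    combined_score=combined,
                    replicate_scores=rep_scores,
                    mean_cmap_score=mean_cmap_score(rep_scores),
                    p_value=p_value,
                    specificity=spec,
                    n_permutations=n_permutations,
                    perturbagen=perturbagen,
                    dose=dose,
                    cell_line=cell_line,
                    platform=platform,
                )
            )
    return results


def build_hit_table(
    results: list[ConnectivityResult],
    signature_metadata: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Assemble the hit table, sorted most-negative mean CMAP score first.

    Columns follow the reporting layout: signature name, dose, mean CMAP
    score, enrichment score (combined score of the replicate-mean profile),
    permutation p-value, specificity, the per-replicate score distribution,
    platform, cell line, and the signature's disease/tissue/species. Missing
    optional metadata is emitted as empty strings.
    """
    if not results:
        raise ValueError("no results to tabulate")
    signature_metadata = signature_metadata or {}
    rows = []
    for r in results:
        meta = signature_metadata.get(r.signature_id, {})
        rows.append({
            "signature_name": r.signature_id,
            "dose": r.dose,
            "mean_cmap_score": r.mean_cmap_score,
            "enrichment_score": r.combined_score,
            "p_value": r.p_value,
            "specificity": r.specificity,
            "score_distribution": ",".join(f"{s:.4f}" for s in r.replicate_scores),
            "platform": r.platform or "",
            "cell_line": r.cell_line or "",
            "disease": meta.get("disease", "") or "",
            "tissue": meta.get("tissue", "") or "",
            "species": meta.get("species", "") or "",
            "instance_id": r.instance_id,
        })
    table = pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS + ["instance_id"])
    table = table.sort_values(
        ["mean_cmap_score", "signature_name", "instance_id"], kind="mergesort"
    ).reset_index(drop=True)
    return table
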