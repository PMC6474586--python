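"""KS enrichment statistic, combined scores, permutation null, specificity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sigreverse as sr
from sigreverse.processing import TreatmentProfile
from sigreverse.scoring import RankedProfile, rank_values


def walk_es(ranked_genes, gene_set):
    """Independent oracle: direct max over all prefixes of the indicator walk."""
    gene_set = set(gene_set)
    n, t = len(ranked_genes), len(gene_set)
    hits = 0
    a = -np.inf
    b = -np.inf
    for i, gene in enumerate(ranked_genes, start=1):
        b = max(b, i / n - hits / t)  # deviation just before absorbing position i
        if gene in gene_set:
            hits += 1
        a = max(a, hits / t - i / n)
    return a if a > b else -b


def _ranked(genes, instance_id="p"):
    return RankedProfile(instance_id=instance_id, ranked_genes=tuple(genes))


def _profile(values, instance_id="p", perturbagen="drug", dose=10.0,
             cell_line="MCF7", replicate_index=0):
    return TreatmentProfile(instance_id=instance_id, perturbagen=perturbagen,
                            dose=dose, cell_line=cell_line,
                            replicate_index=replicate_index,
                            values=pd.Series(values))


class TestRankProfile:
    def test_descending_sort_contract(self):
        profile = _profile({"A": 2.0, "B": -1.0, "C": 0.0})
        assert sr.rank_profile(profile).ranked_genes == ("A", "C", "B")

    def test_ties_break_lexicographically(self):
        profile = _profile({"B": 0.0, "A": 0.0, "C": -1.0})
        assert sr.rank_profile(profile).ranked_genes == ("A", "B", "C")

    def test_negation_reverses_order_without_ties(self):
        values = {"A": 3.0, "B": 1.5, "C": -0.5, "D": -2.0}
        fwd = sr.rank_profile(_profile(values)).ranked_genes
        rev = sr.rank_profile(_profile({g: -v for g, v in values.items()})).ranked_genes
        assert rev == fwd[::-1]


class TestKsEnrichment:
    def test_singleton_at_top_of_ten(self):
        ranked = _ranked([f"g{i}" for i in range(10)])
        assert sr.ks_enrichment(ranked, ["g0"]) == pytest.approx(0.9)

    def test_singleton_at_bottom_of_ten(self):
        ranked = _ranked([f"g{i}" for i in range(10)])
        assert sr.ks_enrichment(ranked, ["g9"]) == pytest.approx(-1.0)

    def test_uniformly_interleaved_set_scores_near_zero(self):
        n, step = 12, 3
        ranked = _ranked([f"g{i}" for i in range(n)])
        evenly = [f"g{i}" for i in range(1, n, step)]
        es = sr.ks_enrichment(ranked, evenly)
        assert abs(es) <= 1 / len(evenly) + 1 / n + 1e-12

    def test_exhaustive_agreement_with_prefix_walk_oracle(self):
        for n in range(2, 13):
            genes = [f"g{i:02d}" for i in range(n)]
            ranked = _ranked(genes)
            for t in range(1, min(4, n) + 1):
                for combo in itertools.combinations(genes, t):
                    assert sr.ks_enrichment(ranked, list(combo)) == pytest.approx(
                        walk_es(genes, combo)), (n, combo)

    def test_absent_gene_is_named_in_error(self):
        ranked = _ranked(["a", "b"])
        with pytest.raises(KeyError, match="zzz"):
            sr.ks_enrichment(ranked, ["zzz"])

    def test_empty_set_fails(self):
        with pytest.raises(ValueError, match="empty"):
            sr.ks_enrichment(_ranked(["a", "b"]), [])

    @given(st.integers(5, 40), st.data())
    def test_reversal_negation_follows_the_grid_characterization(self, n, data):
        # the a/b prefix form is asymmetric on the rank grid: reversal maps
        # (a, b) to (b - 1/n, a + 1/n), so es_rev + es_fwd = -1/n generically,
        # and -(a + b + 1/n) in the near-tie band a < b <= a + 2/n where both
        # orientations take the -b branch
        genes = [f"g{i:02d}" for i in range(n)]
        t = data.draw(st.integers(1, n))
        subset = data.draw(st.permutations(genes).map(lambda p: p[:t]))
        ranks = sorted(genes.index(g) + 1 for g in subset)
        a = max(j / t - v / n for j, v in enumerate(ranks, 1))
        b = max(v / n - (j - 1) / t for j, v in enumerate(ranks, 1))
        es_fwd = sr.ks_enrichment(_ranked(genes), subset)
        es_rev = sr.ks_enrichment(_ranked(genes[::-1]), subset)
        if a > b or b > a + 2 / n:
            expected = -1 / n
        else:
            expected = -(a + b + 1 / n)
        assert es_rev + es_fwd == pytest.approx(expected, abs=1e-12)


class TestCombinedScore:
    def test_same_sign_scores_combine_to_zero(self):
        assert sr.combine_scores(0.4, 0.7) == 0.0
        assert sr.combine_scores(-0.4, -0.7) == 0.0

    def test_opposite_signs_average(self):
        assert sr.combine_scores(0.8, -0.6) == pytest.approx(0.7)
        assert sr.combine_scores(-0.8, 0.6) == pytest.approx(-0.7)

    def test_perfect_reverser_approaches_minus_one(self):
        n, t = 10_000, 250
        genes = [f"g{i:05d}" for i in range(n)]
        up = genes[-t:]      # disease-up genes at the bottom of the profile
        down = genes[:t]     # disease-down genes at the top
        sig = sr.DiseaseSignature("s", tuple(up), tuple(down), t)
        es_up, es_down, combined = sr.connectivity_score(_ranked(genes), sig)
        assert combined == pytest.approx(-1.0, abs=2 * (t / n + 1 / t))
        mirror = sr.DiseaseSignature("s", tuple(down), tuple(up), t)
        _, _, combined_fwd = sr.connectivity_score(_ranked(genes), mirror)
        assert combined_fwd == pytest.approx(-combined)


class TestMeanScore:
    def test_mean_and_identity(self):
        assert sr.mean_cmap_score([-0.9, -0.8, -1.0]) == pytest.approx(-0.9)
        assert sr.mean_cmap_score([0.37]) == 0.37

    def test_empty_replicates_fail(self):
        with pytest.raises(ValueError):
            sr.mean_cmap_score([])


class TestPermutationPvalue:
    def test_zero_observation_gives_p_one(self):
        ranked = _ranked([f"g{i:03d}" for i in range(100)])
        p = sr.permutation_pvalue(ranked, (5, 5), 0.0, n_permutations=200, seed=1)
        assert p == 1.0

    def test_unbeatable_observation_hits_the_floor(self):
        ranked = _ranked([f"g{i:03d}" for i in range(100)])
        p = sr.permutation_pvalue(ranked, (5, 5), 1.0, n_permutations=1000, seed=1)
        assert p == pytest.approx(1 / 1001)

    def test_seeded_reproducibility(self):
        ranked = _ranked([f"g{i:03d}" for i in range(50)])
        p1 = sr.permutation_pvalue(ranked, (4, 4), 0.3, n_permutations=500, seed=9)
        p2 = sr.permutation_pvalue(ranked, (4, 4), 0.3, n_permutations=500, seed=9)
        assert p1 == p2

    def test_oversized_sets_fail(self):
        ranked = _ranked(["a", "b", "c"])
        with pytest.raises(ValueError, match="exceed"):
            sr.permutation_pvalue(ranked, (2, 2), 0.1)

    def test_null_scores_match_direct_enumeration_in_distribution(self):
        # moments of the sampled null agree with scoring explicit random sets
        rng = np.random.default_rng(3)
        genes = [f"g{i:03d}" for i in range(60)]
        ranked = _ranked(genes)
        direct = []
        for _ in range(2000):
            picks = rng.choice(60, size=10, replace=False)
            up = [genes[i] for i in picks[:5]]
            down = [genes[i] for i in picks[5:]]
            es_up = sr.ks_enrichment(ranked, up)
            es_down = sr.ks_enrichment(ranked, down)
            direct.append(sr.combine_scores(es_up, es_down))
        sampled = sr.permutation_null_scores(60, 5, 5, 2000, seed=4)
        assert np.mean(np.abs(sampled)) == pytest.approx(np.mean(np.abs(direct)), rel=0.1)
        assert np.mean(sampled == 0) == pytest.approx(np.mean(np.asarray(direct) == 0), abs=0.06)

    def test_null_scores_are_sign_symmetric(self):
        null = sr.permutation_null_scores(200, 10, 10, 500, seed=8)
        nonzero = null[null != 0]
        n_pos = int((nonzero > 0).sum())
        from scipy.stats import binomtest
        assert binomtest(n_pos, len(nonzero), 0.5).pvalue > 0.01


class TestSpecificity:
    def _signature(self, genes, sig_id):
        return sr.DiseaseSignature(sig_id, tuple(genes[:2]), tuple(genes[2:4]), 2)

    def test_singleton_collection_scores_zero(self):
        genes = [f"g{i}" for i in range(20)]
        sig = self._signature(genes, "t")
        assert sr.specificity(_ranked(genes), sig, [sig]) == 0.0

    def test_exact_reverser_is_most_unique(self):
        rng = np.random.default_rng(0)
        n, t = 500, 25
        genes = [f"g{i:03d}" for i in range(n)]
        target = sr.DiseaseSignature("target", tuple(genes[-t:]), tuple(genes[:t]), t)
        collection = [target]
        for k in range(8):
            picks = rng.choice(n, size=2 * t, replace=False)
            collection.append(sr.DiseaseSignature(
                f"rand{k}", tuple(genes[i] for i in picks[:t]),
                tuple(genes[i] for i in picks[t:]), t))
        assert sr.specificity(_ranked(genes), target, collection) == 0.0

    def test_identical_scores_everywhere_give_one(self):
        genes = [f"g{i}" for i in range(20)]
        target = self._signature(genes, "t")
        clones = [target] + [
            sr.DiseaseSignature(f"c{k}", target.up_genes, target.down_genes, 2)
            for k in range(3)]
        assert sr.specificity(_ranked(genes), target, clones) == 1.0

    def test_adding_weaker_signatures_never_raises_specificity(self):
        rng = np.random.default_rng(1)
        n, t = 400, 20
        genes = [f"g{i:03d}" for i in range(n)]
        target = sr.DiseaseSignature("target", tuple(genes[-t:]), tuple(genes[:t]), t)
        ranked = _ranked(genes)
        collection = [target]
        prev = sr.specificity(ranked, target, collection)
        for k in range(6):
            picks = rng.choice(n, size=2 * t, replace=False)
            collection.append(sr.DiseaseSignature(
                f"rand{k}", tuple(genes[i] for i in picks[:t]),
                tuple(genes[i] for i in picks[t:]), t))
            curr = sr.specificity(ranked, target, collection)
            assert curr <= prev + 1e-12
            prev = curr

    def test_empty_collection_fails(self):
        genes = [f"g{i}" for i in range(20)]
        with pytest.raises(ValueError, match="empty"):
            sr.specificity(_ranked(genes), self._signature(genes, "t"), [])


class TestHitTable:
    def _result(self, mean, sig="s1", inst="i1", reps=(-0.9, -0.8, -1.0)):
        return sr.ConnectivityResult(
            instance_id=inst, signature_id=sig, es_up=-0.5, es_down=0.5,
            combined_score=mean, replicate_scores=list(reps),
            mean_cmap_score=mean, p_value=0.01, specificity=0.0,
            n_permutations=100, perturbagen="d", dose=10.0, cell_line="MCF7")

    def test_most_negative_mean_score_sorts_first(self):
        table = sr.build_hit_table([self._result(-0.2, inst="weak"),
                                    self._result(-0.9, inst="strong")])
        assert table.iloc[0]["instance_id"] == "strong"

    def test_replicate_distribution_lists_all_scores(self):
        table = sr.build_hit_table([self._result(-0.9)])
        assert table.iloc[0]["score_distribution"].count(",") == 2

    def test_missing_metadata_becomes_empty_strings(self):
        table = sr.build_hit_table([self._result(-0.9)])
        assert table.iloc[0]["disease"] == ""
        assert table.iloc[0]["tissue"] == ""
        assert list(table.columns[:12]) == sr.scoring.HIT_TABLE_COLUMNS


class TestScreenRecovery:
    def test_embedded_reverser_wins_and_null_scores_are_symmetric(self, small_cohort, small_signature):
        cfg = sr.SimConfig(n_genes=600, n_compounds=6, noise_sd=0.05, seed=10)
        matrix, metadata, _ = sr.generate_compound_experiment(
            cfg, [sr.EmbeddedEffect("uc", strength=-1.0)],
            {"uc": small_cohort.effect})
        profiles = sr.treatment_to_control(matrix, metadata)
        results = sr.score_screen(profiles, [small_signature],
                                  n_permutations=200, seed=0)
        best = min(results, key=lambda r: r.mean_cmap_score)
        assert best.instance_id.startswith("cmpd_000")
        assert best.mean_cmap_score < -0.1
        assert best.p_value == min(r.p_value for r in results)
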