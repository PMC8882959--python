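"""Alpha/beta diversity estimators, rarefaction and shared-OTU summaries.

scikit-bio serves as the independent oracle for the estimator semantics on
random inputs; hand-derived values pin the documented conventions.
"""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from skbio import TreeNode
from skbio.diversity import alpha as sk_alpha

import phylosym as ps
from phylosym import diversity as dv
from phylosym.errors import (
    DepthExceedsSampleError,
    InvalidArgumentError,
    MetadataMismatchError,
    MissingTaxaError,
    UndefinedStatisticError,
)

count_vectors = st.lists(st.integers(min_value=0, max_value=40), min_size=2,
                         max_size=25).filter(lambda v: sum(v) > 0)


# ------------------------------------------------------------------ rarefaction


class TestRarefy:
    def test_min_rule_and_conservation(self, small_table, rng):
        rare = dv.rarefy_table(small_table, depth="min", seed=1)
        target = int(small_table.sample_totals().min())
        assert (rare.sample_totals() == target).all()
        assert list(rare.otu_ids) == list(small_table.otu_ids)

    def test_sample_at_exact_depth_unchanged(self):
        counts = pd.DataFrame({"s1": [500], "s2": [80]}, index=["o1"])
        rare = dv.rarefy_table(ps.OTUTable(counts), depth=80, seed=0)
        assert rare.counts.loc["o1", "s1"] == 80
        assert rare.counts.loc["o1", "s2"] == 80

    def test_depth_exceeding_sample_names_it(self, small_table):
        with pytest.raises(DepthExceedsSampleError) as err:
            dv.rarefy_table(small_table, depth=10_000)
        assert err.value.sample_id in small_table.sample_ids

    def test_deterministic_given_seed(self, small_table):
        a = dv.rarefy_table(small_table, depth=50, seed=11)
        b = dv.rarefy_table(small_table, depth=50, seed=11)
        assert a.counts.equals(b.counts)

    def test_subsample_never_exceeds_original(self, small_table):
        rare = dv.rarefy_table(small_table, depth=50, seed=2)
        assert (rare.counts.to_numpy() <= small_table.counts.to_numpy()).all()


class TestRarefactionCurve:
    def test_depth_one_and_full_depth(self, small_table):
        tot = int(small_table.sample_totals().min())
        curve = dv.rarefaction_curve(small_table, [1, tot], reps=5, seed=3)
        assert (curve[1] == 1.0).all()
        full = (small_table.counts > 0).sum(axis=0)
        sid = small_table.sample_ids[0]
        if small_table.sample_totals()[sid] == tot:
            assert curve.loc[sid, tot] == full[sid]

    def test_mean_curve_nondecreasing(self, small_table):
        curve = dv.rarefaction_curve(small_table, [5, 20, 50, 80], reps=50, seed=4)
        arr = curve.to_numpy()
        valid = ~np.isnan(arr)
        for row, v in zip(arr, valid):
            vals = row[v]
            assert (np.diff(vals) >= -1e-9).all()

    def test_reps_validation(self, small_table):
        with pytest.raises(InvalidArgumentError):
            dv.rarefaction_curve(small_table, [5], reps=0)


# ------------------------------------------------------------------------ alpha


class TestAlphaDiversity:
    def test_hand_derived_spot_values(self):
        # F1=2, F2=1 in both chao1 forms; two equiprobable categories
        assert dv.alpha_diversity([5, 1, 1, 2], "observed") == 4
        assert dv.alpha_diversity([5, 1, 1, 2], "chao1") == pytest.approx(4.5)
        assert dv.chao1([5, 1, 1, 2], bias_corrected=False) == pytest.approx(6.0)
        assert dv.alpha_diversity([1, 1], "shannon") == pytest.approx(1.0)
        assert dv.alpha_diversity([1, 1], "simpson") == pytest.approx(0.5)

    def test_faith_pd_includes_root_path(self, toy_tree):
        got = dv.faith_pd([1, 1, 0, 0], list("ABCD"), toy_tree)
        assert got == pytest.approx(3.0)  # two pendants + their stem

    def test_faith_pd_missing_taxa_listed(self, toy_tree):
        with pytest.raises(MissingTaxaError) as err:
            dv.faith_pd([1, 1], ["A", "Z"], toy_tree)
        assert err.value.missing == ["Z"]

    def test_all_zero_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            dv.alpha_diversity([0, 0, 0], "shannon")

    def test_shannon_maximal_at_uniform(self):
        k = 16
        h_uniform = dv.shannon([10] * k)
        assert h_uniform == pytest.approx(np.log2(k))
        assert dv.shannon([50, 10, 3, 1] + [10] * (k - 4)) < h_uniform

    def test_shannon_natural_log_option(self):
        assert dv.shannon([1, 1], base=np.e) == pytest.approx(np.log(2))

    def test_simpson_inverse_option(self):
        assert dv.simpson([1, 1], variant="inverse") == pytest.approx(2.0)

    @given(count_vectors)
    def test_estimators_match_scikit_bio(self, vec):
        vec = np.array(vec)
        assert dv.observed_species(vec) == sk_alpha.observed_features(vec)
        assert dv.chao1(vec) == pytest.approx(sk_alpha.chao1(vec))
        assert dv.shannon(vec, base=np.e) == pytest.approx(sk_alpha.shannon(vec))
        assert dv.simpson(vec) == pytest.approx(sk_alpha.simpson(vec))

    @given(count_vectors)
    def test_richness_estimators_at_least_observed(self, vec):
        vec = np.array(vec)
        s_obs = dv.observed_species(vec)
        assert dv.chao1(vec) >= s_obs
        rare = vec[(vec > 0) & (vec <= dv.ACE_RARE_CUTOFF)]
        if len(rare) and rare.sum() > (rare == 1).sum():
            assert dv.ace(vec) >= s_obs - 1e-9

    def test_ace_matches_scikit_bio_on_mixed_vector(self, rng):
        for _ in range(20):
            vec = rng.integers(0, 30, size=15)
            vec[0] = 25  # ensure an abundant OTU
            if (vec == 1).sum() == vec[vec <= 10].sum():
                continue
            assert dv.ace(vec) == pytest.approx(sk_alpha.ace(vec))

    def test_ace_all_singletons_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            dv.ace([1, 1, 1])

    def test_faith_pd_matches_scikit_bio(self, rng):
        otus = [f"O{i}" for i in range(10)]
        tree = ps.simulate_bacterial_tree(otus, seed=8)
        sk_tree = TreeNode.read(io.StringIO(ps.write_newick(tree)))
        for _ in range(10):
            vec = rng.integers(0, 5, size=10)
            if vec.sum() == 0:
                continue
            mine = dv.faith_pd(vec, otus, tree)
            theirs = sk_alpha.faith_pd(vec, taxa=otus, tree=sk_tree)
            assert mine == pytest.approx(theirs)


# ------------------------------------------------------------------------- beta


class TestBetaDistance:
    def test_identity_for_all_metrics(self, toy_tree):
        x = np.array([3, 1, 0, 2])
        for metric in dv.BETA_METRICS:
            d = dv.beta_distance(x, x, metric, tree=toy_tree, otu_ids=list("ABCD"))
            assert d == pytest.approx(0.0)

    def test_bray_curtis_hand_value(self):
        assert dv.beta_distance([2, 2], [1, 3], "bray_curtis") == pytest.approx(0.25)

    def test_unifrac_toy_tree_values(self, toy_tree):
        x, y = [1, 0, 0, 0], [0, 1, 0, 0]
        uu = dv.beta_distance(x, y, "unweighted_unifrac", tree=toy_tree,
                              otu_ids=list("ABCD"))
        wu = dv.beta_distance(x, y, "weighted_unifrac", tree=toy_tree,
                              otu_ids=list("ABCD"))
        wu_raw = dv.beta_distance(x, y, "weighted_unifrac", tree=toy_tree,
                                  otu_ids=list("ABCD"), normalized=False)
        assert uu == pytest.approx(2 / 3)
        assert wu == pytest.approx(0.5)
        assert wu_raw == pytest.approx(2.0)

    def test_both_zero_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            dv.beta_distance([0, 0], [0, 0], "bray_curtis")

    @given(count_vectors, count_vectors)
    def test_metric_axioms_on_random_vectors(self, x, y):
        k = min(len(x), len(y))
        x, y = np.array(x[:k]), np.array(y[:k])
        if x.sum() == 0 or y.sum() == 0:
            return
        for metric in ("bray_curtis", "binary_jaccard"):
            dxy = dv.beta_distance(x, y, metric)
            dyx = dv.beta_distance(y, x, metric)
            assert dxy == pytest.approx(dyx)
            assert 0.0 <= dxy <= 1.0

    def test_unifrac_bounds_and_symmetry(self, rng):
        otus = [f"O{i}" for i in range(8)]
        tree = ps.simulate_bacterial_tree(otus, seed=21)
        for _ in range(20):
            x = rng.integers(0, 10, size=8)
            y = rng.integers(0, 10, size=8)
            if x.sum() == 0 or y.sum() == 0:
                continue
            for metric in ("unweighted_unifrac", "weighted_unifrac"):
                dxy = dv.beta_distance(x, y, metric, tree=tree, otu_ids=otus)
                dyx = dv.beta_distance(y, x, metric, tree=tree, otu_ids=otus)
                assert dxy == pytest.approx(dyx)
                assert 0.0 <= dxy <= 1.0 + 1e-12

    def test_star_tree_unweighted_unifrac_equals_jaccard(self, rng):
        # unit pendant branches only: unique/observed branch length reduces
        # to the complement of presence-overlap
        k = 10
        otus = [f"O{i}" for i in range(k)]
        star = ps.parse_newick("(" + ",".join(f"{o}:1" for o in otus) + ");")
        for _ in range(25):
            x = rng.integers(0, 3, size=k)
            y = rng.integers(0, 3, size=k)
            if x.sum() == 0 or y.sum() == 0:
                continue
            uu = dv.beta_distance(x, y, "unweighted_unifrac", tree=star, otu_ids=otus)
            bj = dv.beta_distance(x, y, "binary_jaccard")
            assert uu == pytest.approx(bj)


class TestDistanceMatrix:
    def test_identical_samples_zero_matrix(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [1, 2]}, index=["o1", "o2"])
        dm = dv.distance_matrix(ps.OTUTable(counts), "bray_curtis")
        assert np.allclose(dm.data, 0.0)

    def test_matches_elementwise_beta_distance(self, small_table, toy_tree):
        tree = ps.simulate_bacterial_tree(small_table.otu_ids, seed=5)
        for metric in dv.BETA_METRICS:
            dm = dv.distance_matrix(small_table, metric, tree=tree)
            X = small_table.counts.to_numpy().T
            for i, si in enumerate(small_table.sample_ids):
                for j, sj in enumerate(small_table.sample_ids):
                    if i >= j:
                        continue
                    d = dv.beta_distance(X[i], X[j], metric, tree=tree,
                                         otu_ids=small_table.otu_ids)
                    assert dm[(si, sj)] == pytest.approx(d)

    def test_label_equivariance_under_sample_permutation(self, small_table):
        dm = dv.distance_matrix(small_table, "bray_curtis")
        perm = list(reversed(small_table.sample_ids))
        shuffled = ps.OTUTable(small_table.counts[perm], small_table.taxonomy)
        dm2 = dv.distance_matrix(shuffled, "bray_curtis")
        assert np.allclose(dm2.filter(dm.ids).data, dm.data)


class TestCollapseToPopulations:
    def test_singleton_populations_passthrough(self):
        from skbio.stats.distance import DistanceMatrix as DM

        frame = pd.DataFrame(
            {"population": ["A", "B"], "endosymbiont_status": ["uninfected"] * 2},
            index=["a1", "b1"],
        )
        dm = DM([[0, 0.4], [0.4, 0]], ids=["a1", "b1"])
        pop = dv.collapse_to_populations(dm, ps.SampleMetadata(frame))
        assert pop[("A", "B")] == pytest.approx(0.4)

    def test_mean_rule(self):
        from skbio.stats.distance import DistanceMatrix as DM

        frame = pd.DataFrame(
            {"population": ["A", "A", "B"], "endosymbiont_status": ["uninfected"] * 3},
            index=["a1", "a2", "b1"],
        )
        mat = np.array([[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]])
        pop = dv.collapse_to_populations(DM(mat, ids=["a1", "a2", "b1"]),
                                         ps.SampleMetadata(frame))
        assert pop[("A", "B")] == pytest.approx(0.7)

    def test_unmapped_sample_raises(self, small_table, small_metadata):
        dm = dv.distance_matrix(small_table, "bray_curtis")
        meta = ps.SampleMetadata(small_metadata.frame.drop(index=["P3_s2"]))
        with pytest.raises(MetadataMismatchError):
            dv.collapse_to_populations(dm, meta)


# ------------------------------------------------------------- shared OTUs etc


class TestSharedOtus:
    def test_toy_core_and_fractions(self):
        counts = pd.DataFrame(
            {"p1_s": [1, 1, 1, 0], "p2_s": [0, 1, 1, 1]},
            index=["o1", "o2", "o3", "o4"],
        )
        frame = pd.DataFrame(
            {"population": ["pop1", "pop2"], "endosymbiont_status": ["uninfected"] * 2},
            index=["p1_s", "p2_s"],
        )
        res = dv.shared_otus(ps.OTUTable(counts), ps.SampleMetadata(frame))
        assert res.core_otus == ["o2", "o3"]
        assert res.shared_percent["pop1"] == pytest.approx(100 * 2 / 3)
        assert res.shared_percent["pop2"] == pytest.approx(100 * 2 / 3)

    def test_single_population_core_is_everything_present(self, small_table):
        frame = pd.DataFrame(
            {
                "population": ["only"] * 6,
                "endosymbiont_status": ["uninfected"] * 6,
            },
            index=small_table.sample_ids,
        )
        res = dv.shared_otus(small_table, ps.SampleMetadata(frame))
        present = (small_table.counts.sum(axis=1) > 0).sum()
        assert len(res.core_otus) == present
        assert res.shared_percent["only"] == pytest.approx(100.0)

    def test_otu_missing_from_one_population_excluded(self, small_table, small_metadata):
        res = dv.shared_otus(small_table, small_metadata)
        # OTU_6 (endosymbiont) absent from P3 => not core
        assert "OTU_6" not in res.core_otus
        # OTU_2 present everywhere => core
        assert "OTU_2" in res.core_otus

    def test_strict_mode_is_subset_of_pooled_mode(self, small_table, small_metadata):
        pooled = set(dv.shared_otus(small_table, small_metadata, mode="any").core_otus)
        strict = set(dv.shared_otus(small_table, small_metadata, mode="all").core_otus)
        assert strict <= pooled


class TestEndosymbiontProportion:
    def test_matching_sum_rule(self, small_table):
        prop = dv.endosymbiont_proportion(small_table, target="Wolbachia")
        expected = small_table.counts.loc["OTU_6"] / small_table.sample_totals()
        assert np.allclose(prop, expected)

    def test_no_match_gives_zero(self, small_table):
        prop = dv.endosymbiont_proportion(small_table, target="Buchnera")
        assert (prop == 0).all()

    def test_multiple_matching_otus_aggregate(self):
        counts = pd.DataFrame({"s": [30, 20, 50]}, index=["o1", "o2", "o3"])
        tax = pd.Series(
            ["g__Wolbachia; s__a", "g__Wolbachia; s__b", "g__Other"],
            index=counts.index,
        )
        prop = dv.endosymbiont_proportion(ps.OTUTable(counts, tax))
        assert prop["s"] == pytest.approx(0.5)

    def test_requires_taxonomy(self):
        counts = pd.DataFrame({"s": [1]}, index=["o1"])
        with pytest.raises(InvalidArgumentError):
            dv.endosymbiont_proportion(ps.OTUTable(counts))
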