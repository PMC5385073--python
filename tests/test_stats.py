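"""Diversity, ordination, group tests, PERMANOVA, effect size, reporter score."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import metagut as mg
from metagut.errors import (
    EmptySampleError,
    InvalidInputError,
    MissingFeatureError,
    UndefinedEffectError,
)
from metagut.stats import ComparisonResult, adjust_pvalues, comparison_frame

from oracles import hommel_closed_testing, permanova_by_hand


def profile(rows, samples=None, level="gene"):
    rows = np.atleast_2d(rows)
    samples = samples or [f"s{i}" for i in range(len(rows))]
    data = pd.DataFrame(rows, index=samples, columns=[f"f{j}" for j in range(rows.shape[1])])
    if level == "gene":
        data = data.div(data.sum(axis=1), axis=0)
    return mg.AbundanceProfile(data, level=level)


class TestShannon:
    def test_uniform_closed_form(self):
        prof = profile(np.full((1, 128), 1.0))
        assert mg.shannon(prof).iloc[0] == pytest.approx(math.log(128))

    def test_single_feature_zero(self):
        prof = profile([[1.0, 0.0, 0.0]])
        assert mg.shannon(prof).iloc[0] == 0.0

    def test_hand_evaluated_mixture(self):
        prof = profile([[0.5, 0.25, 0.25]])
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert mg.shannon(prof).iloc[0] == pytest.approx(expected)
        assert mg.shannon(prof).iloc[0] == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_row_rejected(self):
        data = pd.DataFrame([[0.0, 0.0]], index=["s"], columns=["a", "b"])
        prof = mg.AbundanceProfile(data, level="gene", empty_samples=frozenset({"s"}))
        with pytest.raises(EmptySampleError):
            mg.shannon(prof)

    def test_bounded_by_log_richness(self, rng):
        values = rng.dirichlet(np.ones(40), size=6)
        h = mg.shannon(profile(values))
        assert ((h >= 0) & (h <= math.log(40) + 1e-12)).all()


class TestRichness:
    def make_counts(self, x):
        x = np.asarray(x)
        return mg.CountTable(
            pd.DataFrame({"s": x}, index=[f"g{i}" for i in range(len(x))]),
            pd.Series(500, index=[f"g{i}" for i in range(len(x))]),
        )

    def test_gene_count_examples(self):
        assert mg.gene_count(self.make_counts([0, 0, 0]))["s"] == 0
        assert mg.gene_count(self.make_counts([5, 0, 0]))["s"] == 1

    def test_downsampled_count_never_exceeds_full(self, rng):
        counts = self.make_counts(rng.integers(0, 30, size=50))
        full = mg.gene_count(counts)["s"]
        for seed in range(5):
            sub = mg.gene_count(counts, depth=100, seed=seed)["s"]
            assert sub <= full

    def test_chao1_no_singletons_equals_observed(self):
        assert mg.chao1(s_obs=100, f1=0, f2=3) == 100

    def test_chao1_hand_evaluated(self):
        assert mg.chao1(s_obs=100, f1=10, f2=5) == 110

    def test_chao1_bias_corrected_when_no_doubletons(self):
        assert mg.chao1(s_obs=50, f1=4, f2=0) == 50 + 4 * 3 / 2

    def test_chao1_negative_rejected(self):
        with pytest.raises(InvalidInputError):
            mg.chao1(10, -1, 0)

    def test_chao1_at_least_observed(self, rng):
        counts = rng.integers(0, 5, size=200)
        assert mg.chao1_from_counts(counts) >= (counts > 0).sum()

    def test_ice_at_least_observed(self, rng):
        inc = (rng.random((100, 20)) < 0.15).astype(int)
        s_obs = (inc.sum(axis=1) > 0).sum()
        assert mg.ice(inc) >= s_obs

    def test_ice_complete_census_equals_observed(self):
        inc = np.ones((30, 15), dtype=int)  # every feature in every sample
        assert mg.ice(inc) == 30

    def test_rarefaction_non_decreasing(self, rng):
        counts = self.make_counts(rng.integers(0, 40, size=80))
        curve = mg.rarefaction(counts, depths=[50, 200, 500, 1000], reps=5, seed=1)
        values = curve.loc["s"].to_numpy()
        assert (np.diff(values) >= 0).all()


class TestSorensenDice:
    def test_examples(self):
        assert mg.sorensen_dice({1, 2}, {1, 2}) == 1.0
        assert mg.sorensen_dice({1, 2}, {3, 4}) == 0.0
        assert mg.sorensen_dice(set(), set()) == 0.0
        assert mg.sorensen_dice({1, 2, 3, 4}, {3, 4, 5, 6, 7, 2}) == pytest.approx(0.6)

    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    @settings(derandomize=True, max_examples=30)
    def test_symmetric_and_bounded(self, a, b):
        d = mg.sorensen_dice(a, b)
        assert d == mg.sorensen_dice(b, a)
        assert 0.0 <= d <= 1.0


class TestPcoa:
    def test_identical_samples_collapse_to_origin(self):
        prof = profile(np.tile([0.2, 0.3, 0.5], (4, 1)))
        res = mg.pcoa(prof)
        assert res.coordinates.to_numpy().size == 0 or np.allclose(
            res.coordinates.to_numpy(), 0.0
        )

    def test_right_triangle_distances_reproduced(self):
        dist = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        from skbio.stats.ordination import pcoa as sk_pcoa

        res = sk_pcoa(dist, method="eigh")
        coords = res.samples.to_numpy()
        from scipy.spatial.distance import pdist, squareform

        assert np.allclose(squareform(pdist(coords)), dist, atol=1e-8)

    def test_euclidean_coordinates_recovered_up_to_rotation(self, rng):
        points = rng.normal(size=(6, 3))
        data = pd.DataFrame(np.abs(points), index=[f"s{i}" for i in range(6)])
        prof = mg.AbundanceProfile(data.div(data.sum(axis=1), axis=0), level="gene")
        res = mg.pcoa(prof, transform="none", metric="euclidean")
        from scipy.spatial.distance import pdist

        got = pdist(res.coordinates.to_numpy())
        want = pdist(prof.data.to_numpy())
        assert np.allclose(got, want, atol=1e-8)

    def test_eigenvalues_non_increasing(self, community_with_effects):
        res = mg.pcoa(mg.AbundanceProfile(community_with_effects.abundances))
        eig = res.eigenvalues
        assert (np.diff(eig) <= 1e-9).all()

    def test_too_few_samples_rejected(self):
        prof = profile([[0.5, 0.5], [0.4, 0.6]])
        with pytest.raises(InvalidInputError):
            mg.pcoa(prof)


class TestWilcoxon:
    def test_exact_p_for_separated_triples(self):
        # feature f0 takes values (1,2,3) vs (10,11,12) out of a 20-unit total
        x = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        prof = profile(np.column_stack([x, 20.0 - x]), samples=list("abcdef"))
        groups = dict(zip("abcdef", ["g1"] * 3 + ["g2"] * 3))
        res = mg.wilcoxon_compare(prof, groups, correction="bh")
        assert res[0].p_value == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        data = pd.DataFrame(
            {"f0": [0.5] * 6, "f1": [0.5] * 6}, index=[f"s{i}" for i in range(6)]
        )
        prof = mg.AbundanceProfile(data, level="gene")
        groups = {f"s{i}": "A" if i < 3 else "B" for i in range(6)}
        res = mg.wilcoxon_compare(prof, groups)
        assert all(r.p_value == 1.0 and r.direction == "none" for r in res)

    def test_small_group_rejected(self):
        prof = profile([[0.5, 0.5]] * 3)
        with pytest.raises(InvalidInputError):
            mg.wilcoxon_compare(prof, {"s0": "A", "s1": "B", "s2": "B"})

    def test_hommel_matches_closed_testing_enumeration(self, rng):
        for _ in range(5):
            p = rng.uniform(0.001, 0.5, size=4)
            assert np.allclose(adjust_pvalues(p, "hommel"), hommel_closed_testing(p))

    def test_hommel_example_triple(self):
        got = adjust_pvalues([0.01, 0.02, 0.04], "hommel")
        assert np.allclose(got, hommel_closed_testing([0.01, 0.02, 0.04]))
        assert np.allclose(got, [0.03, 0.04, 0.04])

    @given(st.lists(st.floats(0.0001, 1.0), min_size=2, max_size=8))
    @settings(derandomize=True, max_examples=30)
    def test_adjusted_monotone_in_raw(self, p_values):
        for method in ("hommel", "bh"):
            adj = adjust_pvalues(p_values, method)
            order = np.argsort(p_values)
            assert (np.diff(adj[order]) >= -1e-12).all()
            assert (adj >= np.asarray(p_values) - 1e-12).all()
            assert (adj <= 1.0 + 1e-12).all()

    def test_comparison_frame_columns(self):
        res = [ComparisonResult("f0", 1.0, 2.0, 0.1, 0.2, -50.0, "higher-in-B")]
        frame = comparison_frame(res)
        assert list(frame.columns) == [
            "feature", "mean_a", "mean_b", "p", "p_adjusted", "effect_pct", "direction",
        ]


class TestEffectSize:
    def test_examples(self):
        assert mg.effect_size(0.5, 0.5) == 0.0
        assert mg.effect_size(2.0, 1.0) == 100.0
        assert mg.effect_size(0.03, 0.04) == pytest.approx(-25.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(UndefinedEffectError):
            mg.effect_size(0.1, 0.0)


class TestPermanova:
    def toy(self):
        rng = np.random.default_rng(99)
        a = rng.normal(0, 1, size=(3, 4))
        b = rng.normal(5, 1, size=(3, 4))
        pts = np.vstack([a, b])
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(pts)), ["A"] * 3 + ["B"] * 3

    def test_pseudo_f_matches_hand_partition(self):
        dist, labels = self.toy()
        f, _ = mg.permanova(dist, labels, n_perm=99, seed=1)
        assert f == pytest.approx(permanova_by_hand(dist, labels))

    def test_perfect_separation_minimal_p(self):
        # large enough groups that a random permutation almost never
        # reproduces the observed partition
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 1, (10, 4)), rng.normal(50, 1, (10, 4))])
        from scipy.spatial.distance import pdist, squareform

        dist = squareform(pdist(pts))
        _, p = mg.permanova(dist, ["A"] * 10 + ["B"] * 10, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_agrees_with_independent_reference(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 5))
        pts[6:] += 0.8
        from scipy.spatial.distance import pdist, squareform

        dist = squareform(pdist(pts))
        labels = ["A"] * 6 + ["B"] * 6
        f, _ = mg.permanova(dist, labels, n_perm=99, seed=3)
        ref = sk_permanova(DistanceMatrix(dist), labels, permutations=99)
        assert f == pytest.approx(ref["test statistic"])

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], dtype=float)
        with pytest.raises(InvalidInputError):
            mg.permanova(bad, ["A", "A", "B"])

    def test_invariant_under_joint_relabeling(self):
        dist, labels = self.toy()
        perm = np.array([3, 1, 5, 0, 4, 2])
        dist2 = dist[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        f1, p1 = mg.permanova(dist, labels, n_perm=999, seed=11)
        f2, p2 = mg.permanova(dist2, labels2, n_perm=999, seed=11)
        assert f1 == pytest.approx(f2)
        assert abs(p1 - p2) < 0.05


class TestReporterZscore:
    def make_results(self, p_and_dir):
        out = []
        for i, (p, direction) in enumerate(p_and_dir):
            mean_a, mean_b = (2.0, 1.0) if direction == "higher-in-A" else (1.0, 2.0)
            if direction == "none":
                mean_a = mean_b = 1.0
            out.append(ComparisonResult(f"K{i:05d}", mean_a, mean_b, p, p, 0.0, direction))
        return out

    def test_identical_kos_aggregate_scales_with_sqrt_k(self):
        from scipy.stats import norm

        results = self.make_results([(0.04, "higher-in-A")] * 9 + [(0.5, "none")] * 21)
        kos = [f"K{i:05d}" for i in range(9)]
        _, z_raw = mg.reporter_zscore(results, kos, n_background=100, seed=1)
        z0 = norm.ppf(1 - 0.02)
        assert z_raw == pytest.approx(z0 * 9 / math.sqrt(9))

    def test_null_module_centers_near_zero(self):
        # mid-range p-values without a consistent direction: the module is a
        # plain draw from the background, so the corrected score is ~N(0,1)
        rng = np.random.default_rng(5)
        results = self.make_results(
            [
                (p, d)
                for p, d in zip(
                    rng.uniform(0.3, 0.9, size=40),
                    rng.choice(["higher-in-A", "higher-in-B"], size=40),
                )
            ]
        )
        z_adj, _ = mg.reporter_zscore(results, [r.feature for r in results[:8]],
                                      n_background=2000, seed=5)
        assert abs(z_adj) < 2.5

    def test_background_matches_exhaustive_enumeration(self):
        import itertools

        rng = np.random.default_rng(8)
        results = self.make_results(
            [(p, d) for p, d in zip(rng.uniform(0.01, 0.9, size=10),
                                    rng.choice(["higher-in-A", "higher-in-B"], size=10))]
        )
        kos = [r.feature for r in results[:3]]
        z_adj, z_raw = mg.reporter_zscore(results, kos, n_background=5000, seed=8)

        from scipy.stats import norm

        def signed_z(r):
            sign = 1.0 if r.direction == "higher-in-A" else -1.0
            return sign * norm.ppf(1 - r.p_value / 2)

        z_all = np.array([signed_z(r) for r in results])
        bg = np.array(
            [z_all[list(c)].sum() / math.sqrt(3) for c in itertools.combinations(range(10), 3)]
        )
        expected = (z_raw - bg.mean()) / bg.std(ddof=1)
        assert z_adj == pytest.approx(expected, abs=0.35)

    def test_missing_ko_rejected(self):
        results = self.make_results([(0.2, "none")] * 4)
        with pytest.raises(MissingFeatureError):
            mg.reporter_zscore(results, ["K99999"], seed=1)
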