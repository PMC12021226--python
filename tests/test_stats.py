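"""Dissimilarity, NMDS, PerMANOVA, diversity curves and Steel-Dwass."""

from itertools import combinations, product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from dietbarcode.stats import (
    DissimilarityMatrix,
    StatsError,
    coverage_estimate,
    dissimilarity,
    nmds,
    permanova,
    shannon_re_curve,
    significance_letters,
    steel_dwass,
)
from dietbarcode._util import child_rng


def frame(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids)


class TestDissimilarity:
    def test_identical_rows_zero(self):
        d = dissimilarity(frame([[1, 2, 3], [1, 2, 3]]), "bray_curtis")
        assert d.matrix[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_one(self):
        for metric in ("bray_curtis", "jaccard"):
            d = dissimilarity(frame([[1, 0], [0, 1]]), metric)
            assert d.matrix[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_hand_example(self):
        d = dissimilarity(frame([[0.5, 0.5, 0], [0.5, 0, 0.5]]), "bray_curtis")
        assert d.matrix[0, 1] == pytest.approx(0.5)

    def test_jaccard_exhaustive_on_3_taxon_presence_vectors(self):
        """1 - |intersection|/|union| over all 2^6 binary pairs."""
        for a, b in product(product([0, 1], repeat=3), repeat=2):
            if sum(a) == 0 or sum(b) == 0:
                continue
            d = dissimilarity(frame([a, b]), "jaccard")
            sa, sb = {i for i, v in enumerate(a) if v}, {i for i, v in enumerate(b) if v}
            assert d.matrix[0, 1] == pytest.approx(1 - len(sa & sb) / len(sa | sb))

    def test_matrix_invariants(self):
        rng = np.random.default_rng(0)
        d = dissimilarity(frame(rng.random((6, 4)) + 0.01), "bray_curtis")
        assert np.allclose(d.matrix, d.matrix.T)
        assert np.allclose(np.diag(d.matrix), 0)
        assert (d.matrix >= 0).all() and (d.matrix <= 1).all()


class TestNMDS:
    def test_three_equidistant_points_embed_exactly(self):
        m = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        r = nmds(DissimilarityMatrix(["a", "b", "c"], m, "bray_curtis"),
                 k=2, restarts=5, seed=0)
        assert r.stress < 1e-4

    def test_collinear_points_embed_in_1d(self):
        rng = np.random.default_rng(1)
        pts = np.sort(rng.random(7))
        m = np.abs(pts[:, None] - pts[None, :])
        r = nmds(DissimilarityMatrix([str(i) for i in range(7)], m, "bray_curtis"),
                 k=1, restarts=10, seed=0)
        assert r.stress < 1e-4

    def test_stress_nonincreasing_in_dimension(self):
        rng = np.random.default_rng(2)
        table = frame(rng.random((20, 8)) + 0.01)
        d = dissimilarity(table, "bray_curtis")
        s2 = nmds(d, k=2, restarts=10, seed=3).stress
        s3 = nmds(d, k=3, restarts=10, seed=3).stress
        assert s3 <= s2 + 1e-6

    def test_dimension_guard(self):
        m = np.zeros((3, 3))
        with pytest.raises(StatsError):
            nmds(DissimilarityMatrix(["a", "b", "c"], m, "bray_curtis"), k=3)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        d = dissimilarity(frame(rng.random((10, 5)) + 0.01), "bray_curtis")
        a = nmds(d, k=2, restarts=5, seed=7)
        b = nmds(d, k=2, restarts=5, seed=7)
        assert a.stress == b.stress
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)


class TestPermanova:
    def test_single_group_rejected(self):
        rng = np.random.default_rng(5)
        d = dissimilarity(frame(rng.random((6, 3)) + 0.01), "bray_curtis")
        with pytest.raises(StatsError):
            permanova(d, ["a"] * 6)

    def test_separated_clusters_hit_permutation_floor(self):
        X = np.zeros((12, 2)) + 0.001
        X[:6, 0], X[6:, 1] = 1, 1
        d = dissimilarity(frame(X), "bray_curtis")
        r = permanova(d, ["a"] * 6 + ["b"] * 6, permutations=999, seed=0)
        assert r.p_value == pytest.approx(1 / 1000)
        assert r.r2 > 0.9

    def test_matches_reference_implementation(self):
        """Pseudo-F agrees with scikit-bio's PERMANOVA."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(6)
        d = dissimilarity(frame(rng.random((15, 6)) + 0.01), "bray_curtis")
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        mine = permanova(d, labels, permutations=99, seed=0)
        theirs = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(d.matrix, d.ids), grouping=labels,
            permutations=99,
        )
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_r2_and_p_ranges(self):
        rng = np.random.default_rng(7)
        d = dissimilarity(frame(rng.random((16, 5)) + 0.01), "bray_curtis")
        r = permanova(d, ["a", "b", "c", "d"] * 4, permutations=199, seed=1)
        assert 0.0 <= r.r2 <= 1.0
        assert 0.0 < r.p_value <= 1.0


class TestCoverage:
    def test_no_singletons_full_coverage(self):
        assert coverage_estimate([5, 3, 2]) == 1.0

    def test_all_singletons_zero_coverage(self):
        assert coverage_estimate([1, 1, 1, 1]) == 0.0

    def test_plug_in_example(self):
        assert coverage_estimate([2, 2, 1]) == pytest.approx(0.9)

    def test_empty_rejected(self):
        with pytest.raises(StatsError):
            coverage_estimate([0, 0])


class TestShannonRECurve:
    def test_observed_point_is_plug_in_hill1(self):
        counts = np.array([8, 4, 2, 1])
        n = counts.sum()
        p = counts / n
        expected = float(np.exp(-(p * np.log(p)).sum()))
        curve = shannon_re_curve(counts, grid=[n], bootstrap_reps=0)
        assert curve.estimates[0] == pytest.approx(expected, abs=1e-9)
        assert curve.observed_hill1 == pytest.approx(expected, abs=1e-9)

    def test_uniform_distribution_tends_to_richness(self):
        counts = [200] * 6
        curve = shannon_re_curve(counts, grid=[1200], bootstrap_reps=0)
        assert curve.estimates[0] == pytest.approx(6.0, rel=0.01)

    def test_interpolation_matches_exhaustive_subsample_oracle(self):
        """m=3 of a 6-read vector: compare with all C(6,3) subsamples."""
        counts = np.array([3, 2, 1])
        reads = [0, 0, 0, 1, 1, 2]
        entropies = []
        for comb_idx in combinations(range(6), 3):
            sub = np.bincount([reads[i] for i in comb_idx], minlength=3)
            p = sub[sub > 0] / 3
            entropies.append(float(-(p * np.log(p)).sum()))
        oracle = float(np.exp(np.mean(entropies)))  # exp of the exact E[H]
        curve = shannon_re_curve(counts, grid=[3], bootstrap_reps=0)
        assert curve.estimates[0] == pytest.approx(oracle, abs=1e-9)

    def test_cis_bracket_estimate_and_curve_reports_coverage(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 50, size=12)
        curve = shannon_re_curve(counts, bootstrap_reps=200, seed=0)
        assert (curve.lcl <= curve.estimates + 1e-12).all()
        assert (curve.ucl >= curve.estimates - 1e-12).all()
        assert (np.diff(curve.sizes) > 0).all()
        assert (curve.coverages >= 0).all() and (curve.coverages <= 1).all()
        # coverage at the observed size matches the point estimator
        at_n = np.where(curve.sizes == curve.observed_size)[0]
        assert curve.coverages[at_n[0]] == pytest.approx(curve.observed_coverage)

    def test_monotone_in_size(self):
        counts = [40, 20, 10, 5, 2, 1]
        curve = shannon_re_curve(counts, bootstrap_reps=0)
        assert (np.diff(curve.estimates) >= -1e-9).all()

    def test_bad_grid_rejected(self):
        with pytest.raises(StatsError):
            shannon_re_curve([3, 2], grid=[0], bootstrap_reps=0)

    def test_deterministic_given_seed(self):
        counts = [30, 20, 10, 1, 1]
        a = shannon_re_curve(counts, bootstrap_reps=100, seed=5)
        b = shannon_re_curve(counts, bootstrap_reps=100, seed=5)
        assert np.array_equal(a.lcl, b.lcl) and np.array_equal(a.ucl, b.ucl)


class TestSteelDwass:
    def test_identical_groups_p_one(self):
        out = steel_dwass({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        out = steel_dwass({"a": [1, 1, 1, 2], "b": [9, 9, 10, 10]})
        assert out["p_value"].iloc[0] < 0.05

    def test_k2_matches_exact_rank_test_ordering(self):
        """Asymptotic p preserves the ordering of exact Wilcoxon p-values."""
        rng = np.random.default_rng(9)
        results = []
        for _ in range(50):
            xa = rng.integers(0, 12, size=5).astype(float)
            xb = (rng.integers(0, 12, size=5) + rng.integers(0, 6)).astype(float)
            asym = steel_dwass({"a": xa, "b": xb})["p_value"].iloc[0]
            # exact two-sided rank-sum by full enumeration
            from scipy.stats import rankdata

            pooled = np.concatenate([xa, xb])
            ranks = rankdata(pooled)
            w_obs = ranks[:5].sum()
            ws = [sum(ranks[list(idx)]) for idx in combinations(range(10), 5)]
            center = np.mean(ws)
            exact = np.mean([abs(w - center) >= abs(w_obs - center) - 1e-9 for w in ws])
            results.append((asym, exact))
        asyms = np.array([r[0] for r in results])
        exacts = np.array([r[1] for r in results])
        # rank correlation of the two p-value orderings is strongly positive
        from scipy.stats import spearmanr

        rho = spearmanr(asyms, exacts).statistic
        assert rho > 0.9

    def test_pairwise_symmetry_under_relabelling(self):
        rng = np.random.default_rng(10)
        groups = {g: rng.normal(size=6) for g in ("x", "y", "z")}
        out1 = steel_dwass(groups)
        out2 = steel_dwass({k: groups[k] for k in ("z", "x", "y")})
        p1 = {frozenset((r.group1, r.group2)): r.p_value for r in out1.itertuples()}
        p2 = {frozenset((r.group1, r.group2)): r.p_value for r in out2.itertuples()}
        assert p1 == pytest.approx(p2)

    def test_significance_letters_share_and_split(self):
        pw = pd.DataFrame(
            [
                {"group1": "a", "group2": "b", "p_value": 0.9},
                {"group1": "a", "group2": "c", "p_value": 0.001},
                {"group1": "b", "group2": "c", "p_value": 0.002},
            ]
        )
        letters = significance_letters(pw, ["a", "b", "c"], alpha=0.05)
        assert letters["a"] == letters["b"]
        assert set(letters["c"]) & set(letters["a"]) == set()


def test_permanova_type_one_error_calibrated():
    """Null rejection rate ~5% across 100 label-independent datasets."""
    rejections = 0
    n_sims, alpha = 100, 0.05
    for s in range(n_sims):
        rng = child_rng(2024, 77, s)
        table = frame(rng.random((16, 6)) + 0.01)
        d = dissimilarity(table, "bray_curtis")
        labels = np.repeat(["a", "b", "c", "d"], 4)
        r = permanova(d, labels, permutations=199, seed=s)
        rejections += r.p_value < alpha
    lo, hi = binom.ppf([0.005, 0.995], n_sims, alpha)
    assert lo <= rejections <= hi
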