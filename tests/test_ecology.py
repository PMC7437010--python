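"""Beta-diversity stack: oracle equivalence and statistical calibration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kstest

from barseq_popdyn.ecology import (
    DistanceMatrix,
    beta_dispersion,
    bray_curtis,
    nmds,
    pcoa,
    permanova,
    restricted_permutations,
)


def brute_force_bray_curtis(X):
    """Independent per-pair loop oracle in plain Python floats."""
    n = len(X)
    D = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            shared = sum(min(a, b) for a, b in zip(X[i], X[j]))
            D[i][j] = 1.0 - 2.0 * shared / (sum(X[i]) + sum(X[j]))
    return D


def brute_force_permanova_f(D, labels):
    """Pseudo-F recomputed from first principles in plain Python."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(
        D[i][j] ** 2 for i in range(n) for j in range(i + 1, n)
    ) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            D[i][j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestBrayCurtis:
    def test_identical_rows_zero(self, random_abundance_frame):
        frame = random_abundance_frame(1, 6)
        frame = pd.concat([frame, frame.set_axis(["dup"])])
        assert bray_curtis(frame).d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_one(self):
        frame = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert bray_curtis(frame).d[0, 1] == pytest.approx(1.0)

    def test_hand_evaluated_pair(self):
        frame = pd.DataFrame([[6.0, 2.0], [2.0, 6.0]], index=["a", "b"])
        assert bray_curtis(frame).d[0, 1] == pytest.approx(0.5)

    def test_zero_row_rejected(self):
        frame = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["a", "b"])
        with pytest.raises(ValueError, match="zero"):
            bray_curtis(frame)

    def test_matches_brute_force_on_random_tables(self, random_abundance_frame):
        for seed in range(50):
            frame = random_abundance_frame(5, 8, seed=seed)
            D = bray_curtis(frame).d
            oracle = brute_force_bray_curtis(frame.to_numpy().tolist())
            assert np.allclose(D, oracle, atol=1e-12)

    def test_matches_scikit_bio(self, random_abundance_frame):
        skbio_diversity = pytest.importorskip("skbio.diversity")
        frame = random_abundance_frame(7, 12, seed=123)
        ours = bray_curtis(frame).d
        theirs = skbio_diversity.beta_diversity(
            "braycurtis", frame.to_numpy(), ids=list(frame.index)
        ).data
        assert np.allclose(ours, theirs, atol=1e-12)


class TestPcoa:
    def test_collinear_points_recovered_in_one_axis(self):
        pts = np.array([[0.0], [1.0], [3.0], [7.0]])
        D = squareform(pdist(pts))
        ordn = pcoa(DistanceMatrix(list("abcd"), D), k=1)
        rec = squareform(pdist(ordn.coordinates))
        assert np.allclose(rec, D, atol=1e-9)

    def test_equilateral_triangle_eigenvalues(self):
        # All off-diagonal distances d: centered matrix has two eigenvalues
        # d^2 / 2 and one zero.
        d = 0.8
        D = np.full((3, 3), d)
        np.fill_diagonal(D, 0.0)
        ordn = pcoa(DistanceMatrix(list("abc"), D), k=2)
        expected = d**2 / 2.0
        assert ordn.eigenvalues[0] == pytest.approx(expected, rel=1e-9)
        assert ordn.eigenvalues[1] == pytest.approx(expected, rel=1e-9)
        assert ordn.eigenvalues[2] == pytest.approx(0.0, abs=1e-9)

    def test_identical_samples_collapse_to_origin(self):
        D = np.zeros((4, 4))
        ordn = pcoa(DistanceMatrix(list("abcd"), D), k=2)
        assert np.allclose(ordn.coordinates, 0.0)

    def test_k_too_large_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(list("abc"), D), k=3)

    def test_matches_scikit_bio_distances(self, random_abundance_frame):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        frame = random_abundance_frame(8, 15, seed=9)
        dm = bray_curtis(frame)
        ours = pcoa(dm, k=3).coordinates
        import skbio

        theirs = skbio_ordination.pcoa(
            skbio.DistanceMatrix(dm.d, ids=dm.sample_ids), number_of_dimensions=3
        ).samples.to_numpy()
        # axes are sign- (and near-degeneracy rotation-) ambiguous, so
        # compare the induced configuration distances instead
        assert np.allclose(
            pdist(ours), pdist(theirs), atol=1e-8
        )


class TestNmds:
    def _random_dm(self, seed, n=8):
        rng = np.random.default_rng(seed)
        X = rng.dirichlet(np.ones(12), size=n)
        return bray_curtis(
            pd.DataFrame(X, index=[f"s{i}" for i in range(n)])
        )

    def test_embeddable_configuration_reaches_zero_stress(self, rng):
        pts = rng.normal(size=(9, 2))
        D = DistanceMatrix([f"s{i}" for i in range(9)], squareform(pdist(pts)))
        ordn = nmds(D, k=2, n_restarts=5, seed=0)
        assert ordn.stress < 0.01

    def test_deterministic_given_seed(self):
        dm = self._random_dm(4)
        a = nmds(dm, k=2, n_restarts=6, seed=42)
        b = nmds(dm, k=2, n_restarts=6, seed=42)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_stress_trace_monotone_in_every_restart(self):
        dm = self._random_dm(5)
        ordn = nmds(dm, k=2, n_restarts=10, seed=1)
        for trace in ordn.all_stress_traces:
            assert (np.diff(trace) <= 1e-12).all()

    def test_not_worse_than_pcoa_start_on_euclidean_input(self, rng):
        pts = rng.normal(size=(10, 3))
        D = DistanceMatrix(
            [f"s{i}" for i in range(10)], squareform(pdist(pts))
        )
        ordn = nmds(D, k=2, n_restarts=4, seed=0)
        # the PCoA start is restart 0; its initial stress bounds the result
        assert ordn.stress <= ordn.all_stress_traces[0][0] + 1e-12

    def test_too_few_samples_rejected(self):
        D = DistanceMatrix(list("abc"), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            nmds(D, k=2)


class TestPermanova:
    def _two_group_dm(self):
        # within-group distances 0, between-group distances 1
        D = np.ones((6, 6))
        D[:3, :3] = 0.0
        D[3:, 3:] = 0.0
        np.fill_diagonal(D, 0.0)
        return DistanceMatrix([f"s{i}" for i in range(6)], D)

    def test_perfect_separation(self):
        # Exhaustively: only the observed partition (and its label swap)
        # separates perfectly, so p hits its design minimum 2/20 and R2 its
        # maximum of 1.
        res = permanova(
            self._two_group_dm(), ["a"] * 3 + ["b"] * 3,
            n_permutations="exhaustive",
        )
        assert res.p_value == pytest.approx(2 / 20)
        assert res.R2 == pytest.approx(1.0)

    def test_perfect_separation_large_design(self):
        D = np.ones((16, 16))
        D[:8, :8] = 0.0
        D[8:, 8:] = 0.0
        np.fill_diagonal(D, 0.0)
        dm = DistanceMatrix([f"s{i}" for i in range(16)], D)
        res = permanova(dm, ["a"] * 8 + ["b"] * 8, n_permutations=199, seed=0)
        # ties (a permutation reproducing the split) are ~2/12870 per draw
        assert res.p_value <= 2 / 200
        assert res.R2 == pytest.approx(1.0)

    def test_exhaustive_matches_brute_force_enumeration(self, rng):
        X = rng.dirichlet(np.ones(10), size=6)
        dm = bray_curtis(pd.DataFrame(X, index=[f"s{i}" for i in range(6)]))
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(dm, labels, n_permutations="exhaustive")

        D = dm.d.tolist()
        f_obs = brute_force_permanova_f(D, labels)
        fs = []
        for combo in itertools.combinations(range(6), 3):
            lab = ["a" if i in combo else "b" for i in range(6)]
            fs.append(brute_force_permanova_f(D, lab))
        p_exact = sum(f >= f_obs - 1e-12 for f in fs) / len(fs)
        assert res.n_permutations == 19
        assert res.p_value == pytest.approx(p_exact)
        assert res.pseudo_F == pytest.approx(f_obs)

    def test_pseudo_f_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova

        X = rng.dirichlet(np.ones(20), size=9)
        dm = bray_curtis(pd.DataFrame(X, index=[f"s{i}" for i in range(9)]))
        labels = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        ours = permanova(dm, labels, n_permutations=9, seed=0)
        theirs = skbio_permanova(
            skbio.DistanceMatrix(dm.d, ids=dm.sample_ids),
            grouping=list(labels), permutations=9,
        )
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_null_p_values_super_uniform(self):
        """Under a neutral null, PERMANOVA p-values are (super-)uniform."""
        rng = np.random.default_rng(77)
        pvals = []
        for _ in range(300):
            X = rng.dirichlet(np.ones(8), size=10)
            dm = bray_curtis(
                pd.DataFrame(X, index=[f"s{i}" for i in range(10)])
            )
            labels = rng.permutation(["a"] * 5 + ["b"] * 5)
            pvals.append(
                permanova(dm, labels, n_permutations=99,
                          seed=int(rng.integers(2**31))).p_value
            )
        # KS against uniform; discreteness makes p-values conservative, so
        # only reject on blatant miscalibration
        stat = kstest(pvals, "uniform").statistic
        assert stat < 0.12

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            permanova(self._two_group_dm(), ["a"] * 6)


class TestRestrictedPermutations:
    def test_within_strata_never_mixes_strata(self):
        labels = np.array([0, 5, 24, 0, 5, 24])
        strata = np.array(["r1", "r1", "r1", "r2", "r2", "r2"])
        for perm in restricted_permutations(labels, strata, seed=0, n=500):
            assert sorted(perm[:3]) == [0, 5, 24]
            assert sorted(perm[3:]) == [0, 5, 24]

    def test_constant_labels_permute_whole_blocks(self):
        labels = np.array(["CF", "CF", "DF", "DF", "CF", "CF"])
        strata = np.array(["r1", "r1", "r2", "r2", "r3", "r3"])
        for perm in restricted_permutations(labels, strata, seed=1, n=500):
            # a reactor's samples always share one label: never split
            assert perm[0] == perm[1]
            assert perm[2] == perm[3]
            assert perm[4] == perm[5]
            assert sorted(perm) == ["CF", "CF", "CF", "CF", "DF", "DF"]


class TestBetaDispersion:
    def test_identical_group_has_zero_distances(self, random_abundance_frame):
        frame = random_abundance_frame(1, 8, seed=0)
        rows = [frame.iloc[0]] * 3 + list(
            random_abundance_frame(3, 8, seed=1).iloc[i] for i in range(3)
        )
        frame = pd.DataFrame(rows, index=[f"s{i}" for i in range(6)])
        dm = bray_curtis(frame)
        res = beta_dispersion(dm, ["a"] * 3 + ["b"] * 3, n_permutations=99,
                              seed=0)
        assert np.allclose(res.distances[:3], 0.0, atol=1e-7)

    def test_mirror_groups_indistinguishable(self):
        # two groups with identical internal geometry
        block = np.array([[0.0, 0.2, 0.4], [0.2, 0.0, 0.3], [0.4, 0.3, 0.0]])
        D = np.zeros((6, 6))
        D[:3, :3] = block
        D[3:, 3:] = block
        D[:3, 3:] = 0.9
        D[3:, :3] = 0.9
        np.fill_diagonal(D, 0.0)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], D)
        res = beta_dispersion(dm, ["a"] * 3 + ["b"] * 3, n_permutations=199,
                              seed=0)
        assert res.anova_F == pytest.approx(0.0, abs=1e-9)
        assert res.permutation_p > 0.9

    def test_singleton_group_excluded_but_reported(self, random_abundance_frame):
        frame = random_abundance_frame(7, 10, seed=3)
        groups = ["a", "a", "a", "b", "b", "b", "c"]
        res = beta_dispersion(bray_curtis(frame), groups, n_permutations=49,
                              seed=0)
        assert res.excluded_groups == ["c"]
        assert len(res.distances) == 7

    def test_distances_match_vegan_style_oracle(self, random_abundance_frame):
        """Centroid distances agree with an independent direct computation.

        For group G and sample i in G, the squared centroid distance equals
        mean_{j in G} d^2(i,j) - (1/|G|^2) sum_{j<k in G} d^2(j,k) — an
        identity of the Gower embedding that needs no eigendecomposition.
        """
        frame = random_abundance_frame(9, 14, seed=5)
        dm = bray_curtis(frame)
        groups = np.array(["a"] * 4 + ["b"] * 5)
        res = beta_dispersion(dm, groups, n_permutations=9, seed=0)
        d2 = dm.d**2
        for g in ("a", "b"):
            idx = np.flatnonzero(groups == g)
            m = len(idx)
            within = d2[np.ix_(idx, idx)].sum() / 2.0
            for i in idx:
                expected_sq = d2[i, idx].mean() - within / m**2
                expected = math.sqrt(max(expected_sq, 0.0))
                assert res.distances[i] == pytest.approx(expected, abs=1e-8)
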