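import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix as SkbioDM, TreeNode
from skbio.tree import nj as skbio_nj

from goosepop.genotype_io import MISSING, GenotypeMatrix, LocusRecord
from goosepop.population_structure import (
    DistanceMatrix,
    nj_tree,
    pairwise_distance,
    pca,
    tracy_widom_ppf,
    tracy_widom_sf,
)


def _gm(dosage_rows, names=None):
    dos = np.array(dosage_rows, dtype=np.int8)
    names = names or [f"i{k}" for k in range(dos.shape[0])]
    loci = [LocusRecord("c", 10 * (j + 1), "A", ("C",)) for j in range(dos.shape[1])]
    return GenotypeMatrix(names, loci, dos)


class TestPca:
    def test_two_clusters_rank_one(self, rng):
        block = rng.integers(0, 3, size=30)
        other = 2 - block
        gm = _gm([block] * 5 + [other] * 5)
        res = pca(gm)
        nonzero = res.eigenvalues[res.eigenvalues > 1e-9 * res.eigenvalues[0]]
        assert len(nonzero) == 1
        pc1 = res.scores[:, 0]
        assert (np.sign(pc1[:5]) != np.sign(pc1[5:])).all()

    def test_eigenvalue_sum_equals_normalized_variance(self, synth):
        gm, _, _ = synth
        res = pca(gm)
        # trace identity: sum of eigenvalues equals the normalized
        # individual-by-individual covariance trace
        dos = gm.dosages.astype(float)
        dos[gm.dosages == MISSING] = np.nan
        mu = np.nanmean(dos, axis=0)
        p = mu / 2
        keep = (p > 0) & (p < 1)
        x = dos[:, keep]
        idx = np.where(np.isnan(x))
        x[idx] = np.take(mu[keep], idx[1])
        x = (x - mu[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
        trace = np.trace(x @ x.T / x.shape[1])
        assert res.eigenvalues.sum() == pytest.approx(trace, rel=1e-8)

    def test_structured_data_significant_axes(self, synth):
        gm, _, _ = synth
        res = pca(gm)
        assert res.n_significant >= 2
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-8)

    def test_white_noise_rarely_significant(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            r = np.random.default_rng(seed)
            gm = _gm(r.binomial(2, 0.5, size=(50, 500)))
            hits += pca(gm).n_significant == 0
        assert hits >= int(0.9 * reps) - 1

    def test_no_polymorphic_loci_rejected(self):
        gm = _gm(np.zeros((4, 5), dtype=int))
        with pytest.raises(ValueError):
            pca(gm)


class TestTracyWidom:
    def test_gamma_approximation_quantiles(self):
        # reference TW1 values: mean ~ -1.2065, 95th percentile ~ 0.9793
        assert tracy_widom_ppf(0.95) == pytest.approx(0.979, abs=0.02)
        assert tracy_widom_sf(0.9793) == pytest.approx(0.05, abs=0.005)
        assert tracy_widom_sf(-3.90) == pytest.approx(0.99, abs=0.01)

    def test_white_noise_largest_eigenvalue_calibrated(self):
        """TW statistic of pure-noise matrices under the null stays below
        the 95th percentile about 95% of the time."""
        crit = tracy_widom_ppf(0.95)
        hits = 0
        reps = 40
        for seed in range(reps):
            r = np.random.default_rng(1000 + seed)
            gm = _gm(r.binomial(2, 0.5, size=(40, 400)))
            res = pca(gm)
            hits += res.tw_statistics[0] < crit
        assert hits >= 33  # ~95% with binomial slack


class TestDistances:
    def test_identical_individuals_zero(self):
        gm = _gm([[0, 1, 2], [0, 1, 2], [1, 1, 1]])
        dm = pairwise_distance(gm)
        assert dm.values[0, 1] == 0.0

    def test_maximal_distance(self):
        gm = _gm([[0, 0, 0], [2, 2, 2], [1, 1, 1]])
        dm = pairwise_distance(gm)
        assert dm.values[0, 1] == 1.0

    def test_hand_arithmetic(self):
        gm = _gm([[0, 1], [2, 1], [1, 1]])
        dm = pairwise_distance(gm)
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_missing_restricted_to_cocalled(self):
        gm = _gm([[0, MISSING, 2], [2, 1, 2], [1, 1, 1]])
        dm = pairwise_distance(gm)
        assert dm.values[0, 1] == pytest.approx(0.5)  # loci 1 and 3 only
        assert dm.n_shared_loci[0, 1] == 2

    def test_no_shared_loci_rejected(self):
        gm = _gm([[0, MISSING], [MISSING, 1], [1, 1]])
        with pytest.raises(ValueError, match="share"):
            pairwise_distance(gm)


def _random_additive_matrix(labels, rng):
    """Pairwise distances generated by a random tree (hence exactly additive)."""

    def build(group):
        if len(group) == 1:
            return {}, {group[0]: 0.0}
        group = [group[i] for i in rng.permutation(len(group))]
        k = int(rng.integers(1, len(group)))
        left, right = group[:k], group[k:]
        pairs_l, depth_l = build(left)
        pairs_r, depth_r = build(right)
        el, er = rng.uniform(0.1, 1.0, size=2)
        pairs = {**pairs_l, **pairs_r}
        for a in left:
            for b in right:
                pairs[frozenset((a, b))] = depth_l[a] + el + depth_r[b] + er
        depths = {a: depth_l[a] + el for a in left}
        depths.update({b: depth_r[b] + er for b in right})
        return pairs, depths

    pairs, _ = build(list(labels))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairs[frozenset((labels[i], labels[j]))]
    return d


def _patristic(newick, labels):
    tree = TreeNode.read([newick])
    out = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d = tree.find(a).distance(tree.find(b))
                out[i, j] = out[j, i] = d
    return out


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        newick = nj_tree(dm)
        pat = _patristic(newick, ["A", "B", "C"])
        np.testing.assert_allclose(pat, dm.values)
        tree = TreeNode.read([newick])
        assert tree.find("A").length == pytest.approx(1.0)
        assert tree.find("B").length == pytest.approx(1.0)
        assert tree.find("C").length == pytest.approx(3.0)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:1)); additive distances
        d = np.array(
            [
                [0, 3, 5, 3],
                [3, 0, 6, 4],
                [5, 6, 0, 4],
                [3, 4, 4, 0],
            ],
            float,
        )
        dm = DistanceMatrix(list("ABCD"), d)
        pat = _patristic(nj_tree(dm), list("ABCD"))
        np.testing.assert_allclose(pat, d, atol=1e-9)

    def test_equidistant_taxa_star(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(list("ABCD"), d)
        newick = nj_tree(dm)
        tree = TreeNode.read([newick])
        internal = [n.length for n in tree.non_tips() if n.length is not None]
        assert all(abs(l) < 1e-9 for l in internal)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=4, max_value=8))
    def test_random_additive_trees_recovered(self, seed, n):
        """NJ reconstructs any additive distance matrix exactly."""
        r = np.random.default_rng(seed)
        labels = [f"t{i}" for i in range(n)]
        d = _random_additive_matrix(labels, r)
        recovered = _patristic(nj_tree(DistanceMatrix(labels, d)), labels)
        np.testing.assert_allclose(recovered, d, atol=1e-8)

    def test_agrees_with_skbio_on_random_additive_matrix(self, rng):
        labels = [f"t{i}" for i in range(7)]
        d = _random_additive_matrix(labels, rng)
        mine = _patristic(nj_tree(DistanceMatrix(labels, d)), labels)
        theirs_tree = skbio_nj(SkbioDM(d, ids=labels))
        theirs = np.zeros_like(d)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    dist = theirs_tree.find(a).distance(theirs_tree.find(b))
                    theirs[i, j] = theirs[j, i] = dist
        np.testing.assert_allclose(mine, theirs, atol=1e-6)

    def test_undefined_distance_names_pair(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            DistanceMatrix(list("ABC"), d)
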