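"""Transforms, Bray-Curtis, ANOSIM/PERMANOVA permutation tests and PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from cazymag.errors import ValidationError
from cazymag.ordination import (
    DissimilarityMatrix,
    anosim,
    bray_curtis,
    pca,
    permanova,
    sqrt_wisconsin,
)


class TestSqrtWisconsin:
    def test_hand_example(self):
        m = pd.DataFrame([[1.0, 4.0], [9.0, 16.0]])
        out = sqrt_wisconsin(m).to_numpy()
        assert np.allclose(out, [[0.4, 0.6], [0.5, 0.5]], atol=1e-12)

    def test_zeros_pass_through(self):
        m = pd.DataFrame(np.zeros((3, 3)))
        assert np.all(sqrt_wisconsin(m).to_numpy() == 0)

    def test_single_positive_cell(self):
        m = pd.DataFrame([[0.0, 5.0], [0.0, 0.0]])
        out = sqrt_wisconsin(m).to_numpy()
        assert out[0, 1] == 1.0 and out.sum() == 1.0

    def test_standardization_postconditions(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.poisson(3, (20, 12)).astype(float))
        x = np.sqrt(m.to_numpy())
        colmax = x.max(axis=0)
        step2 = x / np.where(colmax > 0, colmax, 1)
        assert np.allclose(step2.max(axis=0)[colmax > 0], 1.0)
        out = sqrt_wisconsin(m).to_numpy()
        nonzero_rows = out.sum(axis=1) > 0
        assert np.allclose(out[nonzero_rows].sum(axis=1), 1.0, atol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            sqrt_wisconsin(pd.DataFrame([[-1.0]]))


class TestBrayCurtis:
    def test_identity_disjoint_and_hand_value(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [0.0, 3.0], [4.0, 0.0], [2.0, 1.0]])
        d = bray_curtis(m).data
        assert d[0, 1] == 0.0
        assert d[2, 3] == 1.0
        assert d[0, 4] == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_scipy_formula_oracle(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.poisson(5, (15, 8)).astype(float))
        mine = bray_curtis(m).data
        oracle = squareform(pdist(m.to_numpy(), metric="braycurtis"))
        assert np.allclose(mine, oracle, atol=1e-12)

    def test_invariants(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.poisson(2, (10, 6)).astype(float))
        D = bray_curtis(m)
        assert np.allclose(D.data, D.data.T)
        assert np.all(np.diag(D.data) == 0)
        assert D.data.min() >= 0 and D.data.max() <= 1

    def test_double_zero_convention(self):
        m = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        assert bray_curtis(m).data[0, 1] == 0.0


def _toy_distance(seed=0, n_per=3, sep=10.0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([
        np.abs(rng.normal(1, 0.05, (n_per, 3))),
        np.abs(rng.normal(1 + sep, 0.05, (n_per, 3))),
    ])
    return bray_curtis(pd.DataFrame(pts)), ["a"] * n_per + ["b"] * n_per


class TestAnosim:
    def test_full_separation_r_one(self):
        D, labels = _toy_distance()
        assert anosim(D, labels, exact=True).R == pytest.approx(1.0)

    def test_null_r_near_zero(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(np.abs(rng.normal(1, 0.3, (24, 5))))
        D = bray_curtis(m)
        rs = [
            anosim(D, rng.permutation(np.repeat(["a", "b", "c"], 8)),
                   n_permutations=49, seed=int(s)).R
            for s in range(10)
        ]
        assert abs(np.mean(rs)) < 0.1

    def test_exact_p_equals_enumeration_oracle(self):
        """For n=6 the permutation p must equal brute-force enumeration
        computed independently from the rank definition."""
        rng = np.random.default_rng(4)
        m = pd.DataFrame(np.abs(rng.normal(1, 0.5, (6, 4))))
        D = bray_curtis(m)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = anosim(D, labels, exact=True)

        ranks = stats.rankdata(squareform(D.data, checks=False))
        msize = len(ranks)

        def r_of(lab):
            lab = np.asarray(lab)
            same = squareform(lab[:, None] == lab[None, :], checks=False).astype(bool)
            return (ranks[~same].mean() - ranks[same].mean()) / (msize / 2)

        observed = r_of(labels)
        count = sum(
            r_of(labels[list(p)]) >= observed - 1e-12
            for p in itertools.permutations(range(6))
        )
        assert res.p_value == pytest.approx(count / 720)
        assert res.R == pytest.approx(observed, abs=1e-12)

    def test_singleton_group_rejected(self):
        D, _ = _toy_distance()
        with pytest.raises(ValidationError):
            anosim(D, ["a", "a", "a", "a", "a", "b"])

    def test_r_monotone_in_planted_effect(self):
        rng = np.random.default_rng(5)
        rs = []
        for sep in (0.0, 0.5, 3.0):
            pts = np.vstack([
                np.abs(rng.normal(1, 0.4, (12, 6))),
                np.abs(rng.normal(1 + sep, 0.4, (12, 6))),
            ])
            D = bray_curtis(pd.DataFrame(pts))
            rs.append(anosim(D, ["a"] * 12 + ["b"] * 12, n_permutations=99, seed=1).R)
        assert rs[0] < rs[1] < rs[2]


class TestPermanova:
    def test_tight_groups_far_apart_r2_near_one(self):
        D, labels = _toy_distance(sep=100.0)
        res = permanova(D, labels, exact=True)
        assert res.R_squared > 0.95
        assert res.pseudo_F > 10

    def test_one_group_rejected(self):
        D, _ = _toy_distance()
        with pytest.raises(ValidationError):
            permanova(D, ["a"] * 6)

    def test_exact_p_equals_enumeration_oracle(self):
        """Brute-force F over all 720 relabelings, F computed independently
        from the sum-of-squares partition."""
        rng = np.random.default_rng(6)
        m = pd.DataFrame(np.abs(rng.normal(1, 0.5, (6, 4))))
        D = bray_curtis(m)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(D, labels, exact=True)

        d2 = D.data**2
        n, g = 6, 2

        def f_of(lab):
            lab = np.asarray(lab)
            ss_t = d2[np.triu_indices(n, 1)].sum() / n
            ss_w = 0.0
            for grp in np.unique(lab):
                idx = np.where(lab == grp)[0]
                sub = d2[np.ix_(idx, idx)]
                ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
            ss_b = ss_t - ss_w
            return (ss_b / (g - 1)) / (ss_w / (n - g))

        observed = f_of(labels)
        count = sum(
            f_of(labels[list(p)]) >= observed - 1e-12
            for p in itertools.permutations(range(6))
        )
        assert res.p_value == pytest.approx(count / 720)
        assert res.pseudo_F == pytest.approx(observed, rel=1e-10)

    def test_null_p_not_small(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(np.abs(rng.normal(1, 0.3, (18, 5))))
        D = bray_curtis(m)
        res = permanova(D, rng.permutation(np.repeat(["a", "b", "c"], 6)),
                        n_permutations=199, seed=0)
        assert res.p_value > 0.01


class TestAgainstScikitBio:
    """Independent cross-check: statistic values must match scikit-bio's
    ANOSIM and PERMANOVA implementations on the same distances."""

    def test_anosim_r_and_permanova_f_match(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(12)
        m = pd.DataFrame(np.abs(rng.normal(1, 0.4, (12, 5))))
        D = bray_curtis(m)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        dm = skbio_distance.DistanceMatrix(D.data, [str(i) for i in range(12)])
        mine_r = anosim(D, labels, n_permutations=9, seed=0).R
        theirs_r = skbio_distance.anosim(dm, grouping=labels, permutations=9)["test statistic"]
        assert mine_r == pytest.approx(theirs_r, abs=1e-12)
        mine_f = permanova(D, labels, n_permutations=9, seed=0).pseudo_F
        theirs_f = skbio_distance.permanova(dm, grouping=labels, permutations=9)["test statistic"]
        assert mine_f == pytest.approx(theirs_f, rel=1e-10)


class TestPca:
    def test_collinear_points_single_component(self):
        t = np.linspace(0, 1, 10)
        m = pd.DataFrame({"x": t, "y": 2 * t})
        res = pca(m, k=1)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(0, 1, (20, 5)))
        v1 = pca(m).variance_explained
        v2 = pca(m.sample(frac=1, random_state=0)).variance_explained
        assert np.allclose(v1, v2, atol=1e-12)

    def test_k_too_large_rejected(self):
        m = pd.DataFrame(np.random.default_rng(9).normal(0, 1, (5, 3)))
        with pytest.raises(ValidationError):
            pca(m, k=4)

    def test_components_orthogonal_and_variance_sorted(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.normal(0, 1, (30, 6)))
        res = pca(m, k=4)
        gram = res.loadings.T @ res.loadings
        assert np.allclose(gram, np.eye(4), atol=1e-10)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)
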