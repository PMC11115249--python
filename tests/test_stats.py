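import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from cyclodeps.stats import (
    benjamini_hochberg,
    bray_curtis,
    pcoa,
    permanova,
    spearman_bh,
    top_k_select,
)


class TestBrayCurtis:
    def test_identical_columns(self):
        m = np.array([[1.0, 1.0], [2.0, 2.0]])
        assert bray_curtis(m)[0, 1] == 0.0

    def test_disjoint_supports(self):
        m = np.array([[1.0, 0.0], [0.0, 2.0]])
        assert bray_curtis(m)[0, 1] == 1.0

    def test_hand_example(self):
        m = np.array([[1.0, 3.0], [2.0, 0.0]])
        assert bray_curtis(m)[0, 1] == pytest.approx(2.0 / 3.0)

    def test_all_zero_pair_is_zero_with_warning(self):
        m = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.warns(UserWarning):
            d = bray_curtis(m)
        assert d[0, 1] == 0.0

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            m = rng.uniform(0, 10, size=(5, 5))
            d = bray_curtis(m)
            for i in range(5):
                for j in range(5):
                    num = np.abs(m[:, i] - m[:, j]).sum()
                    den = (m[:, i] + m[:, j]).sum()
                    assert d[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0, 5, size=(10, 6))
        ours = bray_curtis(m)
        scipy_d = squareform(pdist(m.T, metric="braycurtis"))
        assert np.allclose(ours, scipy_d, atol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([[-1.0, 0.0]]))

    def test_dataframe_labels(self):
        m = pd.DataFrame({"a": [1.0], "b": [2.0]})
        d = bray_curtis(m)
        assert list(d.index) == ["a", "b"]


class TestPcoa:
    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(d)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert pos.size == 2
        assert pos[0] == pytest.approx(pos[1], abs=1e-10)
        coords = res.coordinates.to_numpy()
        recon = squareform(pdist(coords))
        assert np.allclose(recon, d, atol=1e-8)

    def test_two_points(self):
        delta = 3.7
        d = np.array([[0.0, delta], [delta, 0.0]])
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        assert coords.shape[1] == 1
        assert sorted(coords[:, 0]) == pytest.approx([-delta / 2, delta / 2])

    def test_duplicate_sample(self):
        d = np.array(
            [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]
        )
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        assert np.allclose(coords[0], coords[1], atol=1e-10)

    def test_euclidean_roundtrip(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 3))
        d = squareform(pdist(x))
        res = pcoa(d)
        recon = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(recon, d, atol=1e-8)

    def test_matches_skbio(self):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(2)
        x = rng.normal(size=(7, 4))
        d = squareform(pdist(x))
        ours = pcoa(d)
        import skbio

        theirs = skbio_ordination.pcoa(skbio.DistanceMatrix(d))
        assert np.allclose(
            np.sort(ours.eigenvalues)[::-1][:6],
            np.sort(theirs.eigvals.to_numpy())[::-1][:6],
            atol=1e-8,
        )

    def test_negative_eigenvalues_reported(self):
        # non-Euclidean distances produce negative eigenvalues
        d = np.array(
            [
                [0.0, 1.0, 1.0, 1.0],
                [1.0, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 2.0],
                [1.0, 1.0, 2.0, 0.0],
            ]
        )
        res = pcoa(d)
        assert res.eigenvalues.min() < -1e-10
        assert list(res.eigenvalues) == sorted(res.eigenvalues, reverse=True)

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(d)


class TestPermanova:
    @staticmethod
    def clouds(separation, n=8, seed=0):
        rng = np.random.default_rng(seed)
        x = np.vstack(
            [
                rng.normal(0, 1, size=(n, 3)),
                rng.normal(separation, 1, size=(n, 3)),
            ]
        )
        labels = ["a"] * n + ["b"] * n
        return squareform(pdist(x)), labels

    def test_strong_separation_hits_floor(self):
        d, labels = self.clouds(separation=50.0)
        f, p = permanova(d, labels, n_perm=999, seed=0)
        assert p == pytest.approx(0.001)
        assert f > 100

    def test_relabeling_invariance(self):
        d, labels = self.clouds(separation=2.0)
        f1, _ = permanova(d, labels, n_perm=9, seed=0)
        perm = np.random.default_rng(5).permutation(len(labels))
        d2 = d[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        f2, _ = permanova(d2, labels2, n_perm=9, seed=0)
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_matches_skbio_pseudo_f(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        d, labels = self.clouds(separation=1.0, seed=3)
        import skbio

        ours, _ = permanova(d, labels, n_perm=9, seed=0)
        theirs = skbio_distance.permanova(
            skbio.DistanceMatrix(d), grouping=labels, permutations=9
        )
        assert ours == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_single_group_rejected(self):
        d = np.zeros((4, 4))
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 4)

    def test_small_group_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="2 samples"):
            permanova(d, ["a", "a", "b"])

    def test_type_one_error_calibration(self):
        """Null rejection rate at alpha = 0.05 stays within 0.05 +- 0.02
        over 500 null simulations (99 permutations each)."""
        rng = np.random.default_rng(42)
        labels = ["a"] * 8 + ["b"] * 8
        rejections = 0
        n_sim = 500
        for sim in range(n_sim):
            x = rng.normal(size=(16, 4))
            d = squareform(pdist(x))
            _, p = permanova(d, labels, n_perm=99, seed=int(rng.integers(2**31)))
            if p <= 0.05:
                rejections += 1
        assert abs(rejections / n_sim - 0.05) <= 0.02


class TestBenjaminiHochberg:
    def test_q_ge_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = benjamini_hochberg(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)

    def test_monotone_in_rank_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=200)
        q = benjamini_hochberg(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)


def _tables(features, otus, samples=None):
    samples = samples or [f"s{i}" for i in range(features.shape[1])]
    f = pd.DataFrame(features, columns=samples,
                     index=[f"F{i}" for i in range(features.shape[0])])
    o = pd.DataFrame(otus, columns=samples,
                     index=[f"OTU{i}" for i in range(otus.shape[0])])
    return f, o


class TestSpearmanBh:
    def test_monotone_transform_gives_rho_one(self):
        x = np.linspace(1, 10, 12)
        f, o = _tables(x[None, :] ** 3, np.round(x[None, :] * 7))
        [rec] = spearman_bh(f, o, proportion_transform=False)
        assert rec.rho == pytest.approx(1.0)

    def test_anti_monotone(self):
        x = np.linspace(1, 10, 12)
        f, o = _tables((-x)[None, :] + 20, np.round(x[None, :] * 7))
        [rec] = spearman_bh(f, o, proportion_transform=False)
        assert rec.rho == pytest.approx(-1.0)

    def test_too_few_samples(self):
        f, o = _tables(np.ones((1, 3)), np.ones((1, 3)))
        with pytest.raises(ValueError, match="4"):
            spearman_bh(f, o)

    def test_matches_scipy_spearmanr(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        feats = rng.uniform(size=(3, 20))
        otus = rng.integers(0, 100, size=(2, 20)).astype(float)
        records = spearman_bh(
            pd.DataFrame(feats, columns=[f"s{i}" for i in range(20)],
                         index=["F0", "F1", "F2"]),
            pd.DataFrame(otus, columns=[f"s{i}" for i in range(20)],
                         index=["OTU0", "OTU1"]),
        )
        by_pair = {(r.otu, r.feature): r for r in records}
        depth = otus.sum(axis=0)
        for i in range(2):
            for j in range(3):
                expected = spearmanr(otus[i] / depth, feats[j])
                rec = by_pair[(f"OTU{i}", f"F{j}")]
                assert rec.rho == pytest.approx(expected.statistic, abs=1e-12)
                assert rec.p == pytest.approx(expected.pvalue, abs=1e-9)

    def test_planted_pairs_recovered(self):
        """10 planted monotone pairs among 200 null pairs at n = 50: all
        planted flagged at q < 0.05 with <= 2 false flags."""
        rng = np.random.default_rng(7)
        n = 50
        n_null_feats, n_otus = 20, 10  # 200 pairs
        feats = rng.uniform(size=(n_null_feats, n))
        otus = rng.integers(50, 150, size=(n_otus, n)).astype(float)
        # plant: otu k coupled to feature k for k < 10
        for k in range(10):
            sign = 1 if k % 2 == 0 else -1
            coupled = np.argsort(np.argsort(sign * feats[k])) * 10 + 100.0
            otus[k] = coupled
        f, o = _tables(feats, otus)
        records = spearman_bh(f, o, proportion_transform=False)
        flagged = {(r.otu, r.feature) for r in records if r.significant}
        planted = {(f"OTU{k}", f"F{k}") for k in range(10)}
        assert len(planted & flagged) >= 9
        assert len(flagged - planted) <= 2

    @given(st.sampled_from(["exp", "cube", "affine"]))
    @settings(max_examples=3, deadline=None)
    def test_rho_invariant_under_monotone_transform(self, kind):
        rng = np.random.default_rng(11)
        x = rng.uniform(1, 2, size=(1, 15))
        y = rng.uniform(1, 2, size=(1, 15))
        transform = {
            "exp": np.exp, "cube": lambda v: v**3, "affine": lambda v: 3 * v + 1
        }[kind]
        f1, o1 = _tables(x, np.round(y * 100))
        f2, o2 = _tables(transform(x), np.round(y * 100))
        [r1] = spearman_bh(f1, o1, proportion_transform=False)
        [r2] = spearman_bh(f2, o2, proportion_transform=False)
        assert r1.rho == pytest.approx(r2.rho, abs=1e-12)


class TestTopKSelect:
    @staticmethod
    def records():
        from cyclodeps.stats import CorrelationRecord

        recs = []
        rng = np.random.default_rng(0)
        for i in range(100):
            rho = rng.uniform(-1, 1)
            q = rng.uniform(0, 0.04)
            recs.append(
                CorrelationRecord(f"OTU{i}", f"F{i}", rho, q / 2, q, True)
            )
        return sorted(recs, key=lambda r: (r.q, -abs(r.rho)))

    def test_bounded_selection(self):
        sel = top_k_select(self.records(), k=20)
        assert len(sel) <= 40

    def test_forced_inclusion_when_not_significant(self):
        from cyclodeps.stats import CorrelationRecord

        recs = self.records() + [
            CorrelationRecord("OTU_X", "F_X", 0.5, 0.5, 0.9, False)
        ]
        sel = top_k_select(recs, k=5, forced_ids=("OTU_X",))
        forced = [r for r in sel if r.forced]
        assert len(forced) == 1
        assert forced[0].otu == "OTU_X"

    def test_k_zero_forced_only(self):
        sel = top_k_select(self.records(), k=0, forced_ids=("OTU7",))
        assert len(sel) == 1
        assert sel[0].forced
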