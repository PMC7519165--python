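"""bicor/TOM machinery, module detection, and enrichment statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicfuse.differential import DesignSpec
from omicfuse.network import (
    GREY,
    ModuleSet,
    NetworkParams,
    bicor_matrix,
    consensus_tom,
    detect_modules,
    fisher_exact_2x2,
    geneset_enrichment_logistic,
    hub_selection,
    module_eigengene,
    module_trait_association,
    signed_adjacency,
    topological_overlap,
)
from conftest import paired_metadata


class TestBicor:
    def test_self_correlation_one(self, rng):
        x = rng.normal(size=20)
        C = bicor_matrix(np.vstack([x, x]))
        assert C[0, 1] == pytest.approx(1.0)

    def test_anticorrelation_minus_one(self, rng):
        x = rng.normal(size=20)
        C = bicor_matrix(np.vstack([x, -x]))
        assert C[0, 1] == pytest.approx(-1.0)

    def test_robust_to_single_gross_outlier(self):
        # bicor on contaminated data stays closer to the clean Pearson
        # than the contaminated Pearson does (robustness simulation)
        r = np.random.default_rng(5)
        wins = 0
        for _ in range(100):
            x = r.normal(size=20)
            y = 0.8 * x + 0.6 * r.normal(size=20)
            clean = np.corrcoef(x, y)[0, 1]
            xc = x.copy()
            xc[0] += 15.0
            contaminated_pearson = np.corrcoef(xc, y)[0, 1]
            bc = bicor_matrix(np.vstack([xc, y]))[0, 1]
            if abs(bc - clean) < abs(contaminated_pearson - clean):
                wins += 1
        assert wins >= 80

    def test_mad_zero_falls_back_to_pearson(self, rng):
        x = np.zeros(10)
        x[0] = 1.0  # median deviation zero
        y = rng.normal(size=10)
        with pytest.warns(UserWarning, match="MAD"):
            C = bicor_matrix(np.vstack([x, y]))
        assert np.isfinite(C).all()

    def test_constant_feature_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            bicor_matrix(np.vstack([np.ones(10), rng.normal(size=10)]))


class TestAdjacencyTOM:
    def test_signed_adjacency_endpoints(self):
        cor = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert signed_adjacency(cor, 9)[0, 1] == pytest.approx(1.0)
        cor[0, 1] = cor[1, 0] = -1.0
        assert signed_adjacency(cor, 9)[0, 1] == pytest.approx(0.0)

    def test_signed_adjacency_zero_correlation(self):
        cor = np.eye(2)
        assert signed_adjacency(cor, 9)[0, 1] == pytest.approx(0.5**9)

    def test_tom_complete_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = topological_overlap(a)
        assert tom[0, 1] == pytest.approx((1 + 1) / (2 + 1 - 1))

    def test_tom_isolated_pair(self):
        w = 0.37
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = w
        tom = topological_overlap(a)
        assert tom[0, 1] == pytest.approx(w / (w + 1 - w))

    def test_tom_identical_rows_maximal(self, rng):
        a = rng.uniform(0, 1, (5, 5))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        a[1] = a[0]
        a[:, 1] = a[:, 0]
        a[0, 1] = a[1, 0] = 0.99
        np.fill_diagonal(a, 0)
        tom = topological_overlap(a)
        row = tom[0].copy()
        row[0] = -np.inf
        assert np.argmax(row) == 1

    def test_tom_matches_bruteforce(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 10))
            a = rng.uniform(0, 1, (n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            tom = topological_overlap(a)
            k = a.sum(axis=1)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        assert tom[i, j] == 1.0
                        continue
                    l = sum(a[i, u] * a[u, j] for u in range(n))
                    expect = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                    assert tom[i, j] == pytest.approx(expect)

    def test_tom_range_and_symmetry(self, rng):
        a = rng.uniform(0, 1, (8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        tom = topological_overlap(a)
        assert ((tom >= 0) & (tom <= 1)).all()
        assert np.allclose(tom, tom.T)


class TestConsensusTOM:
    def test_single_bootstrap_without_resampling_is_plain_tom(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 15)))
        params = NetworkParams(beta=6, n_bootstraps=1, min_module_size=2, seed=0)
        cons = consensus_tom(X, params, resample=False)
        plain = topological_overlap(signed_adjacency(bicor_matrix(X), 6))
        assert np.allclose(cons, plain)

    def test_median_of_identical_toms(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 12)))
        params = NetworkParams(beta=6, n_bootstraps=5, min_module_size=2, seed=0)
        cons = consensus_tom(X, params, resample=False)
        plain = topological_overlap(signed_adjacency(bicor_matrix(X), 6))
        assert np.allclose(cons, plain)

    def test_planted_modules_survive_bootstrap_consensus(self):
        r = np.random.default_rng(8)
        f1, f2 = r.normal(size=30), r.normal(size=30)
        block1 = np.vstack([f1 + 0.5 * r.normal(size=30) for _ in range(10)])
        block2 = np.vstack([f2 + 0.5 * r.normal(size=30) for _ in range(10)])
        X = pd.DataFrame(np.vstack([block1, block2]))
        params = NetworkParams(beta=6, n_bootstraps=10, min_module_size=5, seed=1)
        cons = consensus_tom(X, params)
        within = np.r_[cons[:10, :10][np.triu_indices(10, 1)],
                       cons[10:, 10:][np.triu_indices(10, 1)]]
        across = cons[:10, 10:].ravel()
        assert within.mean() > across.mean()


class TestModuleDetection:
    @staticmethod
    def planted(rng, sizes=(20, 20), n=40, within=0.8, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        feats = []
        for s in sizes:
            f = r.normal(size=n)
            lam = np.sqrt(within / (1 - within))
            feats.append(np.vstack([lam * f + r.normal(size=n) for _ in range(s)]))
        X = pd.DataFrame(np.vstack(feats),
                         index=[f"g{i}" for i in range(sum(sizes))])
        return X

    def test_two_planted_blocks_recovered(self, rng):
        X = self.planted(rng, seed=2)
        params = NetworkParams(beta=6, n_bootstraps=1, min_module_size=10, seed=0)
        tom = consensus_tom(X, params, resample=False)
        ms = detect_modules(tom, X, params)
        labs = ms.labels
        assert len(ms.modules) == 2
        assert labs.iloc[:20].nunique() == 1 and labs.iloc[20:].nunique() == 1
        assert labs.iloc[0] != labs.iloc[20]

    def test_small_blocks_all_grey(self, rng):
        X = self.planted(rng, sizes=(6, 6), seed=3)
        params = NetworkParams(beta=6, n_bootstraps=1, min_module_size=50, seed=0)
        tom = consensus_tom(X, params, resample=False)
        with pytest.warns(UserWarning):
            ms = detect_modules(tom, X, params)
        assert (ms.labels == GREY).all()

    def test_highly_correlated_modules_merged(self):
        r = np.random.default_rng(4)
        f = r.normal(size=40)
        # two blocks driven by the same factor -> eigengene corr ~ 1
        X = pd.DataFrame(np.vstack(
            [3.0 * f + r.normal(size=40) for _ in range(24)]),
            index=[f"g{i}" for i in range(24)])
        params = NetworkParams(beta=6, n_bootstraps=1, min_module_size=5,
                               merge_threshold=0.1, seed=0)
        tom = consensus_tom(X, params, resample=False)
        ms = detect_modules(tom, X, params)
        assert len(ms.modules) == 1

    def test_permutation_invariance_of_membership(self, rng):
        X = self.planted(rng, seed=5)
        params = NetworkParams(beta=6, n_bootstraps=1, min_module_size=10, seed=0)
        tom = consensus_tom(X, params, resample=False)
        base = detect_modules(tom, X, params).labels
        perm = rng.permutation(len(X))
        Xp = X.iloc[perm]
        tomp = consensus_tom(Xp, params, resample=False)
        permuted = detect_modules(tomp, Xp, params).labels
        # same partition of features, module names may differ
        joint = pd.crosstab(base.loc[Xp.index], permuted)
        assert (joint.astype(bool).sum(axis=1) == 1).all()


class TestEigengene:
    def test_identical_features_give_standardized_feature(self, rng):
        x = rng.normal(size=12)
        X = pd.DataFrame([x, x, x], index=list("abc"),
                         columns=[f"s{i}" for i in range(12)])
        e = module_eigengene(X, list("abc"))
        zx = (x - x.mean()) / x.std(ddof=1)
        r = np.corrcoef(e, zx)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_sign_flip_of_all_features_changes_nothing_material(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 10)),
                         index=[f"g{i}" for i in range(6)])
        e1 = module_eigengene(X, list(X.index))
        e2 = module_eigengene(-X, list(X.index))
        assert np.allclose(np.abs(e1), np.abs(e2), atol=1e-10)

    def test_matches_independent_svd_oracle(self, rng):
        for _ in range(20):
            X = pd.DataFrame(rng.normal(size=(10, 14)),
                             index=[f"g{i}" for i in range(10)])
            e = module_eigengene(X, list(X.index))
            # oracle: eigenvector of the standardized Gram matrix
            Z = X.to_numpy()
            Z = (Z - Z.mean(1, keepdims=True)) / Z.std(1, ddof=1, keepdims=True)
            w, V = np.linalg.eigh(Z.T @ Z)
            v = V[:, -1]
            if np.dot(v, Z.mean(0)) < 0:
                v = -v
            assert np.abs(e.to_numpy() - v).max() < 1e-8


class TestModuleTrait:
    def test_diagnosis_driven_eigengene_detected(self):
        r = np.random.default_rng(9)
        meta = paired_metadata(20, seed=9)
        eig = pd.Series(
            (meta["diagnosis"] == "ASD").to_numpy(float) + r.normal(0, 0.1, len(meta)),
            index=meta.index)
        spec = DesignSpec(["diagnosis", "age"])
        res = module_trait_association(eig, meta, spec, contrast=("ASD", "control"))
        assert res["estimate"] > 0
        assert res["p"] < 0.01

    def test_constant_eigengene_rejected(self):
        meta = paired_metadata(10)
        eig = pd.Series(1.0, index=meta.index)
        with pytest.raises(ValueError, match="constant"):
            module_trait_association(eig, meta, DesignSpec(["diagnosis"]))

    def test_null_pvalues_uniform(self):
        # eigengene with paired-sample (subject) correlation, independent
        # of diagnosis: the Wald p for the diagnosis term must be uniform
        meta = paired_metadata(20, seed=1)
        subj = pd.factorize(meta["brain_id"])[0]
        spec = DesignSpec(["diagnosis", "age"])
        ps = []
        for seed in range(50):
            r = np.random.default_rng(1000 + seed)
            eig = pd.Series(r.normal(0, 0.5, subj.max() + 1)[subj]
                            + r.normal(size=len(meta)), index=meta.index)
            ps.append(module_trait_association(
                eig, meta, spec, contrast=("ASD", "control"))["p"])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestHubs:
    @staticmethod
    def module_set(kmes):
        idx = [f"g{i}" for i in range(len(kmes))]
        kme = pd.DataFrame({"M1": kmes}, index=idx)
        labels = pd.Series("M1", index=idx)
        return kme, labels

    def test_top_quarter(self):
        kme, labels = self.module_set([0.9, 0.8, 0.7, 0.6])
        assert hub_selection(kme, labels, "M1", 0.25) == ["g0"]

    def test_all_ties_selected(self):
        kme, labels = self.module_set([0.5] * 8)
        assert len(hub_selection(kme, labels, "M1", 0.25)) == 8

    def test_hundred_members_gives_25(self, rng):
        vals = rng.uniform(0, 1, 100)
        kme, labels = self.module_set(list(vals))
        hubs = hub_selection(kme, labels, "M1", 0.25)
        # sort oracle
        expect = set(np.array(kme.index)[np.argsort(vals)[-25:]])
        assert set(hubs) == expect


class TestEnrichment:
    def test_self_enrichment(self, rng):
        bg = [f"g{i}" for i in range(200)]
        s = bg[:40]
        res = geneset_enrichment_logistic(s, s, bg)
        assert res["odds_ratio"] > 1
        assert res["p"] < 0.05

    def test_disjoint_cover_depleted(self):
        bg = [f"g{i}" for i in range(100)]
        res = geneset_enrichment_logistic(bg[:50], bg[50:], bg)
        assert res["odds_ratio"] < 1

    def test_independent_sets_type_one_error(self):
        r = np.random.default_rng(12)
        bg = [f"g{i}" for i in range(1000)]
        rejections = 0
        for _ in range(100):
            s1 = list(r.choice(bg, 50, replace=False))
            s2 = list(r.choice(bg, 50, replace=False))
            if geneset_enrichment_logistic(s1, s2, bg)["p"] < 0.05:
                rejections += 1
        assert rejections <= 12


class TestFisher:
    def test_region_discordance_table(self):
        # 11/43 ASD vs 1/33 control region-discordant individuals
        assert fisher_exact_2x2([[11, 32], [1, 32]]) == pytest.approx(
            0.0096, abs=1e-4)

    def test_zero_margin_gives_one(self):
        assert fisher_exact_2x2([[0, 10], [0, 10]]) == 1.0

    def test_two_by_two_diagonal(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    @staticmethod
    def enumerate_oracle(t):
        t = np.asarray(t)
        r1, r2 = t.sum(axis=1)
        c1 = t[:, 0].sum()
        N = t.sum()
        if N == 0:
            return 1.0
        obs = stats.hypergeom.pmf(t[0, 0], N, r1, c1)
        p = 0.0
        for a in range(max(0, c1 - r2), min(r1, c1) + 1):
            pa = stats.hypergeom.pmf(a, N, r1, c1)
            if pa <= obs * (1 + 1e-9):
                p += pa
        return min(1.0, p)

    def test_matches_enumeration_on_all_small_margins(self):
        for r1 in range(0, 8):
            for r2 in range(0, 8):
                for c1 in range(0, r1 + r2 + 1):
                    a_lo, a_hi = max(0, c1 - r2), min(r1, c1)
                    for a in range(a_lo, a_hi + 1):
                        t = [[a, r1 - a], [c1 - a, r2 - (c1 - a)]]
                        got = fisher_exact_2x2(t)
                        assert got == pytest.approx(self.enumerate_oracle(t),
                                                    abs=1e-10)
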