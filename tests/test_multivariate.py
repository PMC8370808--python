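import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from phylosym import compositional as comp
from phylosym import multivariate as mv
from phylosym import synthetic_data as sd
from phylosym.io_formats import ValidationError

from conftest import make_diet, make_feature_table, make_metadata


def brute_force_one_way_stats(dist: np.ndarray, labels: np.ndarray):
    """Independent one-way PERMANOVA oracle via direct SS computation.

    SS_total = sum of squared distances / n; SS_within from within-group
    pairs; pseudo-F = (SS_between/df_b) / (SS_within/df_w).
    """
    n = len(labels)
    ss_total = (dist**2).sum() / (2 * n)
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        sub = dist[np.ix_(idx, idx)]
        ss_within += (sub**2).sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    df_b = len(np.unique(labels)) - 1
    df_w = n - len(np.unique(labels))
    f = (ss_between / df_b) / (ss_within / df_w)
    return ss_between, ss_within, f


def exact_one_way_p(dist: np.ndarray, labels: np.ndarray) -> float:
    """Exact p by full enumeration of label permutations (n <= 7)."""
    _, _, f_obs = brute_force_one_way_stats(dist, labels)
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(labels))):
        _, _, f = brute_force_one_way_stats(dist, labels[list(perm)])
        count += f >= f_obs - 1e-12
        total += 1
    return count / total


class TestPca:
    def test_collinear_data_single_axis(self):
        x = pd.DataFrame({"a": [0.0, 1, 2, 3], "b": [0.0, 2, 4, 6]}, index=list("wxyz"))
        res = mv.pca(x)
        ev = res.explained_variance
        assert ev[0] / ev.sum() == pytest.approx(1.0)

    def test_explained_variance_sums_to_total(self, dataset):
        clr = comp.clr_transform(dataset.fungi)
        res = mv.pca(clr)
        total = clr.values.to_numpy().var(axis=0, ddof=1).sum()
        assert res.explained_variance.sum() == pytest.approx(total, rel=1e-9)

    def test_scores_preserve_pairwise_distances(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(size=(15, 6)))
        res = mv.pca(x)
        d_orig = pdist(x.to_numpy() - x.to_numpy().mean(axis=0))
        d_scores = pdist(res.scores.to_numpy())
        np.testing.assert_allclose(d_scores, d_orig, atol=1e-9)

    def test_axis_limit_enforced(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            mv.pca(x, n_axes=5)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(10, 4)))
        a = mv.pca(x)
        b = mv.pca(x)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        for col in a.loadings.columns:
            j = a.loadings[col].abs().idxmax()
            assert a.loadings.loc[j, col] > 0


class TestPermanova:
    def _separated(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.3, size=(3, 2))
        b = rng.normal(5, 0.3, size=(3, 2))
        pts = np.vstack([a, b])
        ids = [f"s{i}" for i in range(6)]
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        md = make_metadata(ids, sample_type=["g1"] * 3 + ["g2"] * 3)
        return dm, md

    def test_separated_groups_match_exact_enumeration(self):
        dm, md = self._separated()
        res = mv.permanova_sequential(dm, md, ["sample_type"], n_perm=999, seed=1)
        assert res.table.loc["sample_type", "r2"] > 0.5
        p_exact = exact_one_way_p(np.asarray(dm.data), np.array(["a"] * 3 + ["b"] * 3))
        p_mc = res.table.loc["sample_type", "p"]
        mc_se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(p_mc - p_exact) <= 2 * mc_se + 1 / 1000
        # exact floor for 3+3 with the >= tie convention is 2/20 = 0.1 (the
        # group-label swap always ties the observed F), so equality with the
        # enumerated p -- not an absolute 0.05 -- is the correct check
        assert p_exact == pytest.approx(0.1)
        assert p_mc <= p_exact + 2 * mc_se

    def test_one_way_ss_matches_brute_force(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(9, 3))
        ids = [f"s{i}" for i in range(9)]
        labels = np.array(["a", "b", "c"] * 3)
        dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        md = make_metadata(ids, sample_type=labels)
        res = mv.permanova_sequential(dm, md, ["sample_type"], n_perm=99, seed=0)
        ss_b, ss_w, f = brute_force_one_way_stats(np.asarray(dm.data), labels)
        assert res.table.loc["sample_type", "ss"] == pytest.approx(ss_b, rel=1e-9)
        assert res.table.loc["residual", "ss"] == pytest.approx(ss_w, rel=1e-9)
        assert res.table.loc["sample_type", "f"] == pytest.approx(f, rel=1e-9)

    def test_r2_plus_residual_sums_to_one(self, dataset):
        dm = comp.aitchison_distance(comp.clr_transform(dataset.fungi))
        res = mv.permanova_sequential(
            dm, dataset.metadata, ["sample_type", "tissue_storage", "host_species"],
            n_perm=99, seed=0,
        )
        assert res.table["r2"].sum() == pytest.approx(1.0, abs=1e-9)
        assert res.table["df"].sum() == len(dm.ids) - 1

    def test_terms_reported_in_given_order(self, dataset):
        dm = comp.aitchison_distance(comp.clr_transform(dataset.fungi))
        order = ["extraction_kit", "tissue_storage", "sample_type", "host_class", "host_species"]
        res = mv.permanova_sequential(dm, dataset.metadata, order, n_perm=99, seed=0)
        assert list(res.table.index) == order + ["residual"]

    def test_single_level_term_error(self):
        dm, md = self._separated()
        with pytest.raises(ValidationError, match="single level"):
            mv.permanova_sequential(dm, md, ["host_class"], n_perm=99, seed=0)

    def test_aliased_term_error(self):
        dm, _ = self._separated()
        ids = list(dm.ids)
        md = make_metadata(
            ids,
            sample_type=["g1"] * 3 + ["g2"] * 3,
            tissue_storage=["t1"] * 3 + ["t2"] * 3,  # identical partition -> aliased
        )
        with pytest.raises(ValidationError, match="aliased"):
            mv.permanova_sequential(dm, md, ["sample_type", "tissue_storage"], n_perm=99, seed=0)

    def test_calibration_uniform_p(self):
        # random labels on exchangeable data -> uniform p (crude summary here;
        # the full 500-replicate CI check lives in the acceptance suite)
        rng = np.random.default_rng(1)
        ps = []
        for rep in range(100):
            pts = rng.normal(size=(12, 3))
            ids = [f"s{i}" for i in range(12)]
            dm = DistanceMatrix(squareform(pdist(pts)), ids=ids)
            md = make_metadata(ids, sample_type=list(rng.choice(["a", "b", "c"], size=12)))
            try:
                res = mv.permanova_sequential(dm, md, ["sample_type"], n_perm=99, seed=rep)
            except ValidationError:
                continue  # all labels drawn equal
            ps.append(res.table.loc["sample_type", "p"])
        ps = np.asarray(ps)
        assert 0.3 < ps.mean() < 0.7
        assert (ps <= 0.05).mean() < 0.15


class TestProcrustes:
    def test_rotated_scaled_copy_has_correlation_one(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(size=(20, 2)), index=[f"s{i}" for i in range(20)])
        theta = np.deg2rad(37)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        y = pd.DataFrame(2.0 * x.to_numpy() @ rot, index=x.index)
        res = mv.procrustes_correlation(x, y)
        assert res.correlation == pytest.approx(1.0, abs=1e-9)
        assert res.m12_squared == pytest.approx(0.0, abs=1e-9)

    def test_correlation_equals_sqrt_one_minus_m12sq(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(15, 3)), index=[f"s{i}" for i in range(15)])
        y = pd.DataFrame(rng.normal(size=(15, 3)), index=x.index)
        res = mv.procrustes_correlation(x, y)
        assert res.correlation == pytest.approx(np.sqrt(1 - res.m12_squared), abs=1e-9)

    def test_noise_below_null_95th_percentile(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(100, 3)), index=[f"s{i}" for i in range(100)])
        y = pd.DataFrame(rng.normal(size=(100, 3)), index=x.index)
        obs = mv.procrustes_correlation(x, y).correlation
        nulls = []
        for rep in range(200):
            perm = rng.permutation(100)
            nulls.append(
                mv.procrustes_correlation(
                    x, pd.DataFrame(y.to_numpy()[perm], index=x.index)
                ).correlation
            )
        assert obs < np.percentile(nulls, 95)

    def test_row_reordering_invariance(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(size=(12, 4)), index=[f"s{i}" for i in range(12)])
        y = pd.DataFrame(rng.normal(size=(12, 4)), index=x.index)
        shuffled = y.sample(frac=1.0, random_state=0)
        assert mv.procrustes_correlation(x, y).correlation == pytest.approx(
            mv.procrustes_correlation(x, shuffled).correlation, abs=1e-12
        )

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(size=(10, 2)), index=[f"s{i}" for i in range(10)])
        y = pd.DataFrame(rng.normal(size=(10, 2)), index=x.index)
        base = mv.procrustes_correlation(x, y).correlation
        shifted = pd.DataFrame(y.to_numpy() * 3.0 + np.array([5.0, -2.0]), index=x.index)
        assert mv.procrustes_correlation(x, shifted).correlation == pytest.approx(base, abs=1e-9)

    def test_too_few_shared_rows(self):
        x = pd.DataFrame(np.eye(3), index=["a", "b", "c"])
        y = pd.DataFrame(np.eye(3), index=["a", "b", "z"])
        with pytest.raises(ValidationError):
            mv.procrustes_correlation(x, y)


class TestProtest:
    def test_identical_matrices_minimum_p(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(size=(20, 3)), index=[f"s{i}" for i in range(20)])
        res = mv.protest(x, x.copy(), n_perm=199, seed=1)
        assert res.p == pytest.approx(1 / 200)

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(15, 3)), index=[f"s{i}" for i in range(15)])
        y = pd.DataFrame(rng.normal(size=(15, 3)), index=x.index)
        assert mv.protest(x, y, n_perm=199, seed=5).p == mv.protest(x, y, n_perm=199, seed=5).p


class TestBootstrapProcrustes:
    def test_frac_one_degenerate(self, dataset):
        res = mv.bootstrap_procrustes(
            dataset.fungi,
            dataset.bacteria,
            dataset.taxonomy_fungi,
            dataset.taxonomy_bacteria,
            rank_levels=["asv"],
            frac=1.0,
            n_boot=10,
            seed=0,
        )
        boot = res["asv"]
        np.testing.assert_allclose(boot.correlations, boot.full_correlation, atol=1e-9)

    def test_interval_within_replicate_range(self, dataset):
        res = mv.bootstrap_procrustes(
            dataset.fungi,
            dataset.bacteria,
            dataset.taxonomy_fungi,
            dataset.taxonomy_bacteria,
            rank_levels=["asv", "family"],
            frac=0.9,
            n_boot=99,
            seed=0,
        )
        for boot in res.values():
            lo, hi = boot.interval
            assert boot.correlations.min() - 1e-12 <= lo <= hi <= boot.correlations.max() + 1e-12
            assert len(boot.correlations) == 99

    def test_interval_width_shrinks_with_n(self):
        widths = {}
        for n_spp, label in ((4, "small"), (12, "large")):
            vals = []
            for seed in range(5):
                cfg = sd.SimulationConfig(
                    n_species=6,
                    samples_per_species=n_spp,
                    n_features_per_kingdom=40,
                    depth=300,
                    coupling=0.8,
                    seed=seed,
                )
                ds = sd.simulate_dataset(cfg)
                res = mv.bootstrap_procrustes(
                    ds.fungi, ds.bacteria, ds.taxonomy_fungi, ds.taxonomy_bacteria,
                    rank_levels=["asv"], frac=0.9, n_boot=49, seed=seed,
                )
                lo, hi = res["asv"].interval
                vals.append(hi - lo)
            widths[label] = np.mean(vals)
        assert widths["large"] < widths["small"]


class TestPhylosymbiosis:
    def test_strong_signal_beats_null(self):
        cfg = sd.SimulationConfig(
            n_species=8,
            samples_per_species=3,
            n_features_per_kingdom=60,
            depth=500,
            phylo_strength=2.0,
            sigma_within=0.2,
            batch_effect_size=0.0,
            seed=13,
        )
        ds = sd.simulate_dataset(cfg)
        res = mv.phylosymbiosis_test(
            ds.fungi, ds.taxonomy_fungi, ds.metadata, ds.tree,
            rank_levels=["asv"], n_boot=49, seed=0, n_perm=199,
        )
        assert res["asv"].p <= 0.05

    def test_null_signal_inside_null_band(self, null_dataset):
        ds = null_dataset
        res = mv.phylosymbiosis_test(
            ds.fungi, ds.taxonomy_fungi, ds.metadata, ds.tree,
            rank_levels=["asv"], n_boot=49, seed=0, n_perm=199,
        )
        assert res["asv"].p > 0.05

    def test_missing_species_error(self, dataset):
        tree = sd.simulate_host_tree(3, seed=99)  # wrong tips
        with pytest.raises(ValidationError, match="missing"):
            mv.phylosymbiosis_test(
                dataset.fungi, dataset.taxonomy_fungi, dataset.metadata, tree,
                rank_levels=["asv"], n_boot=9, seed=0,
            )


class TestMantel:
    def _dm(self, mat, ids):
        return DistanceMatrix(mat, ids=ids)

    def test_scaled_copy_r_one(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        ids = [f"s{i}" for i in range(8)]
        res = mv.mantel(self._dm(d, ids), self._dm(2 * d, ids), n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_in_argument_order(self):
        rng = np.random.default_rng(1)
        ids = [f"s{i}" for i in range(10)]
        d1 = squareform(pdist(rng.normal(size=(10, 3))))
        d2 = squareform(pdist(rng.normal(size=(10, 3))))
        a = mv.mantel(self._dm(d1, ids), self._dm(d2, ids), n_perm=99, seed=0)
        b = mv.mantel(self._dm(d2, ids), self._dm(d1, ids), n_perm=99, seed=0)
        assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_spearman_matches_rank_pearson(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(12)]
        d1 = squareform(pdist(rng.normal(size=(12, 3))))
        d2 = squareform(pdist(rng.normal(size=(12, 3))))
        res = mv.mantel(self._dm(d1, ids), self._dm(d2, ids), method="spearman", n_perm=99, seed=0)
        from scipy.stats import spearmanr

        iu = np.triu_indices(12, k=1)
        assert res.r == pytest.approx(spearmanr(d1[iu], d2[iu]).statistic, abs=1e-9)

    def test_label_alignment(self):
        rng = np.random.default_rng(3)
        ids = [f"s{i}" for i in range(8)]
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        dm1 = self._dm(d, ids)
        # same distances with permuted label order must still give r = 1
        perm = rng.permutation(8)
        dm2 = DistanceMatrix(d[np.ix_(perm, perm)], ids=[ids[i] for i in perm])
        res = mv.mantel(dm1, dm2, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_labels_error(self):
        d = np.array([[0.0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]])
        with pytest.raises(ValidationError):
            mv.mantel(self._dm(d, list("abcd")), self._dm(d, list("abcz")), n_perm=99, seed=0)


class TestDietAnalysis:
    def test_mirror_diets_single_axis(self):
        species = [f"sp{i}" for i in range(4)]
        props = np.zeros((4, 10))
        props[:2, 0] = 100.0  # all-invertebrate diet
        props[2:, 6] = 100.0  # all-fruit diet
        diet = make_diet(species, props)
        dmat = diet.proportions
        std = dmat.std(axis=0, ddof=1).replace(0.0, 1.0)
        res = mv.pca((dmat - dmat.mean(axis=0)) / std)
        ev = res.explained_variance
        assert ev[0] / ev.sum() == pytest.approx(1.0, abs=1e-9)
        pc1 = res.scores["PC1"]
        assert set(np.sign(pc1[:2])) != set(np.sign(pc1[2:]))

    def test_runs_on_simulated_dataset(self, dataset):
        res = mv.diet_analysis(
            dataset.fungi, dataset.bacteria, dataset.metadata, dataset.diet,
            n_perm=99, n_boot=49, seed=0,
        )
        assert set(res.mantel) == {"fungi", "bacteria"}
        for m in res.mantel.values():
            assert 0 < m.p <= 1
        assert res.slopes.shape[0] == 4  # 2 kingdoms x 2 axes
        assert res.dropped_species == []

    def test_too_few_species_error(self):
        table = make_feature_table([[1, 2, 3]], sample_ids=["a", "b", "c"])
        md = make_metadata(["a", "b", "c"], host_species=["x", "y", "z"])
        diet = make_diet(["x", "y"])
        with pytest.raises(ValidationError, match=">= 4"):
            mv.diet_analysis(table, table, md, diet, n_perm=99, seed=0)
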