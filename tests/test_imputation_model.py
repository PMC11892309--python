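"""PCA fitting/projection, per-gene OLS models, bundles, and serialization."""

import numpy as np
import pandas as pd
import pytest

import tximpute as tx
from tximpute.model import FORMAT_VERSION

from _oracles import ols_normal_equations
from conftest import make_matrix


def _random_normalized(n_genes, n_samples, seed=0):
    rng = np.random.default_rng(seed)
    return make_matrix(rng.normal(size=(n_genes, n_samples)))


class TestFitPCA:
    def test_projection_reproduces_fit_scores(self):
        blood = _random_normalized(30, 25, seed=1)
        pca = tx.fit_pca(blood, 4)
        x = blood.values.T
        xs = (x - pca.gene_means) / pca.gene_sds
        expected = xs @ pca.rotation
        assert np.allclose(tx.project_pca(pca, blood), expected, atol=1e-10)

    def test_component_variances_match_eigendecomposition(self):
        blood = _random_normalized(4, 5, seed=2)
        pca = tx.fit_pca(blood, 3)
        x = blood.values.T
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(xs.T)))[::-1]
        assert np.allclose(pca.explained_variance, eigvals[:3], atol=1e-8)

    def test_default_component_count_is_twenty(self):
        blood = _random_normalized(60, 40, seed=3)
        assert tx.fit_pca(blood).n_components == 20

    def test_rotation_orthonormal_and_truncation_consistent(self):
        blood = _random_normalized(50, 40, seed=4)
        p5 = tx.fit_pca(blood, 5)
        p10 = tx.fit_pca(blood, 10)
        assert np.allclose(p10.rotation.T @ p10.rotation, np.eye(10), atol=1e-8)
        assert np.allclose(p5.rotation, p10.rotation[:, :5], atol=1e-10)

    def test_sign_convention_deterministic(self):
        blood = _random_normalized(30, 20, seed=5)
        rot = tx.fit_pca(blood, 6).rotation
        for k in range(6):
            assert rot[np.argmax(np.abs(rot[:, k])), k] > 0

    def test_zero_variance_gene_dropped_with_warning(self):
        blood = _random_normalized(10, 15, seed=6)
        blood.data.iloc[3] = 2.5
        with pytest.warns(UserWarning, match="zero-variance"):
            pca = tx.fit_pca(blood, 3)
        assert pca.dropped_genes == ["g4"]
        assert len(pca.gene_ids) == 9

    def test_k_beyond_rank_rejected(self):
        blood = _random_normalized(10, 5, seed=7)
        with pytest.raises(ValueError, match="out of range"):
            tx.fit_pca(blood, 5)  # max is n_samples - 1 = 4

    def test_counts_unit_rejected(self):
        m = make_matrix(np.abs(np.random.default_rng(0).normal(size=(5, 8))), unit="counts")
        with pytest.raises(ValueError, match="log2cpm or normalized"):
            tx.fit_pca(m, 2)


class TestProjectPCA:
    def test_training_mean_projects_to_origin(self):
        blood = _random_normalized(12, 20, seed=8)
        pca = tx.fit_pca(blood, 3)
        mean_sample = make_matrix(pca.gene_means[:, None])
        mean_sample.data.index = pca.gene_ids
        assert np.allclose(tx.project_pca(pca, mean_sample), 0.0, atol=1e-12)

    def test_missing_gene_changes_scores_linearly(self):
        blood = _random_normalized(12, 20, seed=9)
        pca = tx.fit_pca(blood, 3)
        full = blood.select_samples([blood.sample_ids[0]])
        drop_gene = pca.gene_ids[5]
        reduced = full.select_genes([g for g in full.gene_ids if g != drop_gene])
        delta = tx.project_pca(pca, full) - tx.project_pca(pca, reduced)
        i = pca.gene_ids.index(drop_gene)
        standardized = (full.data.loc[drop_gene].iloc[0] - pca.gene_means[i]) / pca.gene_sds[i]
        assert np.allclose(delta[0], standardized * pca.rotation[i], atol=1e-10)

    def test_low_coverage_rejected_with_coverage_report(self):
        blood = _random_normalized(20, 25, seed=10)
        pca = tx.fit_pca(blood, 3)
        partial = blood.select_genes(blood.gene_ids[:5])
        with pytest.raises(ValueError, match="25.0%"):
            tx.project_pca(pca, partial)


class TestGeneModels:
    def test_exact_linear_target_recovered(self):
        blood = _random_normalized(40, 50, seed=11)
        pca = tx.fit_pca(blood, 4)
        scores = tx.project_pca(pca, blood)
        lung = make_matrix((1.0 + 2.0 * scores[:, 0])[None, :], gene_prefix="lg")
        models = tx.train_gene_models(scores, lung)
        assert models.intercepts[0] == pytest.approx(1.0, abs=1e-8)
        assert models.coefficients[0, 0] == pytest.approx(2.0, abs=1e-8)
        assert np.allclose(models.coefficients[0, 1:], 0.0, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=(30, 3))
        lung = make_matrix(rng.normal(size=(50, 30)), gene_prefix="lg")
        models = tx.train_gene_models(scores, lung)
        for g in range(50):
            beta = ols_normal_equations(scores, lung.values[g])
            assert abs(models.intercepts[g] - beta[0]) < 1e-8
            assert np.max(np.abs(models.coefficients[g] - beta[1:])) < 1e-8

    def test_constant_gene_skipped_with_reason(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=(20, 2))
        lung = make_matrix(np.vstack([np.full(20, 3.0), rng.normal(size=20)]), gene_prefix="lg")
        models = tx.train_gene_models(scores, lung)
        assert models.skipped == {"lg1": "zero variance"}
        assert models.gene_ids == ["lg2"]

    def test_duplicate_score_columns_rejected(self):
        rng = np.random.default_rng(14)
        base = rng.normal(size=(20, 1))
        scores = np.hstack([base, base])
        lung = make_matrix(rng.normal(size=(3, 20)), gene_prefix="lg")
        with pytest.raises(ValueError, match="rank-deficient"):
            tx.train_gene_models(scores, lung)


class TestBundle:
    def test_bundle_records_k_and_counts(self, paired_sim):
        blood, lung, _ = paired_sim
        bundle = tx.train_bundle(blood, lung, 6)
        assert bundle.n_components == 6
        assert bundle.training_n == blood.n_samples
        assert len(bundle.models) == lung.n_genes

    def test_noise_free_training_data_imputed_perfectly(self):
        blood, lung, _ = tx.simulate_paired(
            120, 300, 60, n_factors=5, shared_fractions=1.0, noise_sd=0.0, seed=15
        )
        bundle = tx.train_bundle(blood, lung, 5)
        imputed = tx.impute(bundle, blood)
        from tximpute._stats import row_correlations

        r = row_correlations(imputed.values, lung.values)
        assert (r >= 1 - 1e-6).all()

    def test_unpaired_samples_listed(self, paired_sim):
        blood, lung, _ = paired_sim
        bad_lung = lung.select_samples(lung.sample_ids[:-1])
        with pytest.raises(ValueError, match=lung.sample_ids[-1]):
            tx.train_bundle(blood, bad_lung, 4)

    def test_imputation_matches_dot_product_oracle(self, paired_sim):
        blood, lung, _ = paired_sim
        bundle = tx.train_bundle(blood, lung, 5)
        out = tx.impute(bundle, blood)
        scores = tx.project_pca(bundle.pca, blood)
        for g in (0, 17, 93):
            for s in (0, 41):
                expected = bundle.models.intercepts[g] + float(
                    np.dot(bundle.models.coefficients[g], scores[s])
                )
                assert out.values[g, s] == pytest.approx(expected, abs=1e-10)

    def test_single_component_arithmetic(self):
        # hand-built bundle: one gene with beta0=1, beta1=2; score 0.5 -> 2.0
        gene_ids = ["b1", "b2"]
        pca = tx.PCAModel(
            gene_ids=gene_ids,
            gene_means=np.zeros(2),
            gene_sds=np.ones(2),
            rotation=np.array([[1.0], [0.0]]),
            n_components=1,
        )
        models = tx.GeneModelSet(
            gene_ids=["target"], intercepts=np.array([1.0]), coefficients=np.array([[2.0]])
        )
        bundle = tx.ImputationBundle(pca=pca, models=models, training_n=10)
        blood = make_matrix(np.array([[0.5], [9.9]]))
        blood.data.index = gene_ids
        assert tx.impute(bundle, blood).values[0, 0] == pytest.approx(2.0)

    def test_imputation_is_linear(self, paired_sim):
        blood, lung, _ = paired_sim
        bundle = tx.train_bundle(blood, lung, 5)
        x = blood.select_samples(blood.sample_ids[:1])
        y = blood.select_samples(blood.sample_ids[1:2])
        a = 0.3
        mix = x.with_values(a * x.values + (1 - a) * y.values)
        left = tx.impute(bundle, mix).values[:, 0]
        right = a * tx.impute(bundle, x).values[:, 0] + (1 - a) * tx.impute(bundle, y).values[:, 0]
        assert np.allclose(left, right, atol=1e-8)


class TestSerialization:
    def test_save_load_impute_round_trip(self, paired_sim, tmp_path):
        blood, lung, _ = paired_sim
        bundle = tx.train_bundle(blood, lung, 5)
        tx.save_bundle(bundle, tmp_path / "bundle")
        loaded = tx.load_bundle(tmp_path / "bundle")
        a = tx.impute(bundle, blood).values
        b = tx.impute(loaded, blood).values
        assert np.allclose(a, b, atol=1e-12)
        assert loaded.training_n == bundle.training_n

    def test_truncated_bundle_rejected(self, paired_sim, tmp_path):
        blood, lung, _ = paired_sim
        bundle = tx.train_bundle(blood, lung, 5)
        tx.save_bundle(bundle, tmp_path / "bundle")
        models = tmp_path / "bundle" / "models.tsv"
        lines = models.read_text().splitlines()
        models.write_text("\n".join(line.rsplit("\t", 1)[0] for line in lines))
        with pytest.raises(ValueError, match="truncated or malformed"):
            tx.load_bundle(tmp_path / "bundle")

    def test_version_mismatch_rejected(self, paired_sim, tmp_path):
        import json

        blood, lung, _ = paired_sim
        bundle = tx.train_bundle(blood, lung, 5)
        tx.save_bundle(bundle, tmp_path / "bundle")
        meta_path = tmp_path / "bundle" / "meta.json"
        meta = json.loads(meta_path.read_text())
        meta["format_version"] = "0.0"
        meta_path.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match=FORMAT_VERSION):
            tx.load_bundle(tmp_path / "bundle")
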