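"""Proteochemometrics: encoding, PCA, PLS, VIP, full-pipeline recovery."""

import warnings

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from chemrdf.chembl_synth import SyntheticConfig, extract_pcm_dataset, \
    generate_chembl_store
from chemrdf.pcm import (
    cross_terms,
    encode_sequences,
    importance_ranking,
    load_zscales,
    pca_reduce,
    pcm_cross_validate,
    pls_fit,
    pls_predict,
    read_fasta_alignment,
)


class TestZScales:
    def test_twenty_canonical_residues(self):
        table = load_zscales()
        assert len(table) == 20
        assert set("ACDEFGHIKLMNPQRSTVWY") == set(table)
        assert all(len(v) == 3 for v in table.values())


class TestEncoding:
    def test_identical_sequences_identical_rows(self):
        Z = encode_sequences(["ACDY", "ACDY"])
        assert np.array_equal(Z[0], Z[1])
        assert Z.shape == (2, 12)

    def test_single_position_identity(self):
        Z = encode_sequences(["A", "A"])
        assert np.array_equal(Z[0] - Z[1], np.zeros(3))

    def test_columns_are_position_major(self):
        table = load_zscales()
        Z = encode_sequences(["AC"], table)
        assert tuple(Z[0, :3]) == table["A"]
        assert tuple(Z[0, 3:]) == table["C"]

    def test_gap_imputed_by_position_mean(self):
        table = load_zscales()
        Z = encode_sequences(["-A", "CA", "GA"], table)
        expected = np.mean([table["C"], table["G"]], axis=0)
        assert np.allclose(Z[0, :3], expected)

    def test_all_gap_column_is_constant(self):
        Z = encode_sequences(["-A", "-C"])
        assert np.allclose(Z[:, :3], 0.0)
        assert np.all(Z[:, :3].std(axis=0) == 0)  # flagged by zero variance

    def test_unknown_residue_names_sequence_and_position(self):
        with pytest.raises(ValueError, match="sequence 1 position 2"):
            encode_sequences(["ACD", "ACX"])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            encode_sequences(["AC", "ACD"])

    def test_distinct_sequences_distinct_rows(self):
        seqs = ["ACDY", "ACDW", "GCDY", "ACEY"]
        Z = encode_sequences(seqs)
        assert len({tuple(row) for row in Z}) == len(seqs)


@pytest.fixture(scope="module")
def data():
    rng = np.random.default_rng(3)
    return rng.normal(size=(20, 6)) @ rng.normal(size=(6, 6))


class TestPca:
    def test_scores_orthogonal(self, data):
        scores, _, _ = pca_reduce(data, 4)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_full_rank_reconstruction(self, data):
        k = np.linalg.matrix_rank(data - data.mean(axis=0))
        scores, loadings, _ = pca_reduce(data, k)
        rebuilt = scores @ loadings.T + data.mean(axis=0)
        assert np.max(np.abs(rebuilt - data)) < 1e-8

    def test_explained_variance_nonincreasing(self, data):
        _, _, explained = pca_reduce(data, 5)
        assert np.all(np.diff(explained) <= 1e-12)

    def test_excessive_k_rejected(self, data):
        with pytest.raises(ValueError, match="out of range"):
            pca_reduce(data, 7)


class TestCrossTerms:
    def test_zero_protein_block_zero_products(self):
        XL = np.ones((5, 3))
        assert np.all(cross_terms(XL, np.zeros((5, 2))) == 0)

    def test_single_pair_is_elementwise_product(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(7, 1)), rng.normal(size=(7, 1))
        assert np.allclose(cross_terms(a, b)[:, 0], a[:, 0] * b[:, 0])

    def test_dimension_is_always_p_times_k(self):
        rng = np.random.default_rng(2)
        XL, XP = rng.normal(size=(9, 4)), rng.normal(size=(9, 3))
        C = cross_terms(XL, XP)
        assert C.shape == (9, 12)
        # ligand-major ordering: column (a, b) at index a*k + b
        assert np.allclose(C[:, 2 * 3 + 1], XL[:, 2] * XP[:, 1])


class TestPls:
    def test_univariate_single_component_equals_ols(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(50, 1))
        y = 3.0 * x[:, 0] + rng.normal(size=50)
        model = pls_fit(x, y, 1)
        xc = x[:, 0] - x[:, 0].mean()
        yc = y - y.mean()
        ols_slope = float(xc @ yc / (xc @ xc))
        assert model.coef[0] == pytest.approx(ols_slope, abs=1e-8)
        assert np.max(np.abs(
            pls_predict(model, x) - (xc * ols_slope + y.mean()))) < 1e-8

    def test_noiseless_full_rank_exact_fit(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 5))
        b = rng.normal(size=5)
        y = X @ b
        model = pls_fit(X, y, 5)
        assert np.max(np.abs(pls_predict(model, X) - y)) < 1e-6

    def test_agrees_with_reference_implementation(self):
        """Predictions match scikit-learn PLSRegression to 1e-6 on 10 random
        problems (both on pre-scaled inputs)."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            n, m = int(rng.integers(20, 40)), int(rng.integers(3, 8))
            A = int(rng.integers(1, min(m, 4) + 1))
            X = rng.normal(size=(n, m))
            X = (X - X.mean(0)) / X.std(0)
            y = rng.normal(size=n)
            mine = pls_predict(pls_fit(X, y, A), X)
            ref = PLSRegression(n_components=A, scale=False) \
                .fit(X, y.reshape(-1, 1)).predict(X).ravel()
            assert np.max(np.abs(mine - ref)) < 1e-6

    def test_residuals_nonincreasing_in_components(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=30)
        norms = []
        for A in range(1, 7):
            resid = y - pls_predict(pls_fit(X, y, A), X)
            norms.append(np.linalg.norm(resid))
        assert all(b <= a + 1e-10 for a, b in zip(norms, norms[1:]))

    def test_exhausted_covariance_stops_early_with_warning(self):
        X = np.ones((10, 2)) * [[1.0, 2.0]]  # rank-0 after centering
        X[:, 0] = np.arange(10)
        y = 2.0 * X[:, 0]
        with pytest.warns(UserWarning, match="components|degenerate"):
            model = pls_fit(X, y, 2)
        assert model.n_components == 1

    def test_score_orthogonality_invariant(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(25, 5))
        y = rng.normal(size=25)
        model = pls_fit(X, y, 4)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8


class TestVip:
    def test_mean_square_is_one(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=30)
        ranking = importance_ranking(pls_fit(X, y, 3))
        vips = np.array([v for _, v in ranking])
        assert np.mean(vips ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_informative_column_ranks_first(self):
        """A single signal column among pure noise tops the VIP ranking in at
        least 19 of 20 seeded replicates."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 8))
            y = 2.0 * X[:, 3] + 0.3 * rng.normal(size=60)
            ranking = importance_ranking(pls_fit(X, y, 2))
            hits += ranking[0][0] == "x3"
        assert hits >= 19

    def test_pure_noise_has_no_systematic_winner(self):
        winners = []
        for seed in range(40):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(40, 6))
            y = rng.normal(size=40)
            winners.append(importance_ranking(pls_fit(X, y, 2))[0][0])
        counts = {w: winners.count(w) for w in set(winners)}
        assert max(counts.values()) <= 0.45 * len(winners)


@pytest.fixture(scope="module")
def pcm_frame():
    config = SyntheticConfig(seed=5, n_targets=7, n_molecules=80,
                             activities_per_target=50,
                             base_noise_sd=0.2,
                             extra_activity_types=False)
    store, _ = generate_chembl_store(config)
    return extract_pcm_dataset(store, "Sodium|Calcium")


class TestPipeline:
    def test_planted_bilinear_signal_recovered(self, pcm_frame):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = pcm_cross_validate(pcm_frame, seed=5)
        assert len(pcm_frame) == 300
        assert result.pearson_r > 0.9

    def test_shuffled_response_has_no_signal(self, pcm_frame):
        shuffled = pcm_frame.copy()
        shuffled["val"] = np.random.default_rng(5).permutation(
            shuffled["val"].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = pcm_cross_validate(shuffled, seed=5)
        assert abs(result.pearson_r) < 0.2

    def test_same_seed_same_r(self, pcm_frame):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = pcm_cross_validate(pcm_frame, seed=11, n_components=3)
            b = pcm_cross_validate(pcm_frame, seed=11, n_components=3)
        assert a.pearson_r == b.pearson_r

    def test_missing_sequence_is_error(self, pcm_frame):
        broken = pcm_frame.copy()
        broken.loc[0, "seq"] = None
        with pytest.raises(ValueError, match="sequence"):
            pcm_cross_validate(broken)

    def test_protein_components_clamped_with_warning(self, pcm_frame):
        subset = pcm_frame.groupby("target").head(7).reset_index(drop=True)
        with pytest.warns(UserWarning, match="clamped"):
            pcm_cross_validate(subset, n_components=2,
                               protein_components=17)


class TestFasta:
    def test_read_alignment_text(self):
        text = ">a\nAC-D\n>b\nACED\n"
        assert read_fasta_alignment(text) == ["AC-D", "ACED"]

    def test_unaligned_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            read_fasta_alignment(">a\nACD\n>b\nAC\n")
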