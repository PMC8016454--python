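"""Linear model: feature assembly, OLS fitting, prediction decomposition."""

import math

import numpy as np
import pandas as pd
import pytest

from dmsimpact._residues import AMINO_ACIDS
from dmsimpact.datasets import NormalizedScores
from dmsimpact.errors import ConsistencyError, MissingCellError, SingularDesignError
from dmsimpact.homologs import PSEUDOCOUNT, build_profile
from dmsimpact.matrix import fit_matrix
from dmsimpact.model import (
    ModelCoefficients,
    assemble_features,
    fit_coefficients,
    predict,
    single_feature_predictors,
)


def normal_equations(X, y):
    """Oracle: closed-form OLS via the normal equations."""
    return np.linalg.solve(X.T @ X, X.T @ y)


@pytest.fixture(scope="module")
def assembled(corpus_module):
    corpus, matrix = corpus_module
    frames = [
        assemble_features(p.scores, p.profile, matrix)
        for p in corpus.training_corpus()
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="module")
def corpus_module(request):
    corpus = request.getfixturevalue("corpus")
    matrix = fit_matrix([p.scores for p in corpus.training_corpus()])
    return corpus, matrix


class TestAssembleFeatures:
    def test_one_record_per_variant(self, corpus_module, assembled):
        corpus, _ = corpus_module
        n_variants = sum(len(p.scores) for p in corpus.training_corpus())
        assert len(assembled) == n_variants

    def test_absent_variant_frequency_is_pure_pseudocount(self):
        # depth-1 position (query only): an absent variant's frequency is
        # pseudocount / (1 + 20 * pseudocount)
        profile = build_profile("q", "A", alignment_rows=[])
        scores = NormalizedScores("q", {(1, "A", "V"): -0.5})
        matrix = fit_matrix([NormalizedScores("q", {(1, "A", "V"): -0.5})])
        feats = assemble_features(scores, profile, matrix)
        expected = math.log2(PSEUDOCOUNT / (1 + 20 * PSEUDOCOUNT))
        assert feats.loc[0, "log2_var_freq"] == pytest.approx(expected, rel=1e-12)

    def test_wt_sequence_mismatch_names_position(self, corpus_module):
        corpus, matrix = corpus_module
        protein = corpus.training_corpus()[0]
        bad = NormalizedScores(protein.protein_id, {(1, "W" if protein.profile.query_seq[0] != "W" else "Y", "A"): -0.1})
        with pytest.raises(ConsistencyError, match="position 1"):
            assemble_features(bad, protein.profile, matrix)

    def test_missing_matrix_cell_raises(self):
        profile = build_profile("q", "A", alignment_rows=[])
        scores = NormalizedScores("q", {(1, "A", "V"): -0.5})
        sparse = fit_matrix([NormalizedScores("q", {(1, "A", "C"): -0.2})])
        with pytest.raises(MissingCellError):
            assemble_features(scores, profile, sparse)


class TestFitCoefficients:
    def test_zero_noise_exact_recovery(self, zero_noise_corpus):
        c = zero_noise_corpus
        frames = [
            assemble_features(p.scores, p.profile, c.true_matrix)
            for p in c.training_corpus(use_truth_scores=True)
        ]
        fit = fit_coefficients(pd.concat(frames, ignore_index=True))
        np.testing.assert_allclose(
            fit.as_array(), c.true_coefficients.as_array(), atol=1e-10
        )

    def test_matches_normal_equations_oracle(self, assembled):
        fit = fit_coefficients(assembled)
        X = np.column_stack(
            [
                np.ones(len(assembled)),
                assembled["entropy"],
                assembled["log2_var_freq"],
                assembled["matrix_value"],
            ]
        )
        expected = normal_equations(X, assembled["dfitness"].to_numpy())
        np.testing.assert_allclose(fit.as_array(), expected, atol=1e-8)

    def test_noisy_recovery_within_standard_errors(self, corpus):
        c = corpus
        frames = [
            assemble_features(p.scores, p.profile, c.true_matrix)
            for p in c.training_corpus(use_truth_scores=True)
        ]
        records = pd.concat(frames, ignore_index=True)
        assert len(records) >= 10_000
        fit = fit_coefficients(records)
        X = np.column_stack(
            [
                np.ones(len(records)),
                records["entropy"],
                records["log2_var_freq"],
                records["matrix_value"],
            ]
        )
        resid = records["dfitness"].to_numpy() - X @ fit.as_array()
        sigma2 = resid @ resid / (len(records) - 4)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        err = np.abs(fit.as_array() - c.true_coefficients.as_array())
        assert np.all(err <= 4 * se)

    def test_collinear_feature_raises_singular_design(self):
        rng = np.random.default_rng(0)
        n = 50
        entropy = rng.uniform(0, 4, n)
        records = pd.DataFrame(
            {
                "entropy": entropy,
                "log2_var_freq": 2.0 * entropy - 1.0,  # exactly collinear
                "matrix_value": rng.uniform(-1, 0, n),
                "dfitness": rng.uniform(-1, 0, n),
            }
        )
        with pytest.raises(SingularDesignError):
            fit_coefficients(records)

    def test_constant_feature_names_offending_column(self):
        rng = np.random.default_rng(1)
        n = 30
        records = pd.DataFrame(
            {
                "entropy": rng.uniform(0, 4, n),
                "log2_var_freq": rng.uniform(-14, 0, n),
                "matrix_value": np.full(n, -0.3),  # constant -> collinear w/ intercept
                "dfitness": rng.uniform(-1, 0, n),
            }
        )
        with pytest.raises(SingularDesignError) as exc:
            fit_coefficients(records)
        assert exc.value.column in {"matrix", "intercept"}

    def test_too_few_records_rejected(self):
        records = pd.DataFrame(
            {
                "entropy": [1.0, 2.0],
                "log2_var_freq": [-3.0, -1.0],
                "matrix_value": [-0.5, -0.2],
                "dfitness": [-0.4, -0.1],
            }
        )
        with pytest.raises(ValueError):
            fit_coefficients(records)


@pytest.fixture(scope="module")
def setup(small_corpus, corpus):
    c = small_corpus
    pid = c.datasets[0].protein_id
    # matrix from the larger corpus so every substitution cell is observed
    matrix = fit_matrix([p.scores for p in corpus.training_corpus()])
    coefs = ModelCoefficients(-0.1, 0.05, 0.02, 0.9)
    return c.sequences[pid], c.profiles[pid], matrix, coefs


class TestPredict:
    def test_l_times_19_rows(self, setup):
        seq, profile, matrix, coefs = setup
        table = predict(seq, profile, matrix, coefs)
        assert len(table) == len(seq) * 19
        per_pos = table.groupby("pos").size()
        assert (per_pos == 19).all()

    def test_score_equals_intercept_plus_contributions(self, setup):
        seq, profile, matrix, coefs = setup
        table = predict(seq, profile, matrix, coefs)
        reconstructed = (
            coefs.beta0
            + table["contribution_entropy"]
            + table["contribution_freq"]
            + table["contribution_matrix"]
        )
        np.testing.assert_array_equal(table["score"].to_numpy(), reconstructed.to_numpy())

    def test_matrix_projection_with_unit_beta3(self, setup):
        seq, profile, matrix, _ = setup
        table = predict(seq, profile, matrix, ModelCoefficients(0, 0, 0, 1))
        np.testing.assert_array_equal(
            table["score"].to_numpy(), table["matrix"].to_numpy()
        )

    def test_doubling_beta3_doubles_matrix_contribution(self, setup):
        seq, profile, matrix, coefs = setup
        t1 = predict(seq, profile, matrix, coefs)
        t2 = predict(
            seq,
            profile,
            matrix,
            ModelCoefficients(coefs.beta0, coefs.beta1, coefs.beta2, 2 * coefs.beta3),
        )
        np.testing.assert_allclose(
            t2["contribution_matrix"], 2 * t1["contribution_matrix"], atol=1e-12
        )
        np.testing.assert_allclose(
            t2["contribution_entropy"], t1["contribution_entropy"], atol=1e-12
        )

    def test_within_position_ranking_independent_of_intercept_and_entropy(self, setup):
        seq, profile, matrix, coefs = setup
        base = predict(seq, profile, matrix, coefs)
        shifted = predict(
            seq, profile, matrix, ModelCoefficients(5.0, -3.0, coefs.beta2, coefs.beta3)
        )
        for pos, grp in base.groupby("pos"):
            order_a = grp.sort_values("score")["var"].tolist()
            grp_b = shifted[shifted["pos"] == pos]
            order_b = grp_b.sort_values("score")["var"].tolist()
            assert order_a == order_b

    def test_non_standard_query_residue_skipped_with_warning(self, setup):
        seq, profile, matrix, coefs = setup
        seq_x = "X" + seq[1:]
        prof_x = build_profile("q", seq_x, alignment_rows=[])
        with pytest.warns(UserWarning, match="non-standard"):
            table = predict(seq_x, prof_x, matrix, coefs)
        assert len(table) == (len(seq) - 1) * 19
        assert 1 not in set(table["pos"])

    def test_swapping_matrix_changes_only_matrix_column(self, setup):
        from dmsimpact.matrix import load_blosum

        seq, profile, matrix, coefs = setup
        base = predict(seq, profile, matrix, coefs)
        swapped = predict(seq, profile, load_blosum("BLOSUM62"), coefs)
        np.testing.assert_array_equal(base["entropy"], swapped["entropy"])
        np.testing.assert_array_equal(base["log2f_var"], swapped["log2f_var"])
        assert not np.array_equal(base["matrix"], swapped["matrix"])


class TestSingleFeaturePredictors:
    def test_components(self, assembled):
        preds = single_feature_predictors(assembled)
        np.testing.assert_array_equal(
            preds["conservation"], -assembled["entropy"].to_numpy()
        )
        np.testing.assert_array_equal(
            preds["frequency"], assembled["log2_var_freq"].to_numpy()
        )
        np.testing.assert_array_equal(
            preds["matrix"], assembled["matrix_value"].to_numpy()
        )


class TestCoefficientsIO:
    def test_round_trip(self, tmp_path):
        coefs = ModelCoefficients(-0.123456789, 0.05, 0.02, 0.987654321)
        path = tmp_path / "coefs.tsv"
        coefs.write(path)
        back = ModelCoefficients.read(path)
        assert back == coefs
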