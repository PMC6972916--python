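"""NMF pipeline and simplex-constrained least-squares deconvolution."""

import numpy as np
import pandas as pd
import pytest

from cfmarrow import deconvolution as dec
from cfmarrow import signatures as sig
from cfmarrow import synthetic as syn

TPM = 1.0e6


def simplex_ls_oracle(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Closed-form equality-constrained least squares (KKT system).

    Solves min ||A p - b||^2 s.t. sum(p) = 1 ignoring the non-negativity
    bound; valid as an oracle whenever its solution is element-wise >= 0.
    """
    k = A.shape[1]
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2 * A.T @ A
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([2 * A.T @ b, [1.0]])
    sol = np.linalg.solve(kkt, rhs)
    return sol[:k]


class TestFilterAndNormalize:
    def test_gene_below_threshold_removed(self):
        m = pd.DataFrame({"s1": [5.0, 10.0], "s2": [19.0, 50.0]},
                         index=["low", "hi"])
        norm, retained = dec.filter_and_normalize(m, min_tpm=20.0)
        assert retained == ["hi"]
        np.testing.assert_allclose(norm.loc["hi"], [0.2, 1.0])

    def test_every_row_peaks_at_one(self, mixture_set):
        mix, _ = mixture_set
        norm, _ = dec.filter_and_normalize(mix)
        np.testing.assert_allclose(norm.max(axis=1), 1.0)

    def test_retained_count_matches_brute_force(self, mixture_set):
        mix, _ = mixture_set
        _, retained = dec.filter_and_normalize(mix, min_tpm=20.0)
        expected = [g for g in mix.index if mix.loc[g].max() >= 20.0]
        assert retained == expected

    def test_all_filtered_is_error(self):
        m = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="no gene"):
            dec.filter_and_normalize(m, min_tpm=20.0)


class TestNmf:
    def test_rank_one_matrix_factorizes_exactly(self):
        rng = np.random.default_rng(0)
        u, v = rng.uniform(0.1, 1, 40), rng.uniform(0.1, 1, 6)
        m = pd.DataFrame(np.outer(u, v))
        d = dec.nmf_decompose(m, n_components=1, seed=0)
        assert d.reconstruction_error < 1e-8

    def test_noiseless_six_type_mixture_exact_rank_six(self, mixture_set):
        mix, _ = mixture_set
        norm, _ = dec.filter_and_normalize(mix)
        d = dec.nmf_decompose(norm, n_components=6, seed=0)
        assert d.reconstruction_error < 1e-6 * np.linalg.norm(norm.to_numpy())

    def test_objective_monotone_along_iteration_checkpoints(self, mixture_set):
        """Same deterministic init: longer runs never increase the objective."""
        mix, _ = mixture_set
        norm, _ = dec.filter_and_normalize(mix)
        errors = [
            dec.nmf_decompose(norm, 6, seed=0, max_iter=n, tol=1e-15).reconstruction_error
            for n in (20, 50, 100, 300, 1000)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))

    def test_sample_permutation_equivariance(self, mixture_set):
        mix, _ = mixture_set
        norm, _ = dec.filter_and_normalize(mix)
        perm = list(norm.columns[::-1])
        d1 = dec.nmf_decompose(norm, 4, seed=0, max_iter=500)
        d2 = dec.nmf_decompose(norm[perm], 4, seed=0, max_iter=500)
        np.testing.assert_allclose(
            d1.activities[perm].to_numpy(), d2.activities.to_numpy(),
            rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(d1.loadings.to_numpy(), d2.loadings.to_numpy(),
                                   rtol=1e-5, atol=1e-8)

    def test_bad_rank_rejected(self, mixture_set):
        mix, _ = mixture_set
        norm, _ = dec.filter_and_normalize(mix)
        with pytest.raises(ValueError, match="n_components"):
            dec.nmf_decompose(norm, 0)


class TestAnnotation:
    def test_unanimous_top_genes_annotate_component(self, reference_and_truth,
                                                    mixture_set):
        reference, truth = reference_and_truth
        mix, mix_truth = mixture_set
        norm, _ = dec.filter_and_normalize(mix)
        d = dec.nmf_decompose(norm, 6, seed=0)
        calls = sig.call_specific_genes(reference)
        annotations = dec.annotate_components(d, calls, top_n=25)
        labels = [v for v in annotations.values() if v != "unannotated"]
        assert len(labels) >= 5 and len(set(labels)) == len(labels)

    def test_no_calls_means_unannotated(self, mixture_set):
        mix, _ = mixture_set
        norm, _ = dec.filter_and_normalize(mix)
        d = dec.nmf_decompose(norm, 3, seed=0, max_iter=500)
        annotations = dec.annotate_components(d, [], top_n=10)
        assert set(annotations.values()) == {"unannotated"}

    def test_top_n_larger_than_gene_count_rejected(self, mixture_set):
        mix, _ = mixture_set
        norm, _ = dec.filter_and_normalize(mix)
        d = dec.nmf_decompose(norm, 3, seed=0, max_iter=200)
        with pytest.raises(ValueError, match="top_n"):
            dec.annotate_components(d, [], top_n=norm.shape[0] + 1)


@pytest.fixture(scope="module")
def signature(reference_and_truth):
    reference, truth = reference_and_truth
    markers = list(truth.marker_assignment)
    return (reference.div(reference.sum(axis=1), axis=0) * TPM)[markers]


class TestEstimateFractions:
    def test_pure_sample_is_vertex_solution(self, signature):
        sample = signature.iloc[2] * 0.37  # arbitrary rescale of one profile
        est = dec.estimate_fractions(sample, signature)
        expected = np.zeros(6)
        expected[2] = 1.0
        np.testing.assert_allclose(est.fractions.to_numpy(), expected, atol=1e-9)

    def test_noiseless_mixture_matches_kkt_oracle(self, signature):
        p_true = np.array([0.6, 0.3, 0.1, 0.0, 0.0, 0.0])
        sample = pd.Series(signature.to_numpy().T @ p_true, index=signature.columns)
        est = dec.estimate_fractions(sample, signature)
        np.testing.assert_allclose(est.fractions.to_numpy(), p_true, atol=1e-6)
        # interior-type oracle on the three active entities
        sub = signature.iloc[:3]
        oracle = simplex_ls_oracle(sub.to_numpy().T, sample.to_numpy())
        assert (oracle >= -1e-9).all()
        np.testing.assert_allclose(est.fractions.to_numpy()[:3], oracle, atol=1e-6)

    def test_duplicated_gene_row_leaves_solution_unchanged(self, signature):
        p_true = np.array([0.2, 0.2, 0.2, 0.2, 0.1, 0.1])
        sample = pd.Series(signature.to_numpy().T @ p_true, index=signature.columns)
        est = dec.estimate_fractions(sample, signature)
        dup_sig = pd.concat([signature, signature.iloc[:, [0]].add_suffix("_dup")],
                            axis=1)
        dup_sample = pd.concat([sample, sample.iloc[[0]].add_suffix("_dup")])
        est_dup = dec.estimate_fractions(dup_sample, dup_sig)
        np.testing.assert_allclose(est.fractions.to_numpy(),
                                   est_dup.fractions.to_numpy(), atol=1e-7)

    def test_joint_rescaling_invariance(self, signature):
        p_true = np.array([0.5, 0.1, 0.1, 0.1, 0.1, 0.1])
        sample = pd.Series(signature.to_numpy().T @ p_true, index=signature.columns)
        a = dec.estimate_fractions(sample, signature)
        b = dec.estimate_fractions(sample * 1e-4, signature * 1e-4)
        np.testing.assert_allclose(a.fractions.to_numpy(), b.fractions.to_numpy(),
                                   atol=1e-7)

    def test_rank_deficient_signature_warns_but_returns(self, signature):
        collinear = signature.copy()
        collinear.iloc[5] = 0.5 * collinear.iloc[0] + 0.5 * collinear.iloc[1]
        sample = signature.iloc[0]
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            est = dec.estimate_fractions(sample, collinear)
        assert est.rank_deficient
        assert est.fractions.sum() == pytest.approx(1.0)

    def test_single_entity_signature_rejected(self, signature):
        with pytest.raises(ValueError, match="two entities"):
            dec.estimate_fractions(signature.iloc[0], signature.iloc[[0]])


class TestComponentFractions:
    def test_contributions_sum_to_one_and_track_truth(self, reference_and_truth,
                                                      mixture_set):
        reference, _ = reference_and_truth
        mix, truth = mixture_set
        norm, _ = dec.filter_and_normalize(mix)
        d = dec.nmf_decompose(norm, 6, seed=0)
        dec.annotate_components(d, sig.call_specific_genes(reference))
        contributions = dec.component_fractions(d)
        np.testing.assert_allclose(contributions.sum(axis=1), 1.0, atol=1e-9)
        rhos = []
        for ct in truth.true_proportions.columns:
            if ct in contributions.columns:
                rhos.append(
                    pd.Series(contributions[ct].to_numpy()).corr(
                        pd.Series(truth.true_proportions[ct].to_numpy()),
                        method="spearman")
                )
        assert len(rhos) >= 5 and min(rhos) > 0.8

    def test_all_unannotated_is_error(self, mixture_set):
        mix, _ = mixture_set
        norm, _ = dec.filter_and_normalize(mix)
        d = dec.nmf_decompose(norm, 3, seed=0, max_iter=200)
        dec.annotate_components(d, [], top_n=10)
        with pytest.raises(ValueError, match="unannotated"):
            dec.component_fractions(d)

    def test_single_annotated_component_contributes_fully(self):
        d = dec.NmfDecomposition(
            loadings=pd.DataFrame(np.ones((4, 1)), columns=["C1"]),
            activities=pd.DataFrame([[2.0, 5.0]], index=["C1"],
                                    columns=["s1", "s2"]),
            n_components=1, reconstruction_error=0.0, converged=True,
            annotations={"C1": "megakaryocyte"},
        )
        contributions = dec.component_fractions(d)
        np.testing.assert_allclose(contributions["megakaryocyte"], 1.0)
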