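import numpy as np
import pytest
import scipy.linalg

from gradmap import (
    RunConfig,
    align_to_template,
    build_template,
    cosine_affinity,
    diffusion_embedding,
    sparsify_rows,
    subject_gradients,
)
from gradmap.connectivity import FISHER_Z, ConnectivityMatrix
from gradmap.gradients import GradientTemplate, _fix_signs


def dense_diffusion_oracle(w, n_components, alpha=0.5):
    """Independent diffusion-map computation via the nonsymmetric Markov
    operator and scipy.linalg.eig, following the same normalization
    conventions (unit-norm symmetric eigenvectors, division by the trivial
    eigenvector, multiscale lambda/(1-lambda) scaling)."""
    d = w.sum(axis=1)
    lmat = w * np.outer(d ** -alpha, d ** -alpha)
    d2 = lmat.sum(axis=1)
    markov = lmat / d2[:, None]
    evals, evecs = scipy.linalg.eig(markov)
    assert np.abs(evals.imag).max() < 1e-10
    evals = evals.real
    order = np.argsort(-evals)
    evals, evecs = evals[order], evecs[:, order].real
    # normalize each right eigenvector u so that ||d2^(1/2) u|| = 1
    evecs = evecs / np.linalg.norm(np.sqrt(d2)[:, None] * evecs, axis=0)
    psi = evecs / evecs[:, [0]]
    lam = evals[1:n_components + 1]
    return psi[:, 1:n_components + 1] * (lam / (1 - lam)), lam


def random_affinity(rng, p):
    m = rng.uniform(0.05, 1.0, size=(p, p))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return m


class TestSparsifyRows:
    def test_density_ten_percent_keeps_twenty_of_two_hundred(self, rng):
        z = rng.standard_normal((200, 200))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        sparse = sparsify_rows(z, 0.10)
        assert np.all((sparse != 0).sum(axis=1) == 20)

    def test_tie_break_keeps_lowest_indices(self):
        z = np.zeros((6, 6))
        z[0, 1:] = 3.0  # all equal off-diagonal in row 0
        sparse = sparsify_rows(z + z.T, density=0.4)  # k = round(0.4*5) = 2
        assert list(np.flatnonzero(sparse[0])) == [1, 2]

    def test_matches_full_sort_oracle(self, rng):
        p = 21
        z = rng.standard_normal((p, p))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        sparse = sparsify_rows(z, 0.1)  # k = 2
        for i in range(p):
            off = [(z[i, j], j) for j in range(p) if j != i]
            top = {j for _, j in sorted(off, key=lambda t: -t[0])[:2]}
            assert set(np.flatnonzero(sparse[i])) == top
            assert np.allclose(sparse[i, list(top)], z[i, list(top)])

    def test_zero_connections_per_row_errors(self):
        with pytest.raises(ValueError, match="zero connections"):
            sparsify_rows(np.zeros((5, 5)), 0.01)


class TestCosineAffinity:
    def test_identical_rows_have_unit_affinity(self):
        s = np.vstack([[1.0, 2.0, 0.0]] * 2 + [[0.0, 0.0, 3.0]])
        aff = cosine_affinity(s)
        assert aff.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_rows_have_zero_affinity(self):
        s = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.0, 1.0, 1.0]])
        assert cosine_affinity(s).matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        s = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        assert cosine_affinity(s).matrix[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_negative_similarities_clipped(self):
        s = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert cosine_affinity(s).matrix[0, 1] == 0.0

    def test_all_zero_row_errors(self):
        s = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="parcel 2"):
            cosine_affinity(s)


class TestDiffusionEmbedding:
    def test_two_block_affinity_separates_blocks_on_gradient_one(self):
        p = 12
        w = np.full((p, p), 0.01)
        w[:6, :6] = 0.9
        w[6:, 6:] = 0.9
        np.fill_diagonal(w, 1.0)
        emb = diffusion_embedding(w, n_components=3)
        g1 = emb.components[:, 0]
        assert np.ptp(np.sign(g1[:6])) == 0 and np.ptp(np.sign(g1[6:])) == 0
        assert np.sign(g1[0]) != np.sign(g1[-1])
        assert g1[:6].std() < 0.05 * abs(g1[:6].mean() - g1[6:].mean())

    @pytest.mark.parametrize("p", [10, 15, 20])
    def test_matches_dense_nonsymmetric_oracle(self, rng, p):
        w = random_affinity(rng, p)
        emb = diffusion_embedding(w, n_components=5)
        oracle, lam = dense_diffusion_oracle(w, 5)
        assert np.allclose(emb.eigenvalues, lam, atol=1e-10)
        for c in range(5):
            diff = min(
                np.abs(emb.components[:, c] - oracle[:, c]).max(),
                np.abs(emb.components[:, c] + oracle[:, c]).max(),
            )
            assert diff < 1e-8

    def test_explained_variance_normalization(self, rng):
        emb = diffusion_embedding(random_affinity(rng, 12), n_components=4)
        expected = emb.eigenvalues / emb.eigenvalues.sum()
        assert np.allclose(emb.explained_variance, expected, atol=1e-14)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-12)

    def test_disconnected_affinity_reports_component_sizes(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        with pytest.raises(ValueError, match=r"\[3, 3\]"):
            diffusion_embedding(w, n_components=2)

    def test_invariant_to_uniform_affinity_scaling(self, rng):
        w = random_affinity(rng, 14)
        a = diffusion_embedding(w, n_components=4)
        b = diffusion_embedding(0.37 * w, n_components=4)
        for c in range(4):
            diff = min(
                np.abs(a.components[:, c] - b.components[:, c]).max(),
                np.abs(a.components[:, c] + b.components[:, c]).max(),
            )
            assert diff < 1e-8


class TestTemplateAndAlignment:
    def _template(self, rng=None, p=40, m=5):
        rng = rng or np.random.default_rng(p * 1000 + 7)
        z = rng.standard_normal((p, p)) * 0.3
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        fc = ConnectivityMatrix(z, stage=FISHER_Z)
        return build_template(fc, RunConfig(n_components=m))

    def test_template_is_deterministic(self, rng):
        z = rng.standard_normal((30, 30))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        fc = ConnectivityMatrix(z, stage=FISHER_Z)
        t1 = build_template(fc, RunConfig(n_components=4))
        t2 = build_template(fc, RunConfig(n_components=4))
        assert np.array_equal(t1.embedding.components, t2.embedding.components)

    def test_sign_convention_largest_entry_positive(self):
        temp = self._template()
        comp = temp.embedding.components
        for c in range(comp.shape[1]):
            assert comp[np.argmax(np.abs(comp[:, c])), c] > 0

    def test_alignment_to_self_is_identity(self):
        temp = self._template()
        aligned = align_to_template(temp.embedding, temp)
        assert np.allclose(aligned.components, temp.embedding.components, atol=1e-10)
        assert aligned.aligned

    def test_planted_orthogonal_transform_recovered(self):
        temp = self._template()
        q, _ = np.linalg.qr(np.random.default_rng(3).standard_normal((5, 5)))
        rotated = temp.embedding
        rotated = type(rotated)(
            components=rotated.components @ q,
            eigenvalues=rotated.eigenvalues,
            explained_variance=rotated.explained_variance,
        )
        aligned = align_to_template(rotated, temp)
        err = np.linalg.norm(aligned.components - temp.embedding.components)
        assert err < 1e-8

    def test_sign_flips_are_restored(self):
        temp = self._template()
        flipped = type(temp.embedding)(
            components=temp.embedding.components * np.array([1, -1, 1, -1, 1]),
            eigenvalues=temp.embedding.eigenvalues,
            explained_variance=temp.embedding.explained_variance,
        )
        aligned = align_to_template(flipped, temp)
        assert np.allclose(aligned.components, temp.embedding.components, atol=1e-8)

    def test_alignment_preserves_pairwise_distances(self):
        temp = self._template()
        other = self._template(np.random.default_rng(99))
        aligned = align_to_template(other.embedding, temp)
        def pdist(x):
            return np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
        assert np.allclose(pdist(aligned.components), pdist(other.embedding.components), atol=1e-8)

    def test_dimension_mismatch_errors(self):
        temp = self._template()
        small = self._template(p=20)
        with pytest.raises(ValueError, match="match"):
            align_to_template(small.embedding, temp)

    def test_markov_orthogonality_of_template_columns(self, rng):
        # right eigenvectors of M are orthogonal under the D-row inner product
        p = 30
        z = rng.standard_normal((p, p)) * 0.3
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        fc = ConnectivityMatrix(z, stage=FISHER_Z)
        cfg = RunConfig(n_components=4)
        sparse = sparsify_rows(fc, cfg.density)
        aff = cosine_affinity(sparse).matrix
        d = aff.sum(axis=1)
        lmat = aff * np.outer(d ** -0.5, d ** -0.5)
        d2 = lmat.sum(axis=1)
        emb = diffusion_embedding(aff, n_components=4)
        gram = emb.components.T @ (d2[:, None] * emb.components)
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()


class TestSmallPipelineOracle:
    def test_full_chain_matches_brute_force(self, rng):
        """sparsify -> affinity -> embed on P=20 vs independent composition."""
        p = 20
        z = rng.standard_normal((p, p))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        fc = ConnectivityMatrix(z, stage=FISHER_Z)
        emb = subject_gradients(fc, RunConfig(density=0.2, n_components=4))
        # independent: full sort per row, explicit cosine, dense eig oracle
        k = round(0.2 * (p - 1))
        sparse = np.zeros_like(z)
        for i in range(p):
            order = sorted((j for j in range(p) if j != i), key=lambda j: (-z[i, j], j))
            sparse[i, order[:k]] = z[i, order[:k]]
        aff = np.zeros((p, p))
        for i in range(p):
            for j in range(p):
                aff[i, j] = sparse[i] @ sparse[j] / (
                    np.linalg.norm(sparse[i]) * np.linalg.norm(sparse[j])
                )
        aff = np.clip((aff + aff.T) / 2, 0.0, 1.0)
        np.fill_diagonal(aff, 1.0)
        oracle, _ = dense_diffusion_oracle(aff, 4)
        for c in range(4):
            diff = min(
                np.abs(emb.components[:, c] - oracle[:, c]).max(),
                np.abs(emb.components[:, c] + oracle[:, c]).max(),
            )
            assert diff < 1e-8


def test_fix_signs_orients_largest_entry_positive():
    comp = np.array([[0.1, -0.9], [-2.0, 0.3]])
    fixed = _fix_signs(comp)
    assert fixed[1, 0] == 2.0 and fixed[0, 1] == 0.9
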