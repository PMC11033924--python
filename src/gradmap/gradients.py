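"""Diffusion-map gradient embeddings of functional connectivity.

Pipeline: row-wise sparsification of the Fisher-z FC matrix (top 10% of
connections per row), cosine-similarity affinity between sparsified
connectivity profiles, diffusion-map embedding of the affinity (anisotropy
alpha = 0.5, multiscale diffusion time), a group template from the
group-mean FC, and orthogonal Procrustes alignment of each subject's
embedding to that template.

Gradient values have arbitrary units; only relative positions along each
axis are meaningful, which is why individual embeddings must be aligned to a
common template before any cross-subject comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph

from .connectivity import FISHER_Z, ConnectivityMatrix
from .dataio import RunConfig


@dataclass
class AffinityMatrix:
    """Nonnegative parcel-to-parcel similarity of connectivity profiles."""

    matrix: np.ndarray
    kernel: str = "cosine"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("affinity matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12, rtol=0.0):
            raise ValueError("affinity matrix must be symmetric to 1e-12")
        if self.matrix.min() < 0.0 or self.matrix.max() > 1.0 + 1e-12:
            raise ValueError("affinity entries must lie in [0, 1]")

    @property
    def n_parcels(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GradientEmbedding:
    """Parcels-by-components gradient coordinates with spectrum metadata.

    ``components[:, 0]`` and ``components[:, 1]`` are the first (G1) and
    second (G2) gradients. ``eigenvalues`` are the non-trivial eigenvalues of
    the Markov operator in descending order; ``explained_variance`` is each
    eigenvalue over the sum of retained eigenvalues.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    explained_variance: np.ndarray
    aligned: bool = False
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def n_parcels(self) -> int:
        return self.components.shape[0]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def gradient2d(self) -> np.ndarray:
        """First-two-gradient coordinates, shape (P, 2)."""
        return self.components[:, :2]


@dataclass
class GradientTemplate:
    """Reference embedding from the group-mean FC (never itself aligned)."""

    embedding: GradientEmbedding
    provenance: str = "group-mean FC"


def sparsify_rows(z: ConnectivityMatrix | np.ndarray, density: float = 0.10) -> np.ndarray:
    """Keep the k largest off-diagonal values per row, zero the rest.

    k = round(density * (P - 1)); selection is by signed value, ties broken
    by lower parcel index (stable sort). The result is generally asymmetric
    and the retained values are unchanged.
    """
    mat = z.matrix if isinstance(z, ConnectivityMatrix) else np.asarray(z, dtype=float)
    p = mat.shape[0]
    if not (0.0 < density < 1.0):
        raise ValueError("density must lie in (0, 1)")
    k = int(round(density * (p - 1)))
    if k < 1:
        raise ValueError(f"density {density} keeps zero connections per row (P={p})")
    work = mat.copy()
    np.fill_diagonal(work, -np.inf)
    order = np.argsort(-work, axis=1, kind="stable")
    sparse = np.zeros_like(mat)
    rows = np.arange(p)[:, None]
    top = order[:, :k]
    sparse[rows, top] = mat[rows, top]
    return sparse


def cosine_affinity(s: np.ndarray) -> AffinityMatrix:
    """Cosine similarity between rows, negatives clipped to zero, diagonal 1."""
    s = np.asarray(s, dtype=float)
    norms = np.linalg.norm(s, axis=1)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise ValueError(f"parcel {zero[0] + 1} has an all-zero connectivity row")
    a = (s @ s.T) / np.outer(norms, norms)
    np.clip(a, 0.0, 1.0, out=a)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return AffinityMatrix(matrix=a)


def diffusion_embedding(
    w: AffinityMatrix | np.ndarray,
    n_components: int = 10,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
) -> GradientEmbedding:
    """Diffusion-map embedding of a nonnegative affinity matrix.

    Steps: anisotropic normalization ``W' = D^-alpha W D^-alpha`` with D the
    row-sum diagonal of W; row-normalize W' into a Markov operator M; take
    the leading eigenpairs of M via its symmetric conjugate
    ``D'^(1/2) M D'^(-1/2)``; discard the trivial constant eigenvector
    (eigenvalue 1); scale component c by ``lambda_c^t``, or by
    ``lambda_c / (1 - lambda_c)`` when ``diffusion_time == 0`` (multiscale).
    Components are ordered by descending eigenvalue; explained variance is
    each retained eigenvalue over their sum.
    """
    mat = w.matrix if isinstance(w, AffinityMatrix) else np.asarray(w, dtype=float)
    p = mat.shape[0]
    if n_components >= p:
        raise ValueError(f"n_components ({n_components}) must be < P ({p})")
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(mat > 0), directed=False
    )
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(f"affinity graph is disconnected: component sizes {sizes}")

    d = mat.sum(axis=1)
    d_alpha = d ** (-alpha)
    lmat = mat * np.outer(d_alpha, d_alpha)  # W'
    d2 = lmat.sum(axis=1)  # row sums of W'
    inv_sqrt = 1.0 / np.sqrt(d2)
    sym = lmat * np.outer(inv_sqrt, inv_sqrt)  # symmetric conjugate of M
    sym = (sym + sym.T) / 2.0
    evals, evecs = scipy.linalg.eigh(sym, subset_by_index=[p - (n_components + 1), p - 1])
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    if abs(evals[0] - 1.0) > 1e-8:
        raise ValueError(f"leading eigenvalue {evals[0]} differs from 1; invalid Markov operator")
    # back-transform to right eigenvectors of M, fix scale against the
    # trivial eigenvector so the retained columns are comparable across runs
    psi = evecs * inv_sqrt[:, None]
    psi = psi / psi[:, [0]]
    lambdas = evals[1:]
    if diffusion_time == 0.0:
        scale = lambdas / (1.0 - lambdas)
    else:
        scale = lambdas ** diffusion_time
    components = psi[:, 1:] * scale[None, :]
    total = lambdas.sum()
    explained = lambdas / total if total > 0 else np.zeros_like(lambdas)
    return GradientEmbedding(
        components=components,
        eigenvalues=lambdas,
        explained_variance=explained,
        aligned=False,
    )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic orientation: each column's largest-|.| entry positive."""
    out = components.copy()
    for c in range(out.shape[1]):
        col = out[:, c]
        s = np.sign(col[np.argmax(np.abs(col))])
        if s < 0:
            out[:, c] = -col
    return out


def subject_gradients(
    fc_z: ConnectivityMatrix, cfg: RunConfig | None = None
) -> GradientEmbedding:
    """Sparsify -> cosine affinity -> diffusion embedding for one FC matrix."""
    cfg = cfg or RunConfig()
    if fc_z.stage != FISHER_Z:
        raise ValueError("gradients are computed from Fisher-z connectivity")
    sparse = sparsify_rows(fc_z, cfg.density)
    affinity = cosine_affinity(sparse)
    emb = diffusion_embedding(
        affinity, n_components=cfg.n_components, alpha=cfg.alpha,
        diffusion_time=cfg.diffusion_time,
    )
    return replace(emb, subject_id=fc_z.subject_id)


def build_template(group_fc: ConnectivityMatrix, cfg: RunConfig | None = None) -> GradientTemplate:
    """Gradient template from the group-mean FC with fixed sign convention."""
    emb = subject_gradients(group_fc, cfg)
    emb = replace(emb, components=_fix_signs(emb.components), subject_id="template")
    return GradientTemplate(embedding=emb)


def align_to_template(emb: GradientEmbedding, template: GradientTemplate) -> GradientEmbedding:
    """Orthogonal Procrustes alignment of a subject embedding to the template.

    Solves ``min_R ||X R - T||_F`` over orthogonal R (rotation + reflection,
    no scaling or translation) jointly on all retained components, via the
    SVD of X'T.
    """
    target = template.embedding.components
    if emb.components.shape != target.shape:
        raise ValueError(
            f"embedding shape {emb.components.shape} does not match template {target.shape}"
        )
    rot, _ = scipy.linalg.orthogonal_procrustes(emb.components, target)
    return replace(emb, components=emb.components @ rot, aligned=True)
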