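"""Voxel-TAC unmixing: PCA reduction, whitening, non-negative ICA, NMF.

The decomposition chain applied to the heart-VOI voxel-TAC matrix Z
(n_frames x n_voxels, one column per voxel):

1. rank reduction with the n leading covariance eigenvectors B, x = B^T Z;
2. symmetric (ZCA) whitening, z = E D^{-1/2} E^T x = M x;
3. non-negative ICA — rotation descent minimizing the mean squared negative
   part of y = W z (Plumbley-style geodesic updates on the orthogonal
   group);
4. the mixing matrix is mapped back to the original frame space,
   A = B M^{-1} W^T, and G0 = |A|, H0 = |y| initialize multiplicative-update
   NMF for the Frobenius loss, giving Z ~ G H with component TACs in the
   columns of G and voxel weights in the rows of H.

Non-negative ICA alone would suffice for perfectly well-grounded sources;
the NMF refinement relaxes the orthogonality assumption that real tracer
kinetics violate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .io import DynamicImage, Tac, _as_framing

__all__ = [
    "RankDeficiencyError",
    "VoxelTacMatrix",
    "PcaReduction",
    "WhiteningResult",
    "NnIcaResult",
    "NmfDecomposition",
    "build_voxel_matrix",
    "pca_reduce",
    "whiten",
    "nonneg_ica",
    "nmf",
    "unmix_voi",
]


class RankDeficiencyError(ValueError):
    """Requested more components than the data can support."""


@dataclass
class VoxelTacMatrix:
    """Matrix of voxel TACs from a VOI: Z is (n_frames, n_voxels).

    Negative entries (reconstruction noise) are clipped to zero on
    construction; the total clipped mass is recorded for diagnostics.
    """

    Z: np.ndarray
    voxel_indices: np.ndarray  # (n_voxels, 3) integer grid indices
    framing: np.ndarray
    clipped_mass: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.Z.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.Z.shape[1]

    @property
    def frame_mid_times_s(self) -> np.ndarray:
        return self.framing[:, 0] + self.framing[:, 1] / 2.0

    @property
    def frame_durations_s(self) -> np.ndarray:
        return self.framing[:, 1]


def build_voxel_matrix(image: DynamicImage, mask: np.ndarray) -> VoxelTacMatrix:
    """Extract the voxel-TAC matrix for a boolean voxel mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.grid_shape:
        raise ValueError("mask shape does not match the image grid")
    if not mask.any():
        raise ValueError("mask selects no voxels")
    Z = image.data[mask].T.astype(float)  # (n_frames, n_voxels)
    clipped = float(-Z[Z < 0].sum())
    Z = np.clip(Z, 0.0, None)
    return VoxelTacMatrix(
        Z=Z,
        voxel_indices=np.argwhere(mask),
        framing=_as_framing(image.framing),
        clipped_mass=clipped,
    )


def _fix_eigvec_signs(V: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude entry positive (determinism)."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


@dataclass
class PcaReduction:
    B: np.ndarray  # (n_frames, n) leading covariance eigenvectors
    x: np.ndarray  # (n, n_voxels) reduced data, x = B^T Z
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    n_components: int


def pca_reduce(Zmat: VoxelTacMatrix, n: int) -> PcaReduction:
    """Reduce Z to its n leading principal directions.

    Eigenvectors come from the frame-by-frame covariance of Z (voxels are
    the observations, so frame means are removed in the covariance), but
    the reduction is applied to the uncentered data: x = B^T Z.
    """
    Z = Zmat.Z
    if not 1 <= n <= min(Z.shape):
        raise ValueError(f"n must be in 1..{min(Z.shape)}")
    if Z.shape[1] < 2:
        raise ValueError("need at least 2 voxels to form a covariance")
    C = np.cov(Z)
    C = np.atleast_2d(C)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = _fix_eigvec_signs(evecs[:, order])
    if evals[n - 1] <= 1e-12 * max(evals[0], 1e-300):
        raise RankDeficiencyError(
            f"data rank is below {n} requested components; reduce n"
        )
    B = evecs[:, :n]
    return PcaReduction(B=B, x=B.T @ Z, eigenvalues=evals, n_components=n)


@dataclass
class WhiteningResult:
    E: np.ndarray
    D: np.ndarray  # eigenvalues of cov(x), non-increasing
    M: np.ndarray  # symmetric whitening matrix E D^{-1/2} E^T
    M_inv: np.ndarray
    z: np.ndarray  # whitened data, z = M x


def whiten(x: np.ndarray) -> WhiteningResult:
    """Symmetric (ZCA) whitening of the reduced data.

    cov(z) = I because cov(Mx) = M cov(x) M^T and M = cov(x)^{-1/2}.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    C = np.atleast_2d(np.cov(x))
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = _fix_eigvec_signs(evecs[:, order])
    if evals[-1] <= 1e-12 * max(evals[0], 1e-300):
        raise RankDeficiencyError(
            "covariance of reduced data is near-singular; use a smaller n"
        )
    M = evecs @ np.diag(evals**-0.5) @ evecs.T
    M_inv = evecs @ np.diag(evals**0.5) @ evecs.T
    return WhiteningResult(E=evecs, D=evals, M=M, M_inv=M_inv, z=M @ x)


@dataclass
class NnIcaResult:
    W: np.ndarray  # orthonormal demixing rotation (n, n)
    y: np.ndarray  # sources, y = W z
    objective_history: np.ndarray  # mean squared negative part, non-increasing
    A: np.ndarray | None = None  # mixing matrix in frame space, B M^{-1} W^T


def _nonneg_objective(y: np.ndarray) -> float:
    return float(np.mean(np.minimum(y, 0.0) ** 2))


def nonneg_ica(
    z: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> NnIcaResult:
    """Non-negative ICA by geodesic rotation descent.

    Minimizes J(W) = mean(min(Wz, 0)^2) over orthogonal W, following the
    torque/axis-pair rotation idea: the gradient of J restricted to the
    rotation group is the skew-symmetric torque (y^- y^T - y y^-T)/N, and
    each accepted step moves along its matrix exponential geodesic.  The
    step size is halved whenever a trial increases the objective, so the
    recorded objective history is non-increasing by construction.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    n, n_samples = z.shape
    Cz = np.atleast_2d(np.cov(z))
    if np.max(np.abs(Cz - np.eye(n))) > 0.01:
        raise ValueError("input to nonneg_ica must be whitened (cov ~ identity)")

    rng = np.random.default_rng(seed)
    Q, R = np.linalg.qr(rng.standard_normal((n, n)))
    W = Q * np.sign(np.diag(R))  # deterministic random rotation

    obj = _nonneg_objective(W @ z)
    history = [obj]
    mu = 1.0
    for _ in range(max_iter):
        y = W @ z
        yneg = np.minimum(y, 0.0)
        torque = (yneg @ y.T - y @ yneg.T) / n_samples
        if np.max(np.abs(torque)) < 1e-15 or obj < 1e-30:
            break
        accepted = False
        for _ in range(60):
            W_try = expm(-mu * torque) @ W
            obj_try = _nonneg_objective(W_try @ z)
            if obj_try < obj:
                accepted = True
                break
            mu /= 2.0
        if not accepted:
            break
        rel_decrease = (obj - obj_try) / max(obj, 1e-300)
        W, obj = W_try, obj_try
        history.append(obj)
        mu *= 1.5
        if rel_decrease < tol:
            break
    return NnIcaResult(W=W, y=W @ z, objective_history=np.asarray(history))


@dataclass
class NmfDecomposition:
    G: np.ndarray  # (n_frames, n) component TACs
    H: np.ndarray  # (n, n_voxels) voxel weights
    G0: np.ndarray
    H0: np.ndarray
    error_history: np.ndarray  # Frobenius reconstruction error per iteration

    @property
    def n_components(self) -> int:
        return self.G.shape[1]


def nmf(
    Zmat: VoxelTacMatrix | np.ndarray,
    G0: np.ndarray,
    H0: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NmfDecomposition:
    """Frobenius NMF with multiplicative updates from given initializers.

    The classical interleaved updates
    ``H <- H * (G^T Z) / (G^T G H)``, ``G <- G * (Z H^T) / (G H H^T)``
    keep the factors non-negative and never increase the reconstruction
    error; a zero column of G0 (or zero row of H0) can never escape zero,
    so those are rejected up front.  Stops when the relative error decrease
    drops below ``tol``.
    """
    Z = Zmat.Z if isinstance(Zmat, VoxelTacMatrix) else np.asarray(Zmat, float)
    G = np.array(G0, dtype=float, copy=True)
    H = np.array(H0, dtype=float, copy=True)
    if G.ndim != 2 or H.ndim != 2 or G.shape[1] != H.shape[0]:
        raise ValueError("G0 (n_frames, n) and H0 (n, n_voxels) shapes are inconsistent")
    if G.shape[0] != Z.shape[0] or H.shape[1] != Z.shape[1]:
        raise ValueError("initializer shapes do not match Z")
    if np.any(G < 0) or np.any(H < 0):
        raise ValueError("initializers must be non-negative")
    if np.any(G.sum(axis=0) == 0) or np.any(H.sum(axis=1) == 0):
        raise ValueError(
            "zero initializer component: multiplicative updates cannot escape zeros"
        )
    eps = 1e-12
    err = float(np.linalg.norm(Z - G @ H))
    history = [err]
    for _ in range(max_iter):
        H *= (G.T @ Z) / np.maximum(G.T @ G @ H, eps)
        G *= (Z @ H.T) / np.maximum(G @ H @ H.T, eps)
        new_err = float(np.linalg.norm(Z - G @ H))
        history.append(new_err)
        if (err - new_err) < tol * max(history[0], 1e-300):
            err = new_err
            break
        err = new_err
    return NmfDecomposition(G=G, H=H, G0=np.asarray(G0, float), H0=np.asarray(H0, float),
                            error_history=np.asarray(history))


def unmix_voi(
    Zmat: VoxelTacMatrix,
    n: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[NmfDecomposition, NnIcaResult]:
    """Full chain: PCA -> whitening -> non-negative ICA -> NMF.

    Returns the NMF decomposition plus the ICA stage (whose ``A`` field is
    filled in with the frame-space mixing matrix B M^{-1} W^T).
    """
    pca = pca_reduce(Zmat, n)
    wh = whiten(pca.x)
    ica = nonneg_ica(wh.z, max_iter=max_iter, tol=tol, seed=seed)
    ica.A = pca.B @ wh.M_inv @ ica.W.T
    G0 = np.abs(ica.A)
    H0 = np.abs(ica.y)
    # guard against an exactly zero initializer component (degenerate data)
    G0 = np.maximum(G0, 1e-12 * max(G0.max(), 1.0))
    H0 = np.maximum(H0, 1e-12 * max(H0.max(), 1.0))
    decomp = nmf(Zmat, G0, H0, max_iter=max_iter, tol=tol)
    return decomp, ica
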