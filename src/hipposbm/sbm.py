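"""Core source-based morphometry decomposition.

The subjects-by-voxels matrix X is column-centred, its model order chosen by
minimum description length (MDL) on the subject-space covariance
eigenspectrum, reduced and whitened by PCA, unmixed by Infomax ICA
(natural-gradient maximum-entropy learning with a logistic nonlinearity),
and finally expressed as X ~= A S with per-subject loading coefficients A
(N x K) and spatial sources S (K x V).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ICADecomposition",
    "NumericError",
    "RankError",
    "center_matrix",
    "estimate_order_mdl",
    "mdl_curve",
    "pca_whiten",
    "infomax_ica",
    "back_reconstruct",
    "decompose",
]


class NumericError(RuntimeError):
    """Non-finite values encountered during estimation."""


class RankError(ValueError):
    """Requested subspace dimension exceeds the matrix rank."""


@dataclass
class ICADecomposition:
    """Loading coefficients and spatial sources with X_centered ~= A S."""

    A: np.ndarray  # N x K loading coefficients
    S: np.ndarray  # K x V sources, rows standardized to unit SD
    convergence_info: dict = field(default_factory=dict)
    seed: int | None = None
    column_means: np.ndarray | None = None
    flagged: list[dict] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.S.shape[0]

    def residual(self, X_centered: np.ndarray) -> float:
        """Relative Frobenius residual of the rank-K factorization."""
        num = np.linalg.norm(X_centered - self.A @ self.S)
        return float(num / np.linalg.norm(X_centered))


def center_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove voxel (column) means; row means are retained so the
    subject-space covariance keeps its between-subject structure."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 rows")
    means = X.mean(axis=0)
    return X - means, means


def _subject_eigenvalues(X_centered: np.ndarray) -> np.ndarray:
    N, V = X_centered.shape
    C = (X_centered @ X_centered.T) / V
    lam = np.linalg.eigvalsh(C)[::-1]
    if not np.all(np.isfinite(lam)):
        raise NumericError("non-finite eigenvalues in subject covariance")
    return np.clip(lam, 0.0, None)


def mdl_curve(X_centered: np.ndarray, k_max: int) -> np.ndarray:
    """MDL(k) for k = 1..k_max from the subject-space eigenspectrum.

    MDL(k) = -V (N-k) log(g_k / a_k) + 0.5 k (2N - k) log V, with g_k and
    a_k the geometric and arithmetic means of the trailing eigenvalues
    lambda_{k+1..N}.
    """
    X_centered = np.asarray(X_centered, dtype=float)
    N, V = X_centered.shape
    if not 1 <= k_max < min(N, V):
        raise ValueError(f"k_max must lie in [1, {min(N, V) - 1})")
    lam = _subject_eigenvalues(X_centered)
    # column centering makes the rows sum to zero, so the smallest
    # eigenvalue is numerically zero; restrict to the positive spectrum
    eps = np.finfo(float).eps * max(lam[0], 1.0) * N
    lam = lam[lam > eps]
    N = len(lam)
    if k_max >= N:
        raise ValueError(f"k_max must be below the effective rank {N}")
    log_lam = np.log(lam)
    # suffix cumulative sums for trailing means
    suf_sum = np.cumsum(lam[::-1])[::-1]
    suf_logsum = np.cumsum(log_lam[::-1])[::-1]
    ks = np.arange(1, k_max + 1)
    out = np.empty(k_max)
    for i, k in enumerate(ks):
        m = N - k
        a = suf_sum[k] / m
        log_g = suf_logsum[k] / m
        out[i] = -V * m * (log_g - np.log(a)) + 0.5 * k * (2 * N - k) * np.log(V)
    return out


def estimate_order_mdl(X: np.ndarray, k_max: int) -> int:
    """Model order minimizing the MDL criterion (columns are centred first).

    ``k_max`` is clamped below the effective rank of the centred matrix
    (N - 1 for full-rank data, since centring zeroes one eigenvalue).
    """
    X_centered, _ = center_matrix(X)
    lam = _subject_eigenvalues(X_centered)
    eps = np.finfo(float).eps * max(lam[0], 1.0) * len(lam)
    rank = int(np.sum(lam > eps))
    curve = mdl_curve(X_centered, min(k_max, rank - 1))
    return int(np.argmin(curve)) + 1


def pca_whiten(
    X_centered: np.ndarray, K: int, rank_tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project onto the top-K subject-space principal axes and whiten.

    Returns (Z, whitening, dewhitening): Z = whitening @ X_centered is K x V
    with row covariance (Z Z^T / V) equal to the identity, and
    dewhitening @ whitening is the identity on the retained subspace.
    """
    X_centered = np.asarray(X_centered, dtype=float)
    N, V = X_centered.shape
    C = (X_centered @ X_centered.T) / V
    lam, E = np.linalg.eigh(C)
    lam, E = lam[::-1], E[:, ::-1]
    if K > N or lam[K - 1] <= rank_tol * max(lam[0], 1.0):
        raise RankError(
            f"K={K} exceeds the effective rank of X "
            f"(note: column centring caps it at N - 1)"
        )
    d = np.sqrt(lam[:K])
    whitening = (E[:, :K] / d).T          # K x N
    dewhitening = E[:, :K] * d            # N x K
    Z = whitening @ X_centered
    return Z, whitening, dewhitening


def _sigmoid(u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


def infomax_ica(
    Z: np.ndarray,
    learning_rate: float | None = None,
    max_iter: int = 512,
    tol: float = 1e-5,
    seed: int | None = None,
    block: int | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Infomax ICA on whitened data by stochastic natural-gradient ascent.

    Mini-batches are random voxel permutations; the update is
    dW = eta (I + (1 - 2 y) u^T / B) W with y = logistic(u), u = W z. The
    learning rate anneals (halves) when successive full-pass updates turn by
    more than 60 degrees, and the pass loop stops when ||dW||_F < tol.
    Divergence (non-finite W) restarts with a halved initial rate up to 3
    times. Non-convergence within ``max_iter`` passes is recorded in the
    returned info dict rather than raised.

    Returns (W, S, convergence_info) with S = W Z.
    """
    Z = np.asarray(Z, dtype=float)
    K, V = Z.shape
    if K < 1:
        raise ValueError("Z must have at least one row")
    if K == 1:
        W = np.ones((1, 1))
        return W, W @ Z, {"converged": True, "n_iter": 0, "final_update_norm": 0.0}
    rng = np.random.default_rng(seed)
    eta0 = learning_rate if learning_rate is not None else 0.01 / np.log(max(K, 3))
    if block is None:
        block = max(8, int(np.floor(np.sqrt(V / 3.0))))
    W0 = np.linalg.qr(rng.standard_normal((K, K)))[0]

    for attempt in range(4):
        eta = eta0 / (2**attempt)
        W = W0.copy()
        prev_dW = None
        update_norm = np.inf
        n_iter = 0
        diverged = False
        for it in range(max_iter):
            n_iter = it + 1
            perm = rng.permutation(V)
            W_old = W.copy()
            ok = True
            for start in range(0, V - block + 1, block):
                idx = perm[start : start + block]
                u = W @ Z[:, idx]
                y = _sigmoid(u)
                grad = np.eye(K) + (1.0 - 2.0 * y) @ u.T / idx.size
                W = W + eta * grad @ W
                if not np.all(np.isfinite(W)) or np.max(np.abs(W)) > 1e8:
                    ok = False
                    break
            if not ok:
                diverged = True
                break
            dW = W - W_old
            update_norm = float(np.linalg.norm(dW))
            if prev_dW is not None:
                denom = np.linalg.norm(dW) * np.linalg.norm(prev_dW)
                if denom > 0:
                    cosang = float(np.sum(dW * prev_dW) / denom)
                    if cosang < 0.5:  # turned by more than 60 degrees
                        eta *= 0.5
            prev_dW = dW
            if update_norm < tol:
                break
        if not diverged:
            info = {
                "converged": bool(update_norm < tol),
                "n_iter": n_iter,
                "final_update_norm": update_norm,
                "learning_rate_final": eta,
                "restarts": attempt,
            }
            return W, W @ Z, info
    raise NumericError("Infomax diverged repeatedly; learning rate too large for this data")


def back_reconstruct(
    X_centered: np.ndarray,
    S: np.ndarray,
    dewhitening: np.ndarray,
    W: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Loading coefficients A with X_topK = A S, plus canonicalized sources.

    A = dewhitening W^{-1}; each source row is then standardized to unit SD
    with the scale absorbed into A's column, and its sign fixed so the
    largest-|value| voxel is positive (sign absorbed into A as well).
    """
    S = np.asarray(S, dtype=float).copy()
    try:
        W_inv = np.linalg.inv(np.asarray(W, dtype=float))
    except np.linalg.LinAlgError as exc:
        raise NumericError("unmixing matrix is singular") from exc
    A = np.asarray(dewhitening, dtype=float) @ W_inv
    A = A.copy()
    for k in range(S.shape[0]):
        sd = S[k].std()
        if sd == 0:
            raise NumericError(f"source {k} has zero variance")
        S[k] /= sd
        A[:, k] *= sd
        j = int(np.argmax(np.abs(S[k])))
        if S[k, j] < 0:
            S[k] = -S[k]
            A[:, k] = -A[:, k]
    return A, S


def decompose(
    X: np.ndarray,
    K: int | None = None,
    k_max: int = 30,
    seed: int | None = None,
    **ica_kwargs,
) -> ICADecomposition:
    """Single-run pipeline: centre, (optionally) pick K by MDL, whiten,
    run Infomax, back-reconstruct."""
    X_centered, means = center_matrix(X)
    if K is None:
        K = estimate_order_mdl(X, min(k_max, X.shape[0] - 1))
    Z, _, dewhite = pca_whiten(X_centered, K)
    W, S, info = infomax_ica(Z, seed=seed, **ica_kwargs)
    A, S = back_reconstruct(X_centered, S, dewhite, W)
    return ICADecomposition(A=A, S=S, convergence_info=info, seed=seed, column_means=means)
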