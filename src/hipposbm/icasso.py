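"""ICASSO-style stability analysis for ICA.

ICA is rerun under random initializations on the same whitened data
(RandInit mode), all run-components are compared by absolute spatial
correlation, clustered by average-linkage agglomeration, and each cluster is
summarized by its quality index Iq and its centrotype (the member most
similar to the rest of its cluster). A cluster whose size falls outside the
expected band — ideally one member per run — marks an unstable component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .sbm import ICADecomposition, NumericError, infomax_ica

__all__ = [
    "IcassoResult",
    "StabilityError",
    "run_icasso",
    "select_stable_components",
    "plot_similarity",
]


class StabilityError(RuntimeError):
    """Too many failed runs, or no stable component survived."""


@dataclass
class IcassoResult:
    """All runs, their pairwise similarity, and the cluster summary."""

    runs: list[tuple[np.ndarray, np.ndarray] | None]  # per run (W, S); None if failed
    similarity: np.ndarray          # (R'K) x (R'K) |corr| over successful runs
    clusters: list[np.ndarray]      # K index sets into the stacked components
    iq: np.ndarray                  # per-cluster quality index in [-1, 1]
    centrotypes: np.ndarray         # per-cluster stacked-component index
    cluster_sizes: np.ndarray
    stable: np.ndarray              # size within [min_size, max_size]
    sources: np.ndarray             # stacked sources of successful runs, (R'K) x V
    run_of: np.ndarray              # stacked index -> run index
    K: int
    n_runs: int
    size_bounds: tuple[int, int]
    seed: int | None = None
    convergence: list[dict] = field(default_factory=list)


def _abs_corr(sources: np.ndarray) -> np.ndarray:
    Xc = sources - sources.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    norms[norms == 0] = 1.0
    Xn = Xc / norms[:, None]
    sim = np.abs(Xn @ Xn.T)
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, 0.0, 1.0)


def cluster_quality_index(similarity: np.ndarray, members: np.ndarray) -> float:
    """Iq = mean within-cluster similarity minus mean similarity between
    cluster members and all non-members. 1 for a perfectly tight, perfectly
    isolated cluster; sign flips of sources leave it unchanged because the
    similarity is an absolute correlation."""
    n = similarity.shape[0]
    members = np.asarray(members)
    inside = np.zeros(n, dtype=bool)
    inside[members] = True
    sub = similarity[np.ix_(members, members)]
    if len(members) > 1:
        intra = float((sub.sum() - len(members)) / (len(members) * (len(members) - 1)))
    else:
        intra = 1.0
    if inside.all():
        extra = 0.0
    else:
        extra = float(similarity[np.ix_(members, ~inside)].mean())
    return intra - extra


def run_icasso(
    Z: np.ndarray,
    K: int,
    n_runs: int = 20,
    mode: str = "RandInit",
    seed: int | None = None,
    min_size: int = 16,
    max_size: int = 20,
    run_seeds: list[int] | None = None,
    **ica_kwargs,
) -> IcassoResult:
    """Repeat Infomax ICA ``n_runs`` times and cluster the components.

    Per-run seeds derive from the master seed. Components are compared by
    absolute correlation over voxels; average-linkage clustering of
    1 - |corr| is cut at K clusters. Runs whose ICA fails (after its internal
    restarts) are recorded and excluded; more than 20% failures raises a
    stability error.
    """
    if mode != "RandInit":
        raise ValueError("only RandInit mode is supported (bootstrap is out of scope)")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if run_seeds is None:
        ss = np.random.SeedSequence(seed)
        run_seeds = [int(s) for s in ss.generate_state(n_runs) % (2**31)]
    elif len(run_seeds) != n_runs:
        raise ValueError("run_seeds must have one entry per run")
    runs: list[tuple[np.ndarray, np.ndarray] | None] = []
    convergence: list[dict] = []
    for r in range(n_runs):
        try:
            W, S, info = infomax_ica(Z, seed=run_seeds[r], **ica_kwargs)
            runs.append((W, S))
            convergence.append(info)
        except NumericError as exc:
            runs.append(None)
            convergence.append({"failed": True, "error": str(exc)})
    ok = [r for r in runs if r is not None]
    if len(ok) < 0.8 * n_runs:
        raise StabilityError(f"{n_runs - len(ok)}/{n_runs} ICA runs failed")

    sources = np.vstack([S for _, S in ok])
    run_of = np.repeat(
        [i for i, r in enumerate(runs) if r is not None], K
    )
    sim = _abs_corr(sources)
    dissim = 1.0 - sim
    np.fill_diagonal(dissim, 0.0)
    link = linkage(squareform(dissim, checks=False), method="average")
    labels = fcluster(link, t=K, criterion="maxclust")
    clusters = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    iq = np.array([cluster_quality_index(sim, m) for m in clusters])
    centrotypes = np.array(
        [m[int(np.argmax(sim[np.ix_(m, m)].sum(axis=1)))] for m in clusters]
    )
    sizes = np.array([len(m) for m in clusters])
    stable = (sizes >= min_size) & (sizes <= max_size)
    # order clusters by descending Iq for stable reporting
    order = np.argsort(-iq, kind="stable")
    return IcassoResult(
        runs=runs,
        similarity=sim,
        clusters=[clusters[i] for i in order],
        iq=iq[order],
        centrotypes=centrotypes[order],
        cluster_sizes=sizes[order],
        stable=stable[order],
        sources=sources,
        run_of=run_of,
        K=K,
        n_runs=n_runs,
        size_bounds=(min_size, max_size),
        seed=seed,
        convergence=convergence,
    )


def select_stable_components(
    result: IcassoResult,
    X_centered: np.ndarray,
    iq_threshold: float = 0.8,
) -> ICADecomposition:
    """Canonical decomposition from the centrotype of each cluster.

    Centrotype sources are re-standardized and sign-fixed; loading
    coefficients are re-estimated against them by least squares on the
    centred data. Clusters that fail the size band or the Iq threshold are
    flagged (recorded on the decomposition), never silently dropped.
    """
    S = result.sources[result.centrotypes].copy()
    flagged = []
    for c in range(len(result.clusters)):
        reasons = []
        if not result.stable[c]:
            lo, hi = result.size_bounds
            reasons.append(f"cluster size {result.cluster_sizes[c]} outside [{lo}, {hi}]")
        if result.iq[c] < iq_threshold:
            reasons.append(f"Iq {result.iq[c]:.3f} < {iq_threshold}")
        if reasons:
            flagged.append({"component": c, "reason": "; ".join(reasons)})
    if len(flagged) == len(result.clusters):
        raise StabilityError("no stable components: " + "; ".join(f["reason"] for f in flagged))

    # standardize + sign-fix, then least-squares loadings A = Xc S+ so that
    # X_centered ~= A S
    for k in range(S.shape[0]):
        sd = S[k].std()
        if sd == 0:
            raise NumericError(f"centrotype {k} has zero variance")
        S[k] = S[k] / sd
        j = int(np.argmax(np.abs(S[k])))
        if S[k, j] < 0:
            S[k] = -S[k]
    G = S @ S.T
    A = np.linalg.solve(G, S @ X_centered.T).T
    return ICADecomposition(
        A=A,
        S=S,
        convergence_info={
            "icasso_runs": result.n_runs,
            "iq": result.iq.tolist(),
            "cluster_sizes": result.cluster_sizes.tolist(),
        },
        seed=result.seed,
        flagged=flagged,
    )


def plot_similarity(result: IcassoResult, path=None):
    """Heat map of the run-component similarity matrix, ordered by cluster,
    with cluster boundaries drawn. Returns the figure; saves a PNG if a
    path is given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.concatenate(result.clusters)
    sim = result.similarity[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(sim, vmin=0, vmax=1, cmap="viridis", interpolation="nearest")
    edge = 0
    for members in result.clusters[:-1]:
        edge += len(members)
        ax.axhline(edge - 0.5, color="w", lw=0.6)
        ax.axvline(edge - 0.5, color="w", lw=0.6)
    ax.set_xlabel("run components (cluster order)")
    ax.set_ylabel("run components (cluster order)")
    ax.set_title(f"ICASSO similarity, {result.n_runs} runs x K={result.K}")
    fig.colorbar(im, ax=ax, label="|corr|")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
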