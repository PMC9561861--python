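"""Signal-subspace extraction and spatial ICA with multi-restart run selection.

The union FC matrix X (patients x voxels) is modelled as X = A S with a
full-rank mixing matrix A and spatially independent sources S. PCA first
reduces X to a q-dimensional whitened subspace, with q chosen at the knee
of the cumulative explained-variance curve. Infomax ICA is then run many
times from random initializations; the run most consistent with the others
under the pairwise Amari inter-symbol-interference distance (cross-ISI) is
kept. Selected sources are z-scored over brain voxels, sign-oriented so the
network side is positive, and thresholded at |Z| > 1 into network maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import skew

from .connectome import FCMatrix
from .volumes import Mask, Volume, binarize, embed

__all__ = [
    "PCAResult",
    "ICARun",
    "Decomposition",
    "NetworkMap",
    "pca_reduce",
    "knee_point",
    "infomax_ica",
    "amari_isi",
    "cross_isi_select",
    "zscore_and_orient",
    "threshold_map",
    "decompose",
]


@dataclass
class PCAResult:
    components: np.ndarray  # patients x q left-singular basis
    whitened: np.ndarray  # q x V, unit-variance rows
    back_projection: np.ndarray  # patients x q with X ~ back_projection @ whitened
    singular_values: np.ndarray
    cumulative_explained_variance: np.ndarray
    q: int


@dataclass
class ICARun:
    demixing: np.ndarray  # W, q x q
    mixing: np.ndarray  # W^{-1}
    sources: np.ndarray  # q x V
    seed: int
    converged: bool
    n_iter: int


@dataclass
class NetworkMap:
    """A thresholded component (or reference) map: continuous z plus binary parts."""

    zmap: Volume
    threshold: float
    positive_mask: Mask
    negative_mask: Mask
    label: str = ""


@dataclass
class Decomposition:
    pca: PCAResult
    runs: list[ICARun]
    selected_run: int
    cross_isi: np.ndarray
    sources_z: np.ndarray  # q x V z-scored, sign-oriented
    ic_zmaps: list[Volume]
    patient_mixing: np.ndarray  # patients x q
    brain: Mask = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_components(self) -> int:
        return self.sources_z.shape[0]


def knee_point(cumvar: np.ndarray) -> int:
    """Order at the knee of the cumulative explained-variance curve.

    The curve is prepended with the origin (zero components explain zero
    variance) and the chord is drawn from the origin to the final point;
    the returned order (1-based) maximizes the distance above the chord,
    ties resolved to the smallest order.
    """
    y = np.asarray(cumvar, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(np.diff(y) < -1e-12) or y.min() < -1e-12 or y.max() > 1 + 1e-9:
        raise ValueError("cumvar must be nondecreasing within [0, 1]")
    if np.all(y == y[0]):
        warnings.warn("flat cumulative-variance curve; returning order 1")
        return 1
    ext = np.concatenate([[0.0], y])
    x = np.arange(ext.size, dtype=float)
    chord = ext[-1] * x / x[-1]
    dist = ext - chord
    if np.allclose(dist, 0):
        warnings.warn("linear cumulative-variance curve; returning order 1")
        return 1
    return int(np.argmax(dist[1:]) + 1)


def pca_reduce(fc: FCMatrix | np.ndarray, q: int | None = None) -> PCAResult:
    """SVD of the (row-standardized) FC matrix; whitened q x V signal subspace.

    Rows are assumed already centred across voxels, so no further centring
    is applied. Explained variance comes from squared singular values; when
    ``q`` is not given it is chosen by :func:`knee_point`.
    """
    X = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)
    m, v = X.shape
    if m < 3:
        raise ValueError("need at least 3 patients")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    power = s**2
    cumvar = np.cumsum(power) / power.sum()
    rank = int((s > s[0] * 1e-10).sum())
    if q is None:
        q = min(knee_point(cumvar), rank)
    if q > m:
        raise ValueError(f"q={q} exceeds number of patients {m}")
    if q > rank:
        raise ValueError(f"requested order {q} exceeds achievable rank {rank}")
    whitened = Vt[:q] * np.sqrt(v)  # rows zero-mean (rows of X are), unit variance
    back = U[:, :q] * s[:q] / np.sqrt(v)
    return PCAResult(
        components=U[:, :q],
        whitened=whitened,
        back_projection=back,
        singular_values=s,
        cumulative_explained_variance=cumvar,
        q=int(q),
    )


def infomax_ica(
    whitened: np.ndarray,
    seed: int,
    lrate: float | None = None,
    max_iter: int = 1024,
    tol: float = 1e-6,
    batch_size: int | None = None,
    anneal: float = 0.9,
    anneal_deg: float = 60.0,
) -> ICARun:
    """Natural-gradient Infomax with logistic nonlinearity on whitened data.

    W is updated per randomized mini-batch by the Bell-Sejnowski/Amari rule
    dW = lrate * (I + (1 - 2*g(U)) U^T / batch) W  with  g(u) = 1/(1+e^-u),
    suited to super-Gaussian (sparse) spatial sources. The learning rate is
    multiplied by ``anneal`` whenever the aggregate per-pass update turns by
    more than ``anneal_deg`` degrees (oscillation near an optimum), and
    halved with a weight reset if an update blows up; convergence is a
    Frobenius weight change below ``tol`` between passes. Deterministic
    given ``seed``.
    """
    X = np.asarray(whitened, dtype=float)
    q, v = X.shape
    if q < 2:
        raise ValueError("need at least 2 components")
    if v <= q:
        raise ValueError("need more samples than components")
    if lrate is None:
        lrate = 0.01 / np.log(q * np.e)
    if batch_size is None:
        batch_size = min(v, 256)
    rng = np.random.default_rng(seed)
    W = np.linalg.qr(rng.standard_normal((q, q)))[0]
    I = np.eye(q)
    converged = False
    n_iter = 0
    prev_step: np.ndarray | None = None
    cos_limit = np.cos(np.deg2rad(anneal_deg))
    for it in range(max_iter):
        n_iter = it + 1
        W_old = W.copy()
        perm = rng.permutation(v)
        blowup = False
        for start in range(0, v, batch_size):
            idx = perm[start : start + batch_size]
            U = W @ X[:, idx]
            Y = expit(U)
            dW = lrate * (I + (1.0 - 2.0 * Y) @ U.T / idx.size) @ W
            W = W + dW
            if not np.all(np.isfinite(W)) or np.abs(W).max() > 1e8:
                blowup = True
                break
        if blowup:
            lrate *= 0.5
            W = np.linalg.qr(rng.standard_normal((q, q)))[0]
            prev_step = None
            continue
        step = W - W_old
        delta = np.linalg.norm(step)
        if delta < tol:
            converged = True
            break
        if prev_step is not None:
            denom = np.linalg.norm(prev_step) * delta
            if denom > 0 and float(np.sum(prev_step * step)) / denom < cos_limit:
                lrate *= anneal
        prev_step = step
    mixing = np.linalg.inv(W)
    return ICARun(
        demixing=W,
        mixing=mixing,
        sources=W @ X,
        seed=seed,
        converged=converged,
        n_iter=n_iter,
    )


def amari_isi(g: np.ndarray) -> float:
    """Amari inter-symbol interference of a gain matrix; 0 iff scaled permutation.

    ISI = (1 / (2 q (q-1))) * [ sum_i (sum_j |g_ij| / max_k |g_ik| - 1)
                               + sum_j (sum_i |g_ij| / max_k |g_kj| - 1) ],
    invariant to row/column permutation and nonzero scaling, bounded in [0, 1].
    """
    g = np.abs(np.asarray(g, dtype=float))
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError("matrix must be square")
    q = g.shape[0]
    row_max = g.max(axis=1)
    col_max = g.max(axis=0)
    if np.any(row_max == 0) or np.any(col_max == 0):
        raise ValueError("matrix has an all-zero row or column")
    rows = (g / row_max[:, None]).sum(axis=1) - 1.0
    cols = (g / col_max[None, :]).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * q * (q - 1)))


def cross_isi_select(runs: list[ICARun]) -> tuple[int, np.ndarray]:
    """Pick the restart most consistent with the others.

    Pairwise score(i, j) = amari_isi(W_i @ W_j^{-1}); the selected run
    minimizes the mean score against the other converged runs (ties to the
    smallest index). Non-converged runs appear in the matrix but are never
    candidates.
    """
    n = len(runs)
    ok = [i for i, r in enumerate(runs) if r.converged]
    if len(ok) < 2:
        raise ValueError("need at least 2 converged runs")
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = amari_isi(runs[i].demixing @ runs[j].mixing)
            scores[i, j] = scores[j, i] = s
    means = np.array([scores[i, ok].sum() / (len(ok) - 1) for i in ok])
    selected = ok[int(np.argmin(means))]
    return selected, scores


def zscore_and_orient(sources: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each source over voxels and orient so skewness is positive.

    Returns (z-scored sources, signs applied); a source and its negation
    yield identical output, resolving the ICA sign indeterminacy so the
    network side of each map is the positive tail.
    """
    S = np.asarray(sources, dtype=float)
    sd = S.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance source")
    Z = (S - S.mean(axis=1, keepdims=True)) / sd[:, None]
    signs = np.where(skew(Z, axis=1) < 0, -1.0, 1.0)
    return Z * signs[:, None], signs


def threshold_map(zmap: Volume, z: float, brain: Mask | None = None, label: str = "") -> NetworkMap:
    """Split a z-map into positive (z > thr) and negative (z < -thr) masks."""
    if z <= 0:
        raise ValueError("threshold must be positive")
    pos = binarize(zmap, z)
    neg = binarize(Volume(zmap.grid, -zmap.data), z)
    if brain is not None:
        pos = pos.intersect(brain)
        neg = neg.intersect(brain)
    return NetworkMap(zmap=zmap, threshold=z, positive_mask=pos, negative_mask=neg, label=label)


def decompose(
    fc: FCMatrix,
    n_runs: int = 30,
    seed: int = 0,
    order: int | None = None,
    **ica_kwargs,
) -> Decomposition:
    """PCA (knee-point order unless overridden) + ``n_runs`` Infomax restarts
    + cross-ISI selection + z-scored, sign-oriented component maps."""
    pca = pca_reduce(fc, q=order)
    runs = [infomax_ica(pca.whitened, seed=seed + i, **ica_kwargs) for i in range(n_runs)]
    selected, scores = cross_isi_select(runs)
    best = runs[selected]
    sources_z, signs = zscore_and_orient(best.sources)
    patient_mixing = (pca.back_projection @ best.mixing) * signs[None, :]
    ic_zmaps = [embed(sources_z[i], fc.brain) for i in range(pca.q)]
    return Decomposition(
        pca=pca,
        runs=runs,
        selected_run=selected,
        cross_isi=scores,
        sources_z=sources_z,
        ic_zmaps=ic_zmaps,
        patient_mixing=patient_mixing,
        brain=fc.brain,
    )
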