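"""ICA unmixing with reproducible restarts and stability analysis.

The default separator is Infomax (logistic score, natural-gradient
updates), the historical default of group-ICA pipelines for fMRI, whose
sparse super-Gaussian sources it suits.  After convergence the demixing
matrix is replaced by its polar (closest-orthogonal) factor: on whitened
input the true unmixing is orthogonal and Infomax's solution differs
from it only by a per-row scale (W = diag * O), which the polar factor
removes exactly.  This enforces the package-wide convention that source
estimates have unit power and are exactly uncorrelated.

Stability follows the ICASSO recipe: rerun ICA with derived seeds,
pool all component estimates, cluster them by absolute spatial
similarity (single linkage, i.e. minimum-spanning-tree agglomeration),
and score each cluster by average intra-cluster minus average
inter-cluster similarity.  The "best run" is the one whose components
sit closest to the cluster centrotypes.

Similarity is the absolute uncentered correlation (cosine); source rows
are zero-mean to numerical precision, and the uncentered form makes the
degenerate identical-runs case exact (quality 1.0) instead of
approximate.  Values within 1e-12 of 0 or 1 are snapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.optimize
import scipy.spatial.distance as ssd
from sklearn.decomposition import FastICA

__all__ = [
    "IcaRun",
    "StabilityReport",
    "run_ica",
    "icasso",
    "align_components",
    "ConvergenceError",
]

DEFAULT_N_RUNS = 20  # reruns with random initial conditions
_SNAP_TOL = 1e-12


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, n_iter: int):
        super().__init__(message)
        self.n_iter = n_iter


class WhitenessContractError(ValueError):
    """ICA input rows are not uncorrelated with unit variance."""


@dataclass(frozen=True)
class IcaRun:
    """One ICA solution: demixing matrix, sources, convergence metadata."""

    demix_w: np.ndarray
    sources: np.ndarray
    converged: bool
    n_iter: int
    seed: int


@dataclass(frozen=True)
class StabilityReport:
    """Per-component cluster quality in [0, 1], plus best-run bookkeeping."""

    cluster_quality: np.ndarray
    best_run_index: int
    run_count: int

    def __post_init__(self) -> None:
        if self.best_run_index >= self.run_count:
            raise ValueError("best_run_index out of range")


def joint_whiten(x: np.ndarray, rcond: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Symmetrically whiten the rows of x: returns (K @ x, K).

    K is the inverse symmetric square root of the (uncentered) row Gram
    ``x x'/(n-1)``.  Raises if the Gram is numerically rank-deficient —
    the requested order exceeds the information in the data.
    """
    c, n = x.shape
    gram = x @ x.T / (n - 1)
    evals, evecs = np.linalg.eigh(gram)
    if evals[0] < rcond * evals[-1]:
        raise ValueError(
            "row space is rank-deficient; reduce the model order "
            f"(Gram eigenvalue ratio {evals[0] / evals[-1]:.2e})"
        )
    k = evecs @ np.diag(evals**-0.5) @ evecs.T
    return k @ x, k


def _check_white(x: np.ndarray, tol: float) -> None:
    c, n = x.shape
    gram = x @ x.T / (n - 1)
    if not np.allclose(gram, np.eye(c), atol=tol):
        raise WhitenessContractError(
            f"input rows not white within {tol:g} "
            f"(max deviation {np.abs(gram - np.eye(c)).max():.2e})"
        )


def _polar_orthogonalize(w: np.ndarray) -> np.ndarray:
    """Closest orthogonal matrix: W (W W')^(-1/2)... applied from the left."""
    evals, evecs = np.linalg.eigh(w @ w.T)
    evals = np.maximum(evals, 1e-30)
    inv_sqrt = evecs @ np.diag(evals**-0.5) @ evecs.T
    return inv_sqrt @ w


def _infomax(
    x: np.ndarray, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, bool, int]:
    """Batch natural-gradient Infomax with logistic nonlinearity.

    Update: W <- W + lr * (I - tanh(Y/2) Y'/n) W, with the learning rate
    annealed whenever the step grows.  Weight change is measured after
    re-orthogonalization so the stopping rule tracks movement on the
    manifold the final solution lives on.
    """
    c, n = x.shape
    q, _ = np.linalg.qr(rng.standard_normal((c, c)))
    w = q
    lr = 0.1 / max(1.0, np.log(c) if c > 1 else 1.0)
    eye = np.eye(c)
    last_delta = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        y = w @ x
        grad = eye - np.tanh(y / 2.0) @ y.T / n
        w_new = _polar_orthogonalize(w + lr * grad @ w)
        delta = np.abs(w_new - w).max()
        if delta > last_delta * 1.5:
            lr *= 0.8
        last_delta = delta
        w = w_new
        if delta < tol:
            return w, True, n_iter
    return w, False, n_iter


def run_ica(
    whitened: np.ndarray,
    seed: int = 0,
    max_iter: int = 2500,
    tol: float = 1e-7,
    algorithm: str = "infomax",
    whiten_tol: float = 1e-6,
) -> IcaRun:
    """Unmix a whitened c x m matrix into c independent source rows.

    ``algorithm`` is one of ``"infomax"`` (default), ``"fastica"``
    (deflationary, logcosh, via scikit-learn — also handles sub-Gaussian
    sources) or ``"identity"`` (no separation; W = I).  Non-convergence
    sets the ``converged`` flag rather than raising.
    """
    x = np.asarray(whitened, dtype=float)
    if x.ndim != 2 or x.shape[0] > x.shape[1]:
        raise ValueError("expected a c x m matrix with c <= m")
    if algorithm == "identity":
        c = x.shape[0]
        return IcaRun(demix_w=np.eye(c), sources=x.copy(), converged=True, n_iter=0, seed=seed)
    _check_white(x, whiten_tol)
    if algorithm == "infomax":
        rng = np.random.default_rng(seed)
        w, converged, n_iter = _infomax(x, rng, max_iter, tol)
    elif algorithm == "fastica":
        model = FastICA(
            n_components=x.shape[0],
            algorithm="deflation",
            fun="logcosh",
            whiten=False,
            max_iter=max_iter,
            tol=max(tol, 1e-10),
            random_state=np.random.RandomState(seed),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x.T)
        w = _polar_orthogonalize(np.asarray(model.components_))
        converged, n_iter = model.n_iter_ < max_iter, int(np.max(model.n_iter_))
    else:
        raise ValueError(f"unknown ICA algorithm {algorithm!r}")
    if not converged:
        warnings.warn(
            f"ICA ({algorithm}) did not converge in {n_iter} iterations", RuntimeWarning
        )
    # deterministic orientation: strongest entry of each source positive
    sources = w @ x
    idx = np.abs(sources).argmax(axis=1)
    signs = np.sign(sources[np.arange(sources.shape[0]), idx])
    signs[signs == 0] = 1.0
    w = w * signs[:, None]
    return IcaRun(demix_w=w, sources=sources * signs[:, None], converged=converged,
                  n_iter=n_iter, seed=seed)


def _abs_cosine_similarity(rows: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(rows, axis=1)
    norms[norms == 0] = 1.0
    unit = rows / norms[:, None]
    sim = np.abs(unit @ unit.T)
    sim[sim > 1.0] = 1.0
    sim[sim > 1.0 - _SNAP_TOL] = 1.0
    sim[sim < _SNAP_TOL] = 0.0
    return sim


def icasso(
    whitened: np.ndarray,
    n_runs: int = DEFAULT_N_RUNS,
    base_seed: int = 0,
    algorithm: str = "infomax",
    max_iter: int = 2500,
    tol: float = 1e-7,
    identical_seeds: bool = False,
) -> tuple[IcaRun, StabilityReport]:
    """Rerun ICA ``n_runs`` times and assess component reproducibility.

    Run ``i`` uses seed ``base_seed + i``.  Returns the best run (the one
    whose components are most similar to the cluster centrotypes, ties
    broken by lowest run index) and the stability report with one quality
    index per component of that run.

    ``identical_seeds=True`` seeds every run with ``base_seed`` — the
    degenerate configuration in which all runs coincide and every cluster
    quality index is exactly 1; useful for validating the analysis itself.
    """
    if n_runs < 2:
        raise ValueError("icasso needs at least 2 runs")
    runs = [
        run_ica(
            whitened,
            seed=base_seed if identical_seeds else base_seed + i,
            max_iter=max_iter,
            tol=tol,
            algorithm=algorithm,
        )
        for i in range(n_runs)
    ]
    c = whitened.shape[0]
    pooled = np.vstack([r.sources for r in runs])  # (n_runs*c) x m
    sim = _abs_cosine_similarity(pooled)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    link = sch.linkage(ssd.squareform(dist, checks=False), method="single")
    labels = sch.fcluster(link, t=c, criterion="maxclust")

    n_total = pooled.shape[0]
    quality_by_cluster: dict[int, float] = {}
    centrotype: dict[int, int] = {}
    for cl in np.unique(labels):
        members = np.flatnonzero(labels == cl)
        others = np.flatnonzero(labels != cl)
        block = sim[np.ix_(members, members)]
        if members.size > 1:
            intra = (block.sum() - members.size) / (members.size * (members.size - 1))
        else:
            intra = 1.0
        inter = sim[np.ix_(members, others)].mean() if others.size else 0.0
        quality_by_cluster[int(cl)] = float(np.clip(intra - inter, 0.0, 1.0))
        centrotype[int(cl)] = int(members[np.argmax(block.sum(axis=1))])

    cluster_ids = sorted(quality_by_cluster)
    cent_idx = np.array([centrotype[cl] for cl in cluster_ids])
    # score each run by how close its components come to every centrotype
    scores = np.empty(n_runs)
    for i in range(n_runs):
        rows = slice(i * c, (i + 1) * c)
        scores[i] = sim[rows, :][:, cent_idx].max(axis=0).sum()
    best = int(np.argmax(scores))  # argmax takes the lowest index on ties
    best_labels = labels[best * c : (best + 1) * c]
    quality = np.array([quality_by_cluster[int(cl)] for cl in best_labels])
    return runs[best], StabilityReport(
        cluster_quality=quality, best_run_index=best, run_count=n_runs
    )


def align_components(
    est: np.ndarray, ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimally match estimated to reference maps (max total |Pearson r|).

    Returns ``(perm, signs, corrs)`` such that ``signs[i] * est[perm[i]]``
    is the positively-correlated match of ``ref[i]`` and ``corrs[i]`` the
    corresponding |r|.  Zero-variance rows are excluded from matching
    (their slots get perm -1, sign +1, corr NaN) and reported.
    """
    est = np.atleast_2d(np.asarray(est, dtype=float))
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    if est.shape != ref.shape:
        raise ValueError("est and ref must have identical shapes")
    k = est.shape[0]
    est_sd = est.std(axis=1)
    ref_sd = ref.std(axis=1)
    ok_e = np.flatnonzero(est_sd > 0)
    ok_r = np.flatnonzero(ref_sd > 0)
    if ok_e.size < k or ok_r.size < k:
        warnings.warn("zero-variance rows excluded from component matching", RuntimeWarning)
    ec = est[ok_e] - est[ok_e].mean(axis=1, keepdims=True)
    rc = ref[ok_r] - ref[ok_r].mean(axis=1, keepdims=True)
    ec /= np.linalg.norm(ec, axis=1, keepdims=True)
    rc /= np.linalg.norm(rc, axis=1, keepdims=True)
    corr = rc @ ec.T  # |ok_r| x |ok_e|
    n_match = min(ok_r.size, ok_e.size)
    row_ind, col_ind = scipy.optimize.linear_sum_assignment(-np.abs(corr))
    perm = np.full(k, -1, dtype=int)
    signs = np.ones(k)
    corrs = np.full(k, np.nan)
    for r_i, c_i in zip(row_ind[:n_match], col_ind[:n_match]):
        slot = ok_r[r_i]
        perm[slot] = ok_e[c_i]
        signs[slot] = 1.0 if corr[r_i, c_i] >= 0 else -1.0
        corrs[slot] = abs(corr[r_i, c_i])
    return perm, signs, corrs
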