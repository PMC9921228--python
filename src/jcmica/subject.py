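"""Single-subject connectivity-matrix decomposition.

The functional connectivity matrix of a subject is the voxel-pair
temporal correlation ``C = X'X/(T-1)`` of the temporally normalized
time series ``X`` (T x V).  cmICA never forms this V x V matrix: a
truncated SVD ``X = V_t S U'`` carries the same spatial eigenstructure
(``C = U S^2 U'/(T-1)``), so ICA can run directly on the top spatial
singular vectors.  Sources and connectivity maps then follow as

    S = W u',        R = u S^2 W^{-1} / (T - 1)

and ``R S`` reproduces the rank-c truncation of ``C`` exactly.  The
structural branch applies the same factorization to the (optionally
log1p-transformed) gray x white fiber-count matrix, with
``R = v S W^{-1}`` living on white-matter voxels.

Conventions: sample statistics use the n-1 denominator; every spatial
basis column is oriented so its maximum-magnitude entry is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .ica import ConvergenceError, run_ica
from .volume_io import StructuralConnectivity

__all__ = [
    "ReducedSubject",
    "SubjectDecomposition",
    "temporal_normalize",
    "explicit_fc_matrix",
    "reduce_subject_fc",
    "reduce_subject_sc",
    "single_subject_cmica",
    "save_reduced",
    "load_reduced",
]


class NormalizationContractError(ValueError):
    """Input expected to be temporally normalized was not."""


def fix_signs(basis_u: np.ndarray, *cofactors: np.ndarray) -> tuple[np.ndarray, ...]:
    """Orient each spatial basis column so its max-|entry| is positive.

    Any co-factor matrices (with matching columns) are flipped in step so
    products are unchanged.  Determinism across platforms is the point.
    """
    if basis_u.size == 0:
        return (basis_u, *cofactors)
    idx = np.abs(basis_u).argmax(axis=0)
    signs = np.sign(basis_u[idx, np.arange(basis_u.shape[1])])
    signs[signs == 0] = 1.0
    return (basis_u * signs, *(c * signs for c in cofactors))


@dataclass(frozen=True)
class ReducedSubject:
    """Truncated SVD factors of one subject, one modality.

    ``basis_u`` (V_A x r) spans gray-matter space; ``basis_v`` spans the
    co-dimension (time for FC, white-matter voxels for SC); ``n_samples``
    is T for FC and V_B for SC.
    """

    modality: str  # "FC" or "SC"
    basis_u: np.ndarray
    sing_vals: np.ndarray
    basis_v: np.ndarray
    n_samples: int
    subject_id: str = ""
    transform: str = "none"

    def __post_init__(self) -> None:
        if self.modality not in {"FC", "SC"}:
            raise ValueError(f"unknown modality {self.modality!r}")
        r = self.sing_vals.size
        if self.basis_u.shape[1] != r or self.basis_v.shape[1] != r:
            raise ValueError("factor shapes inconsistent with number of singular values")
        if np.any(np.diff(self.sing_vals) > 1e-12):
            raise ValueError("singular values must be non-increasing")

    @property
    def r(self) -> int:
        return self.sing_vals.size

    @property
    def n_voxels_a(self) -> int:
        return self.basis_u.shape[0]


@dataclass(frozen=True)
class SubjectDecomposition:
    """Source maps S (c x V_A), connectivity maps R (V_B x c), demixing W."""

    S: np.ndarray
    R: np.ndarray
    demix_w: np.ndarray
    modality: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.S.shape[0] < 1:
            raise ValueError("need at least one component")
        for a in (self.S, self.R, self.demix_w):
            if not np.all(np.isfinite(a)):
                raise ValueError("decomposition contains non-finite values")


def temporal_normalize(
    data: np.ndarray, return_zero_variance: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Standardize every voxel time course to mean 0, sample sd 1.

    Zero-variance voxels are zeroed in place of standardization (dropping
    them would break mask alignment across subjects); their indices are
    reported through a warning and, optionally, the second return value.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("data must be T x V with T >= 2")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(sd <= 1e-13 * max(1.0, np.abs(mean).max()))
    sd_safe = sd.copy()
    sd_safe[zero_var] = 1.0
    out = (data - mean) / sd_safe
    out[:, zero_var] = 0.0
    if zero_var.size:
        warnings.warn(
            f"{zero_var.size} zero-variance voxel(s) zeroed during normalization",
            RuntimeWarning,
            stacklevel=2,
        )
    if return_zero_variance:
        return out, zero_var
    return out


def explicit_fc_matrix(x_norm: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Voxel-pair correlation matrix ``X'X/(T-1)`` — test oracle only.

    Refuses input that is not temporally normalized (columns must have
    sample sd 1, or be all-zero for flagged degenerate voxels).
    """
    x_norm = np.asarray(x_norm, dtype=float)
    t = x_norm.shape[0]
    sd = x_norm.std(axis=0, ddof=1)
    ok = np.isclose(sd, 1.0, atol=1e-6) | np.isclose(sd, 0.0, atol=tol)
    if not ok.all():
        raise NormalizationContractError("input to explicit_fc_matrix is not normalized")
    return (x_norm.T @ x_norm) / (t - 1)


def reduce_subject_fc(x_norm: np.ndarray, r: int, subject_id: str = "") -> ReducedSubject:
    """Truncated SVD of normalized time series; spatial basis over voxels."""
    x_norm = np.asarray(x_norm, dtype=float)
    t, v = x_norm.shape
    if not 1 <= r <= min(t - 1, v):
        raise ValueError(f"r={r} out of range [1, {min(t - 1, v)}]")
    vt_full, s, uh = np.linalg.svd(x_norm, full_matrices=False)
    basis_u = uh.T[:, :r]
    basis_v = vt_full[:, :r]
    basis_u, basis_v = fix_signs(basis_u, basis_v)
    return ReducedSubject(
        modality="FC",
        basis_u=basis_u,
        sing_vals=s[:r],
        basis_v=basis_v,
        n_samples=t,
        subject_id=subject_id,
    )


def reduce_subject_sc(
    c_sc: StructuralConnectivity, r: int, transform: str = "none"
) -> ReducedSubject:
    """Truncated SVD of the gray x white fiber-count matrix.

    ``transform="log1p"`` compresses the heavy-tailed count distribution
    before factorization; the default applies no transform.
    """
    if transform not in {"none", "log1p"}:
        raise ValueError(f"unknown transform {transform!r}")
    dense = c_sc.to_dense()
    v_a, v_b = dense.shape
    if not 1 <= r <= min(v_a, v_b):
        raise ValueError(f"r={r} out of range [1, {min(v_a, v_b)}]")
    if transform == "log1p":
        dense = np.log1p(dense)
    if not dense.any():
        warnings.warn("all-zero connectivity matrix; degenerate factors", RuntimeWarning)
        return ReducedSubject(
            modality="SC",
            basis_u=np.zeros((v_a, r)),
            sing_vals=np.zeros(r),
            basis_v=np.zeros((v_b, r)),
            n_samples=v_b,
            subject_id=c_sc.subject_id,
            transform=transform,
        )
    u, s, vh = np.linalg.svd(dense, full_matrices=False)
    basis_u = u[:, :r]
    basis_v = vh.T[:, :r]
    basis_u, basis_v = fix_signs(basis_u, basis_v)
    return ReducedSubject(
        modality="SC",
        basis_u=basis_u,
        sing_vals=s[:r],
        basis_v=basis_v,
        n_samples=v_b,
        subject_id=c_sc.subject_id,
        transform=transform,
    )


def whitened_spatial(red: ReducedSubject, c: int) -> np.ndarray:
    """Top-c spatial basis rows scaled to unit (uncentered) row variance.

    Rows of ``basis_u'`` have unit norm, so multiplying by sqrt(V_A - 1)
    gives ``X X'/(V_A - 1) = I`` exactly — the whiteness contract the ICA
    engine checks.
    """
    v_a = red.n_voxels_a
    return np.sqrt(v_a - 1.0) * red.basis_u[:, :c].T


def single_subject_cmica(
    red: ReducedSubject,
    c: int,
    ica: str = "infomax",
    seed: int = 0,
    max_iter: int = 2500,
    tol: float = 1e-7,
    strict_convergence: bool = True,
) -> SubjectDecomposition:
    """Decompose one subject's connectivity structure into c components.

    ``ica="identity"`` bypasses source separation (W = I), exposing the
    raw PCA factors; useful for the algebraic-identity tests.

    Raises :class:`jcmica.ica.ConvergenceError` (carrying the iteration
    count) if the separator fails to converge; pass
    ``strict_convergence=False`` to accept the flagged solution instead
    (the R·S reconstruction identity holds either way).
    """
    if not 1 <= c <= red.r:
        raise ValueError(f"c={c} out of range [1, {red.r}]")
    u = red.basis_u[:, :c]
    s = red.sing_vals[:c]
    if ica == "identity":
        w_eff = np.eye(c)
        sources = u.T
    else:
        x_white = whitened_spatial(red, c)
        run = run_ica(x_white, seed=seed, max_iter=max_iter, tol=tol, algorithm=ica)
        if strict_convergence and not run.converged:
            raise ConvergenceError(
                f"ICA did not converge within {run.n_iter} iterations", run.n_iter
            )
        scale = np.sqrt(red.n_voxels_a - 1.0)
        # rescale sources to unit sample variance over voxels; W absorbs it
        raw = run.sources
        sd = raw.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        w_eff = (run.demix_w * scale) / sd[:, None]
        sources = w_eff @ u.T
    w_inv = np.linalg.inv(w_eff)
    if red.modality == "FC":
        r_maps = u @ np.diag(s**2) @ w_inv / (red.n_samples - 1)
    else:
        r_maps = red.basis_v[:, :c] @ np.diag(s) @ w_inv
    return SubjectDecomposition(
        S=sources, R=r_maps, demix_w=w_eff, modality=red.modality, subject_id=red.subject_id
    )


def save_reduced(red: ReducedSubject, path: str | Path) -> None:
    """Serialize subject-level factors to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("basis_u", data=red.basis_u)
        f.create_dataset("sing_vals", data=red.sing_vals)
        f.create_dataset("basis_v", data=red.basis_v)
        f.attrs["modality"] = red.modality
        f.attrs["subject_id"] = red.subject_id
        f.attrs["n_samples"] = red.n_samples
        f.attrs["transform"] = red.transform


def load_reduced(path: str | Path) -> ReducedSubject:
    with h5py.File(path, "r") as f:
        return ReducedSubject(
            modality=str(f.attrs["modality"]),
            basis_u=np.asarray(f["basis_u"]),
            sing_vals=np.asarray(f["sing_vals"]),
            basis_v=np.asarray(f["basis_v"]),
            n_samples=int(f.attrs["n_samples"]),
            subject_id=str(f.attrs["subject_id"]),
            transform=str(f.attrs["transform"]),
        )
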