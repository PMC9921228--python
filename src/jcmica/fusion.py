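"""Joint decomposition of functional and structural connectivity.

Two-stage reduction, balanced concatenation, joint spatial ICA, and
group-ICA back-reconstruction:

1. Per subject and modality, a truncated SVD yields an orthonormal
   gray-matter spatial basis (``subject.reduce_subject_*``).
2. Per modality, the subject bases are stacked along the sample
   dimension and reduced again (``group_reduce``), giving a group
   spatial basis U (V_gm x m), singular values S, and per-subject
   partitions V_k of the co-basis.
3. The two modality bases are scaled to exactly unit row power and
   stacked (``concatenate_modalities``) — the balancing step that stops
   the higher-variance modality from monopolizing the decomposition.
4. ICASSO-stabilized spatial ICA on the (m_FC + m_SC) x V_gm matrix
   extracts the shared gray-matter sources.
5. Subject- and modality-specific maps come back through the stored
   projection chain (``back_reconstruct``):

       U_k' = N * S^-1 V_k' u_k'                (subject spatial estimate)
       S_k  = W[:, block] * scale * U_k'        (subject source maps)
       R_k  = u_k s_k^p V_k S A[block, :] / (scale * norm)

   with p = 2, norm = T-1 for the functional branch and p = 1, norm = 1
   for the structural branch; A = W^-1.  The subject-mean of S_k equals
   the aggregate sources' modality contribution exactly, by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .ica import StabilityReport, icasso, joint_whiten
from .subject import (
    ReducedSubject,
    fix_signs,
    reduce_subject_fc,
    reduce_subject_sc,
    temporal_normalize,
)
from .synthetic import TimeSeriesSubject
from .volume_io import StructuralConnectivity

__all__ = [
    "GroupReduction",
    "ConcatOrder",
    "JointICAModel",
    "SubjectComponentMaps",
    "group_reduce",
    "concatenate_modalities",
    "fit_joint_cmica",
    "back_reconstruct",
    "group_average_maps",
    "save_model",
    "load_model",
]

DEFAULT_SUBJECT_R = 40
DEFAULT_M_PER_MODALITY = 30  # symmetric orders; joint order 60


@dataclass(frozen=True)
class GroupReduction:
    """Second-stage (group-level) PCA for one modality."""

    modality: str
    group_basis: np.ndarray  # V_A x m, orthonormal columns
    group_sing: np.ndarray  # m
    subject_partitions: tuple[np.ndarray, ...]  # each r x m
    subject_r: int

    @property
    def m(self) -> int:
        return self.group_sing.size

    @property
    def n_subjects(self) -> int:
        return len(self.subject_partitions)


@dataclass(frozen=True)
class ConcatOrder:
    """Bookkeeping for the stacked modality blocks."""

    modalities: tuple[str, ...]
    block_sizes: tuple[int, ...]
    scale: float  # balancing scale applied to every block

    def block(self, modality: str) -> slice:
        start = 0
        for mod, size in zip(self.modalities, self.block_sizes):
            if mod == modality:
                return slice(start, start + size)
            start += size
        raise KeyError(f"modality {modality!r} not in concatenation")


@dataclass(frozen=True)
class JointICAModel:
    """Fitted joint decomposition: group factors, demixing, sources."""

    reductions: dict[str, GroupReduction]
    demix_w: np.ndarray  # c x c, acts on the balanced concatenated matrix
    aggregate_S: np.ndarray  # c x V_gm, unit-variance rows
    stability: StabilityReport | None
    concat_order: ConcatOrder
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c != sum(self.concat_order.block_sizes):
            raise ValueError("joint order must equal the sum of modality orders")
        if not np.all(np.isfinite(self.aggregate_S)):
            raise ValueError("aggregate sources contain non-finite values")

    @property
    def c(self) -> int:
        return self.demix_w.shape[0]

    @property
    def mixing(self) -> np.ndarray:
        """Mixing matrix A = W^-1; rows are concatenated PCA directions."""
        return np.linalg.inv(self.demix_w)

    @property
    def n_subjects(self) -> int:
        return next(iter(self.reductions.values())).n_subjects

    def modality_contribution(self, modality: str) -> np.ndarray:
        """The aggregate-source term contributed by one modality block."""
        bl = self.concat_order.block(modality)
        red = self.reductions[modality]
        return self.demix_w[:, bl] @ (self.concat_order.scale * red.group_basis.T)


@dataclass(frozen=True)
class SubjectComponentMaps:
    """Back-reconstructed subject maps for one modality."""

    subject_id: str
    subject_index: int
    modality: str
    S_k: np.ndarray  # c x V_gm
    R_k: np.ndarray  # V_B x c

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.S_k)) and np.all(np.isfinite(self.R_k))):
            raise ValueError("subject maps contain non-finite values")


def group_reduce(subjects: list[ReducedSubject], m: int) -> GroupReduction:
    """Stack subject spatial bases and reduce to a group basis of order m."""
    if not subjects:
        raise ValueError("no subjects")
    modality = subjects[0].modality
    v_a = subjects[0].n_voxels_a
    r = subjects[0].r
    for s in subjects:
        if s.modality != modality:
            raise ValueError("mixed modalities in group reduction")
        if s.n_voxels_a != v_a:
            raise ValueError("subjects disagree on gray-matter voxel count")
        if s.r != r:
            raise ValueError("subjects must share the same subject-level order")
    n = len(subjects)
    if not 1 <= m <= min(n * r, v_a):
        raise ValueError(f"group order m={m} out of range [1, {min(n * r, v_a)}]")
    stacked = np.vstack([s.basis_u.T for s in subjects])  # (n*r) x V_A
    co, sing, uh = np.linalg.svd(stacked, full_matrices=False)
    basis = uh.T[:, :m]
    co = co[:, :m]
    basis, co = fix_signs(basis, co)
    partitions = tuple(co[i * r : (i + 1) * r, :].copy() for i in range(n))
    return GroupReduction(
        modality=modality,
        group_basis=basis,
        group_sing=sing[:m],
        subject_partitions=partitions,
        subject_r=r,
    )


def concatenate_modalities(
    fc: GroupReduction, sc: GroupReduction
) -> tuple[np.ndarray, ConcatOrder]:
    """Stack the balanced modality bases into the joint ICA input.

    Each block is ``scale * U_mod'`` with ``scale = sqrt(V_gm - 1)``:
    rows of an orthonormal basis have unit norm, so every row of every
    block gets exactly unit (uncentered) variance and the two modalities
    enter the joint decomposition with equal weight.
    """
    if fc.group_basis.shape[0] != sc.group_basis.shape[0]:
        raise ValueError("modalities disagree on gray-matter voxel count")
    for red in (fc, sc):
        if not np.all(red.group_sing > 1e-12):
            raise ValueError(
                f"{red.modality} group reduction is degenerate (zero singular values); "
                "cannot whiten"
            )
    v_gm = fc.group_basis.shape[0]
    scale = float(np.sqrt(v_gm - 1.0))
    joint = np.vstack([scale * fc.group_basis.T, scale * sc.group_basis.T])
    order = ConcatOrder(
        modalities=(fc.modality, sc.modality), block_sizes=(fc.m, sc.m), scale=scale
    )
    return joint, order


def fit_joint_cmica(
    fmri: list[TimeSeriesSubject],
    sc: list[StructuralConnectivity],
    subject_r: int = DEFAULT_SUBJECT_R,
    m_per_modality: int = DEFAULT_M_PER_MODALITY,
    icasso_runs: int = 20,
    seed: int = 0,
    sc_transform: str = "none",
    ica_algorithm: str = "infomax",
    max_iter: int = 2500,
    tol: float = 1e-7,
    return_reduced: bool = False,
):
    """Fit the full joint pipeline on a paired cohort.

    Normalize -> subject SVD per modality -> group reduction per modality
    -> balanced concatenation -> ICASSO-stabilized ICA.  The joint model
    order is ``2 * m_per_modality`` (symmetric convention).  Every source
    of randomness derives from ``seed``.

    With ``return_reduced=True`` also returns the per-subject reduced
    factors, keyed by modality, for back-reconstruction.
    """
    if len(fmri) != len(sc):
        raise ValueError("functional and structural subject lists must be paired")
    if len(fmri) < 2:
        raise ValueError("the group model needs at least 2 subjects")
    reduced_fc = [
        reduce_subject_fc(temporal_normalize(s.data), subject_r, subject_id=s.subject_id)
        for s in fmri
    ]
    reduced_sc = [reduce_subject_sc(c, subject_r, transform=sc_transform) for c in sc]
    group_fc = group_reduce(reduced_fc, m_per_modality)
    group_sc = group_reduce(reduced_sc, m_per_modality)
    joint, order = concatenate_modalities(group_fc, group_sc)
    # the two balanced blocks share variance along the shared sources, so
    # the stacked rows are correlated; ICA wants a jointly white input.
    # The whitening matrix folds into the stored demixing matrix below.
    joint_white, k_white = joint_whiten(joint)
    best, stability = icasso(
        joint_white,
        n_runs=icasso_runs,
        base_seed=seed,
        algorithm=ica_algorithm,
        max_iter=max_iter,
        tol=tol,
    )
    # unit-variance source convention; the demixing matrix absorbs the scale
    sd = best.sources.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    demix = (best.demix_w @ k_white) / sd[:, None]
    aggregate = best.sources / sd[:, None]
    model = JointICAModel(
        reductions={"FC": group_fc, "SC": group_sc},
        demix_w=demix,
        aggregate_S=aggregate,
        stability=stability,
        concat_order=order,
        seed=seed,
    )
    if return_reduced:
        return model, {"FC": reduced_fc, "SC": reduced_sc}
    return model


def back_reconstruct(
    model: JointICAModel,
    reduced: ReducedSubject,
    modality: str,
    subject_index: int,
) -> SubjectComponentMaps:
    """Recover one subject's source and connectivity maps for a modality."""
    if modality not in model.reductions:
        raise ValueError(f"modality {modality!r} not in model")
    red = model.reductions[modality]
    if not 0 <= subject_index < red.n_subjects:
        raise ValueError(f"subject index {subject_index} was not part of the fit")
    if reduced.modality != modality:
        raise ValueError("reduced subject modality does not match request")
    n = red.n_subjects
    bl = model.concat_order.block(modality)
    scale = model.concat_order.scale
    v_k = red.subject_partitions[subject_index]  # r x m
    u_k = reduced.basis_u[:, : red.subject_r]
    s_k = reduced.sing_vals[: red.subject_r]
    sig_inv = 1.0 / red.group_sing
    # GICA subject spatial estimate; subject-mean equals the group basis exactly
    u_subj = (n * sig_inv)[:, None] * (v_k.T @ u_k.T)  # m x V_gm
    s_maps = model.demix_w[:, bl] @ (scale * u_subj)
    a_block = model.mixing[bl, :]  # m x c
    if modality == "FC":
        core = (u_k * (s_k**2)[None, :]) / (reduced.n_samples - 1)
    else:
        core = reduced.basis_v[:, : red.subject_r] * s_k[None, :]
    r_maps = core @ v_k @ np.diag(red.group_sing) @ a_block / scale
    return SubjectComponentMaps(
        subject_id=reduced.subject_id,
        subject_index=subject_index,
        modality=modality,
        S_k=s_maps,
        R_k=r_maps,
    )


def group_average_maps(
    model: JointICAModel, maps: list[SubjectComponentMaps], modality: str
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise mean of subject maps (S_mean c x V_gm, R_mean V_B x c)."""
    selected = [m for m in maps if m.modality == modality]
    indices = sorted(m.subject_index for m in selected)
    expected = list(range(model.reductions[modality].n_subjects))
    if indices != expected:
        raise ValueError(
            f"need maps for all {len(expected)} fitted subjects, got indices {indices}"
        )
    s_mean = np.mean([m.S_k for m in selected], axis=0)
    r_mean = np.mean([m.R_k for m in selected], axis=0)
    return s_mean, r_mean


def save_model(model: JointICAModel, path: str | Path) -> None:
    """Serialize the fitted model to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = model.seed
        f.attrs["scale"] = model.concat_order.scale
        f.attrs["modalities"] = list(model.concat_order.modalities)
        f.attrs["block_sizes"] = list(model.concat_order.block_sizes)
        f.create_dataset("demix_w", data=model.demix_w)
        f.create_dataset("aggregate_S", data=model.aggregate_S)
        if model.stability is not None:
            g = f.create_group("stability")
            g.create_dataset("cluster_quality", data=model.stability.cluster_quality)
            g.attrs["best_run_index"] = model.stability.best_run_index
            g.attrs["run_count"] = model.stability.run_count
        for mod, red in model.reductions.items():
            g = f.create_group(f"reduction_{mod}")
            g.create_dataset("group_basis", data=red.group_basis)
            g.create_dataset("group_sing", data=red.group_sing)
            g.attrs["subject_r"] = red.subject_r
            for i, part in enumerate(red.subject_partitions):
                g.create_dataset(f"partition_{i:04d}", data=part)


def load_model(path: str | Path) -> JointICAModel:
    with h5py.File(path, "r") as f:
        reductions = {}
        for mod in f.attrs["modalities"]:
            g = f[f"reduction_{mod}"]
            parts = sorted(k for k in g.keys() if k.startswith("partition_"))
            reductions[str(mod)] = GroupReduction(
                modality=str(mod),
                group_basis=np.asarray(g["group_basis"]),
                group_sing=np.asarray(g["group_sing"]),
                subject_partitions=tuple(np.asarray(g[k]) for k in parts),
                subject_r=int(g.attrs["subject_r"]),
            )
        stability = None
        if "stability" in f:
            g = f["stability"]
            stability = StabilityReport(
                cluster_quality=np.asarray(g["cluster_quality"]),
                best_run_index=int(g.attrs["best_run_index"]),
                run_count=int(g.attrs["run_count"]),
            )
        return JointICAModel(
            reductions=reductions,
            demix_w=np.asarray(f["demix_w"]),
            aggregate_S=np.asarray(f["aggregate_S"]),
            stability=stability,
            concat_order=ConcatOrder(
                modalities=tuple(str(m) for m in f.attrs["modalities"]),
                block_sizes=tuple(int(b) for b in f.attrs["block_sizes"]),
                scale=float(f.attrs["scale"]),
            ),
            seed=int(f.attrs["seed"]),
        )
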