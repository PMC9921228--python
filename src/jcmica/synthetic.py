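"""Synthetic multimodal cohorts with known ground truth.

The generator plants a set of compact gray-matter sources and expresses
them in two modalities that mirror how connectivity-matrix ICA reads real
data:

* **Functional**: each subject's voxel time series is a sum of rank-1
  terms, ``data[t, v] = sum_k strength[k] * M_fc[k, v] * tau_k(t)`` plus
  white Gaussian noise, with independent unit-variance latent courses
  ``tau_k``.  The implied voxel-correlation matrix is then exactly a sum
  of source x network outer products — the structure cmICA assumes.
  ``M_fc`` is the source blob plus a weaker (0.3) disjoint "network
  partner" blob, so functional networks extend beyond the source itself.
* **Structural**: fiber counts are Poisson with mean
  ``mean_count * sum_k strength[k] * S_true[k, v] * B_sc[k, w]`` where
  ``B_sc`` are elongated tract-like white-matter regions.

Sources are partitioned into shared / functional-only / structural-only
sets.  Shared sources use the same gray-matter support in both modalities,
giving an unambiguous recovery target for the joint decomposition.

Default study conditions
------------------------
Shared sources get base strength 1.0 and modality-specific sources 0.7,
with per-subject multiplicative jitter U(0.9, 1.1).  Shared sources are
modeled as the dominant connectivity modes: symmetric model orders sized
to the shared subspace (the convention the joint pipeline uses) are only
well-posed when that subspace carries the top per-subject variance, and
variance-ordered subject-level PCA needs a strength gap to make the
truncation stable rather than rotation-degenerate.  Default observation
noise is ``noise_sd = 0.5`` (SNR of roughly 2 at blob cores) and the mean
total fiber count per connected voxel pair is 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import BrainMask, StructuralConnectivity

__all__ = [
    "GroundTruth",
    "TimeSeriesSubject",
    "make_ground_truth",
    "simulate_subject_fmri",
    "simulate_subject_sc",
    "simulate_cohort",
]

#: Weight of the disjoint "network partner" blob in the functional map.
PARTNER_WEIGHT = 0.3
#: Base strength of sources expressed in both modalities.
SHARED_STRENGTH = 1.0
#: Base strength of sources expressed in a single modality.
SPECIFIC_STRENGTH = 0.7
#: Half-width of the per-subject multiplicative strength jitter.
STRENGTH_JITTER = 0.1
#: Rejection-sampling cap for blob placement.
MAX_PLACEMENT_ATTEMPTS = 1000
#: Max fraction of a tract's voxels allowed to overlap other tracts.
TRACT_OVERLAP_TOL = 0.10


class CapacityError(RuntimeError):
    """Raised when blobs cannot be placed disjointly on the requested grid."""


@dataclass(frozen=True)
class TimeSeriesSubject:
    """One subject's voxel time courses (T timepoints x V_gm voxels)."""

    data: np.ndarray
    subject_id: str
    mask: BrainMask

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 2:
            raise ValueError("time-series data must be T x V with T >= 2")
        if data.shape[1] != self.mask.n_voxels:
            raise ValueError("voxel count does not match mask")
        if not np.all(np.isfinite(data)):
            raise ValueError("time-series data contains non-finite values")
        object.__setattr__(self, "data", data)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class GroundTruth:
    """Planted sources and their modality-specific expression maps."""

    S_true: np.ndarray  # K_total x V_gm, nonneg, unit max per row
    M_fc: np.ndarray  # K_fc-expressed x V_gm functional maps
    B_sc: np.ndarray  # K_sc-expressed x V_wm white-matter target maps
    shared_ids: tuple[int, ...]
    fc_only_ids: tuple[int, ...]
    sc_only_ids: tuple[int, ...]
    subject_strengths: np.ndarray  # N_subj x K_total, positive
    gm_mask: BrainMask
    wm_mask: BrainMask
    seed: int
    fc_expressed_ids: tuple[int, ...] = field(init=False)
    sc_expressed_ids: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        k_total = self.S_true.shape[0]
        all_ids = sorted(self.shared_ids + self.fc_only_ids + self.sc_only_ids)
        if all_ids != list(range(k_total)):
            raise ValueError("shared/fc_only/sc_only must partition source ids")
        if np.any(self.subject_strengths <= 0):
            raise ValueError("subject strengths must be positive")
        for maps in (self.S_true, self.M_fc, self.B_sc):
            if maps.size and (maps.min() < 0 or not np.allclose(maps.max(axis=1), 1.0)):
                raise ValueError("expressed maps must be nonnegative with unit maximum")
        object.__setattr__(
            self, "fc_expressed_ids", tuple(sorted(self.shared_ids + self.fc_only_ids))
        )
        object.__setattr__(
            self, "sc_expressed_ids", tuple(sorted(self.shared_ids + self.sc_only_ids))
        )

    @property
    def k_total(self) -> int:
        return self.S_true.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.subject_strengths.shape[0]


def _sphere_offsets(radius: float) -> np.ndarray:
    """Integer offsets within ``radius`` of the origin."""
    r = int(np.floor(radius))
    grid = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1].reshape(3, -1).T
    return grid[np.linalg.norm(grid, axis=1) <= radius]

def _blob_values(offsets: np.ndarray, sigma: float) -> np.ndarray:
    d2 = (offsets**2).sum(axis=1)
    vals = np.exp(-d2 / (2.0 * sigma**2))
    return vals / vals.max()


def _place_disjoint_blobs(
    shape: tuple[int, int, int],
    offset_sets: list[np.ndarray],
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Rejection-sample blob centers so supports never overlap.

    ``offset_sets`` holds one voxel-offset template per blob, so blobs of
    different sizes can share the grid.
    """
    occupied = np.zeros(shape, dtype=bool)
    placements: list[np.ndarray] = []
    for offsets in offset_sets:
        lo = -offsets.min(axis=0)
        hi = np.array(shape) - offsets.max(axis=0)
        if np.any(hi <= lo):
            raise CapacityError(f"grid {shape} too small for the requested blob size")
        for _attempt in range(MAX_PLACEMENT_ATTEMPTS):
            center = rng.integers(lo, hi)
            vox = center[None, :] + offsets
            if not occupied[vox[:, 0], vox[:, 1], vox[:, 2]].any():
                occupied[vox[:, 0], vox[:, 1], vox[:, 2]] = True
                placements.append(vox)
                break
        else:
            raise CapacityError(
                f"could not place {len(offset_sets)} disjoint blobs on grid {shape} "
                f"within {MAX_PLACEMENT_ATTEMPTS} attempts"
            )
    return placements


def _tract_voxels(
    shape: tuple[int, int, int],
    rng: np.random.Generator,
    occupied: np.ndarray,
    length: int = 6,
    radius: float = 1.2,
) -> np.ndarray:
    """An elongated axis-aligned cylinder of voxels, fully inside the grid.

    Tracts are placed near-disjointly: candidate placements are tried in
    random order and one is accepted when at most TRACT_OVERLAP_TOL of
    its voxels touch previously placed tracts.  Distinct bundles thus
    occupy essentially distinct white matter, keeping the structural
    maps linearly independent — heavily overlapping tracts would make
    sources indistinguishable on the structural side by construction.
    """
    rc = int(np.ceil(radius))
    disc = [
        (du, dv)
        for du in range(-rc, rc + 1)
        for dv in range(-rc, rc + 1)
        if np.hypot(du, dv) <= radius
    ]
    margin = max(max(abs(du), abs(dv)) for du, dv in disc)
    candidates: list[tuple[int, np.ndarray]] = []
    for axis in range(3):
        tract_len = min(length, shape[axis])
        perp = [a for a in range(3) if a != axis]
        lo = np.zeros(3, dtype=int)
        hi = np.array(shape)
        lo[axis], hi[axis] = 0, shape[axis] - tract_len + 1
        small = False
        for p in perp:
            lo[p], hi[p] = margin, shape[p] - margin
            if hi[p] <= lo[p]:
                small = True
        if small:
            continue
        for sx in range(lo[0], hi[0]):
            for sy in range(lo[1], hi[1]):
                for sz in range(lo[2], hi[2]):
                    candidates.append((axis, np.array([sx, sy, sz])))
    if not candidates:
        raise CapacityError(f"white-matter grid {shape} too small for tract radius {radius}")

    def cylinder(axis: int, start: np.ndarray) -> np.ndarray:
        tract_len = min(length, shape[axis])
        perp = [a for a in range(3) if a != axis]
        vox = []
        for step in range(tract_len):
            c = start.copy()
            c[axis] += step
            for du, dv in disc:
                p = c.copy()
                p[perp[0]] += du
                p[perp[1]] += dv
                vox.append(p)
        return np.unique(np.array(vox), axis=0)

    order = rng.permutation(len(candidates))
    for i in order[:MAX_PLACEMENT_ATTEMPTS]:
        axis, start = candidates[int(i)]
        vox = cylinder(axis, start)
        n_overlap = int(occupied[vox[:, 0], vox[:, 1], vox[:, 2]].sum())
        if n_overlap <= TRACT_OVERLAP_TOL * len(vox):
            occupied[vox[:, 0], vox[:, 1], vox[:, 2]] = True
            return vox
    raise CapacityError(
        f"could not place disjoint tracts on white-matter grid {shape} "
        f"within {MAX_PLACEMENT_ATTEMPTS} attempts"
    )


def _vector_from_voxels(
    voxels: np.ndarray, values: np.ndarray, mask: BrainMask
) -> np.ndarray:
    vol = np.zeros(mask.shape)
    vol[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = values
    return vol.ravel(order="F")[mask.flat_indices]


def make_ground_truth(
    grid_gm: tuple[int, int, int],
    grid_wm: tuple[int, int, int],
    k_shared: int,
    k_fc_only: int,
    k_sc_only: int,
    seed: int,
    n_subjects: int = 10,
    blob_radius: float = 1.6,
    partner_radius: float = 1.2,
) -> GroundTruth:
    """Plant disjoint gray-matter sources and their modality expressions.

    Sources are spheres of fixed radius with a smooth (Gaussian-profile)
    interior, placed by rejection sampling with strictly disjoint support.
    Functional maps add a weaker disjoint partner blob; structural maps
    are elongated tract-like cylinders in the white-matter grid.

    Partner blobs are smaller than source blobs (weaker secondary network
    nodes).  This is a property of the generative design, not a free
    dial: the functional expression map ``S + 0.3 * partner`` must itself
    stay highly correlated with the source for the source to remain a
    recoverable target; equal-mass partners would cap that correlation
    near 0.96 regardless of estimation quality.
    """
    if min(k_shared, k_fc_only, k_sc_only) < 0:
        raise ValueError("source counts must be nonnegative")
    k_total = k_shared + k_fc_only + k_sc_only
    if k_total < 2:
        raise ValueError("need at least 2 sources in total")
    rng = np.random.default_rng(seed)
    gm_mask = BrainMask.full(grid_gm)
    wm_mask = BrainMask.full(grid_wm)

    shared_ids = tuple(range(k_shared))
    fc_only_ids = tuple(range(k_shared, k_shared + k_fc_only))
    sc_only_ids = tuple(range(k_shared + k_fc_only, k_total))
    fc_expressed = sorted(shared_ids + fc_only_ids)
    sc_expressed = sorted(shared_ids + sc_only_ids)

    offsets = _sphere_offsets(blob_radius)
    profile = _blob_values(offsets, sigma=blob_radius / 1.2)
    p_offsets = _sphere_offsets(partner_radius)
    p_profile = _blob_values(p_offsets, sigma=partner_radius / 1.2)
    # one blob per source plus one partner blob per FC-expressed source,
    # all mutually disjoint in the gray-matter grid
    templates = [offsets] * k_total + [p_offsets] * len(fc_expressed)
    blobs = _place_disjoint_blobs(grid_gm, templates, rng)
    source_blobs, partner_blobs = blobs[:k_total], blobs[k_total:]

    v_gm = gm_mask.n_voxels
    S_true = np.zeros((k_total, v_gm))
    for k in range(k_total):
        S_true[k] = _vector_from_voxels(source_blobs[k], profile, gm_mask)

    M_fc = np.zeros((len(fc_expressed), v_gm))
    for j, k in enumerate(fc_expressed):
        partner = _vector_from_voxels(partner_blobs[j], p_profile, gm_mask)
        M_fc[j] = S_true[k] + PARTNER_WEIGHT * partner
    if M_fc.size:
        M_fc /= M_fc.max(axis=1, keepdims=True)

    v_wm = wm_mask.n_voxels
    B_sc = np.zeros((len(sc_expressed), v_wm))
    wm_occupied = np.zeros(grid_wm, dtype=bool)
    for j in range(len(sc_expressed)):
        tract = _tract_voxels(grid_wm, rng, wm_occupied)
        B_sc[j] = _vector_from_voxels(tract, np.ones(len(tract)), wm_mask)

    base = np.full(k_total, SPECIFIC_STRENGTH)
    base[list(shared_ids)] = SHARED_STRENGTH
    jitter = rng.uniform(1.0 - STRENGTH_JITTER, 1.0 + STRENGTH_JITTER, size=(n_subjects, k_total))
    strengths = base[None, :] * jitter

    return GroundTruth(
        S_true=S_true,
        M_fc=M_fc,
        B_sc=B_sc,
        shared_ids=shared_ids,
        fc_only_ids=fc_only_ids,
        sc_only_ids=sc_only_ids,
        subject_strengths=strengths,
        gm_mask=gm_mask,
        wm_mask=wm_mask,
        seed=seed,
    )


def fc_mixing_matrix(truth: GroundTruth, subject: int) -> np.ndarray:
    """Per-subject functional mixing M (V_gm x K_fc): strength-weighted maps."""
    ids = list(truth.fc_expressed_ids)
    weights = truth.subject_strengths[subject, ids]
    return (truth.M_fc * weights[:, None]).T


def analytic_fc_correlation(truth: GroundTruth, subject: int, noise_sd: float) -> np.ndarray:
    """Closed-form voxel correlation implied by the generative mixing.

    With independent unit-variance latent courses and white noise the
    covariance is ``M M' + noise_sd^2 I``; the correlation follows by
    normalizing the diagonal.
    """
    m = fc_mixing_matrix(truth, subject)
    cov = m @ m.T + noise_sd**2 * np.eye(m.shape[0])
    d = np.sqrt(np.diag(cov))
    d[d == 0] = 1.0
    return cov / np.outer(d, d)


def simulate_subject_fmri(
    truth: GroundTruth, subject: int, t_len: int, noise_sd: float, seed: int
) -> TimeSeriesSubject:
    """Draw one subject's BOLD-like voxel time series."""
    n_fc = len(truth.fc_expressed_ids)
    if t_len < 2 * max(n_fc, 1):
        raise ValueError(f"t_len={t_len} too small for {n_fc} functional sources")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    m = fc_mixing_matrix(truth, subject)  # V x K
    tau = rng.standard_normal((t_len, n_fc))
    data = tau @ m.T
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    return TimeSeriesSubject(data=data, subject_id=f"sub-{subject:03d}", mask=truth.gm_mask)


def expected_sc_mean(truth: GroundTruth, subject: int, mean_count: float) -> np.ndarray:
    """Expected count matrix (V_gm x V_wm) of the structural generator."""
    ids = list(truth.sc_expressed_ids)
    weights = truth.subject_strengths[subject, ids]
    lam = np.zeros((truth.gm_mask.n_voxels, truth.wm_mask.n_voxels))
    for j, k in enumerate(ids):
        lam += weights[j] * np.outer(truth.S_true[k], truth.B_sc[j])
    return mean_count * lam


def simulate_subject_sc(
    truth: GroundTruth, subject: int, mean_count: float, seed: int
) -> StructuralConnectivity:
    """Draw one subject's Poisson fiber-count matrix."""
    if mean_count <= 0:
        raise ValueError("mean_count must be positive")
    rng = np.random.default_rng(seed)
    lam = expected_sc_mean(truth, subject, mean_count)
    counts = rng.poisson(lam)
    return StructuralConnectivity(
        matrix=counts,
        row_mask=truth.gm_mask,
        col_mask=truth.wm_mask,
        subject_id=f"sub-{subject:03d}",
    )


def _subject_seeds(master_seed: int, n_subjects: int) -> np.ndarray:
    """Independent per-subject streams derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2 * n_subjects)])


def simulate_cohort(
    truth: GroundTruth,
    n_subjects: int,
    t_len: int = 300,
    noise_sd: float = 0.5,
    mean_count: float = 20.0,
    seed: int = 0,
) -> tuple[list[TimeSeriesSubject], list[StructuralConnectivity]]:
    """Paired functional + structural datasets for a whole cohort."""
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if n_subjects > truth.n_subjects:
        raise ValueError(
            f"ground truth holds strengths for {truth.n_subjects} subjects, "
            f"requested {n_subjects}"
        )
    seeds = _subject_seeds(seed, n_subjects)
    fmri = [
        simulate_subject_fmri(truth, k, t_len, noise_sd, int(seeds[2 * k]))
        for k in range(n_subjects)
    ]
    sc = [
        simulate_subject_sc(truth, k, mean_count, int(seeds[2 * k + 1]))
        for k in range(n_subjects)
    ]
    return fmri, sc
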