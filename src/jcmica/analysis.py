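"""Post-decomposition analytics.

Variance sorting, the modality contribution ratio with its 20-80%
shared-source screen, cross-modality spatial similarity, t-statistic
maps, mean + k*sigma thresholding (k = 3 for source maps, k = 2 for
connectivity maps), and atlas-overlap labeling.

"Loadings" of a component are the entries of the corresponding column
of the mixing matrix A = W^-1, partitioned by modality block: they say
how strongly each modality's reduced data expresses that source.  A
component whose mean absolute loading is balanced between the two
blocks (contribution ratio within [0.2, 0.8], bounds inclusive) counts
as shared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fusion import JointICAModel
from .volume_io import AtlasVolume

__all__ = [
    "ComponentSummary",
    "sort_by_variance",
    "explained_variance",
    "contribution_ratio",
    "select_shared",
    "spatial_similarity",
    "tstat_map",
    "threshold_map",
    "atlas_overlap",
    "component_report",
]

SHARED_LOW = 0.2
SHARED_HIGH = 0.8
K_SIGMA_SOURCE = 3.0  # source (S) maps
K_SIGMA_CONNECTIVITY = 2.0  # connectivity (R) maps


class UndefinedRatioError(ZeroDivisionError):
    """Both modality loadings of a component are zero."""


@dataclass(frozen=True)
class ComponentSummary:
    component_id: int
    variance_fc: float
    variance_sc: float
    contribution_fc: float
    shared: bool
    spatial_similarity: float = np.nan
    atlas_label: str | None = None
    atlas_overlap_pct: float = np.nan

    @property
    def contribution_sc(self) -> float:
        return 1.0 - self.contribution_fc


def explained_variance(model: JointICAModel) -> dict[str, np.ndarray]:
    """Per-component share of each modality block's variance.

    Sources have unit variance, so component j explains a share of block
    m's variance proportional to the squared norm of its loading column
    restricted to that block.
    """
    a = model.mixing
    out = {}
    for mod in model.concat_order.modalities:
        bl = model.concat_order.block(mod)
        power = (a[bl, :] ** 2).sum(axis=0)
        out[mod] = power / power.sum()
    return out


def sort_by_variance(model: JointICAModel) -> np.ndarray:
    """Component indices by descending mean explained variance.

    The mean is over the two modalities; ties break by component index
    (stable sort).  Indices are 0-based.
    """
    var = explained_variance(model)
    mean_var = np.mean([var[m] for m in model.concat_order.modalities], axis=0)
    return np.argsort(-mean_var, kind="stable")


def contribution_ratio(model: JointICAModel) -> np.ndarray:
    """Per-component (contribution_fc, contribution_sc), rows sum to 1.

    For component j, a modality's contribution is the mean absolute
    loading over its block of A[:, j]; the ratio is FC's share of the
    two contributions.
    """
    a = np.abs(model.mixing)
    fc_bl = model.concat_order.block("FC")
    sc_bl = model.concat_order.block("SC")
    a_fc = a[fc_bl, :].mean(axis=0)
    a_sc = a[sc_bl, :].mean(axis=0)
    total = a_fc + a_sc
    dead = np.flatnonzero(total == 0)
    if dead.size:
        raise UndefinedRatioError(
            f"components {dead.tolist()} have zero loadings in both modalities"
        )
    ratio_fc = a_fc / total
    return np.column_stack([ratio_fc, 1.0 - ratio_fc])


def select_shared(
    ratios: np.ndarray, low: float = SHARED_LOW, high: float = SHARED_HIGH
) -> np.ndarray:
    """Indices of components whose FC contribution lies in [low, high].

    Bounds are inclusive ("no more than 80% and no less than 20%").
    Accepts either the two-column output of :func:`contribution_ratio`
    or a bare vector of FC ratios.
    """
    if low >= high:
        raise ValueError("low bound must be below high bound")
    ratios = np.asarray(ratios, dtype=float)
    fc = ratios[:, 0] if ratios.ndim == 2 else ratios
    if np.any((fc < 0) | (fc > 1)):
        raise ValueError("ratios must lie in [0, 1]")
    return np.flatnonzero((fc >= low) & (fc <= high))


def spatial_similarity(
    s_fc: np.ndarray,
    s_sc: np.ndarray,
    n_permutations: int = 0,
    seed: int = 0,
) -> float | tuple[float, float]:
    """Pearson correlation between two spatial maps over gray voxels.

    With ``n_permutations > 0`` also returns a voxel-shuffle permutation
    p-value (two-sided on |r|).
    """
    x = np.asarray(s_fc, dtype=float)
    y = np.asarray(s_sc, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("maps must be 1-D and of equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("spatial similarity undefined for zero-variance maps")
    r = float(np.corrcoef(x, y)[0, 1])
    if n_permutations <= 0:
        return r
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
    p = (1 + np.sum(np.abs(null) >= abs(r))) / (n_permutations + 1)
    return r, float(p)


def tstat_map(subject_maps: np.ndarray) -> np.ndarray:
    """Voxel-wise one-sample t statistic across subjects.

    ``subject_maps`` is n_subjects x V.  Zero-variance voxels get t = 0
    and a warning (the statistic is undefined there).
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance voxel(s) set to t=0", RuntimeWarning
        )
    sd_safe = np.where(zero, 1.0, sd)
    t = mean / (sd_safe / np.sqrt(n))
    t[zero] = 0.0
    return t


def threshold_map(values: np.ndarray, k_sigma: float) -> np.ndarray:
    """Binary ROI of voxels exceeding the map's own mean + k*sigma.

    ``k_sigma`` defaults are 3 for source maps and 2 for connectivity
    maps (module constants).  A constant map has sigma 0 and yields an
    empty ROI with a warning.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("map contains non-finite values")
    mu = values.mean()
    sigma = values.std(ddof=1) if values.size > 1 else 0.0
    if sigma == 0:
        warnings.warn("constant map: threshold ROI is empty", RuntimeWarning)
        return np.zeros_like(values, dtype=bool)
    return values > mu + k_sigma * sigma


def atlas_overlap(
    roi: np.ndarray, atlas: AtlasVolume
) -> tuple[dict[int, float], int | None]:
    """Percentage overlap of an ROI with each atlas label.

    ``overlap%(label) = 100 * |ROI ∩ label| / |ROI|`` — containment of
    the ROI, not Dice.  Returns the per-label percentages (nonzero
    labels the ROI touches) and the best label (max overlap, ties to the
    lowest id; None when the ROI only covers background).
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != atlas.labels.shape:
        raise ValueError("ROI and atlas grids differ")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    labels_in = atlas.labels[roi]
    ids, counts = np.unique(labels_in, return_counts=True)
    overlaps = {
        int(i): 100.0 * int(c) / n_roi for i, c in zip(ids, counts) if i != 0
    }
    best = None
    if overlaps:
        best_pct = max(overlaps.values())
        best = min(i for i, p in overlaps.items() if p == best_pct)
    return overlaps, best


def component_report(
    model: JointICAModel,
    spatial_sims: np.ndarray | None = None,
    atlas_labels: dict[int, tuple[str, float]] | None = None,
    exclude: set[int] | None = None,
) -> pd.DataFrame:
    """Tabular per-component summary (machine twin of the labeled tables).

    Columns: component_id, variance_fc, variance_sc, contribution_fc,
    shared, spatial_similarity, atlas_label, overlap_pct.  ``exclude``
    is the manual artifact-screen list; excluded components are kept in
    the table but flagged.
    """
    var = explained_variance(model)
    ratios = contribution_ratio(model)
    shared = set(select_shared(ratios).tolist())
    exclude = exclude or set()
    rows = []
    for j in range(model.c):
        label, pct = (None, np.nan)
        if atlas_labels and j in atlas_labels:
            label, pct = atlas_labels[j]
        rows.append(
            {
                "component_id": j,
                "variance_fc": var["FC"][j],
                "variance_sc": var["SC"][j],
                "contribution_fc": ratios[j, 0],
                "shared": (j in shared) and (j not in exclude),
                "excluded": j in exclude,
                "spatial_similarity": (
                    spatial_sims[j] if spatial_sims is not None else np.nan
                ),
                "atlas_label": label if label is not None else "unlabeled",
                "overlap_pct": pct,
            }
        )
    df = pd.DataFrame(rows)
    order = sort_by_variance(model)
    return df.iloc[order].reset_index(drop=True)
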