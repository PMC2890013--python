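"""Random-effects group statistics on subject z maps.

Subjects' connectivity z maps are treated as draws from a population:
intragroup maps are voxelwise one-sample t statistics (df = n-1), intergroup
maps voxelwise pooled-variance two-sample t statistics (df = n1+n2-2).
Voxel-level significance uses a one-sided threshold on positive t, by
default Bonferroni-corrected over the in-brain voxel count. Surviving
suprathreshold voxels are decomposed into connected components
(18-connectivity by default) and components smaller than the minimum
cluster extent - 125 voxels, i.e. 1 cm^3 at 2 mm isotropic voxels - are
eliminated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .connectivity import SubjectConnectivityMap

__all__ = [
    "GroupStatMap",
    "one_sample_map",
    "two_sample_map",
    "voxel_threshold",
    "cluster_filter",
    "peak_report",
    "CONNECTIVITY_STRUCTURES",
]

#: scipy generate_binary_structure rank per neuroimaging connectivity name
CONNECTIVITY_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass
class GroupStatMap:
    """Voxelwise t map with degrees of freedom and threshold metadata."""

    t: np.ndarray
    df: int
    affine: np.ndarray
    contrast: str
    n_subjects: tuple[int, ...]
    voxel_p_threshold: float = 0.001
    correction: str = "bonferroni"
    report_t_threshold: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.t)


def _stack(maps: list[SubjectConnectivityMap]) -> np.ndarray:
    shapes = {m.z.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"subject maps on different grids: {sorted(shapes)}")
    return np.stack([m.z for m in maps])


def one_sample_map(subject_maps: list[SubjectConnectivityMap],
                   contrast: str = "group_mean") -> GroupStatMap:
    """Voxelwise one-sample t across subjects: t = mean / (sd / sqrt(n)).

    Undefined (NaN) wherever any subject is undefined. Zero between-subject
    variance yields +/-inf where the mean is nonzero and 0 where it is zero.
    """
    if len(subject_maps) < 2:
        raise ValueError("one-sample map needs >= 2 subjects")
    z = _stack(subject_maps)
    n = z.shape[0]
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = (sd == 0) & ~np.isnan(mean)
    m = mean[degenerate]
    t[degenerate] = np.where(m > 0, np.inf, np.where(m < 0, -np.inf, 0.0))
    return GroupStatMap(t=t, df=n - 1, affine=subject_maps[0].affine,
                        contrast=contrast, n_subjects=(n,))


def two_sample_map(group_a: list[SubjectConnectivityMap],
                   group_b: list[SubjectConnectivityMap],
                   contrast: str = "A_minus_B") -> GroupStatMap:
    """Voxelwise pooled-variance two-sample t for group A minus group B."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("two-sample map needs >= 2 subjects per group")
    za, zb = _stack(group_a), _stack(group_b)
    if za.shape[1:] != zb.shape[1:]:
        raise ValueError(f"grid mismatch: {za.shape[1:]} vs {zb.shape[1:]}")
    n1, n2 = za.shape[0], zb.shape[0]
    diff = za.mean(axis=0) - zb.mean(axis=0)
    pooled_var = (
        (n1 - 1) * za.var(axis=0, ddof=1) + (n2 - 1) * zb.var(axis=0, ddof=1)
    ) / (n1 + n2 - 2)
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    degenerate = (se == 0) & ~np.isnan(diff)
    d = diff[degenerate]
    t[degenerate] = np.where(d > 0, np.inf, np.where(d < 0, -np.inf, 0.0))
    return GroupStatMap(t=t, df=n1 + n2 - 2, affine=group_a[0].affine,
                        contrast=contrast, n_subjects=(n1, n2))


def voxel_threshold(
    stat_map: GroupStatMap,
    p: float = 0.001,
    correction: str = "bonferroni",
    brain_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """One-sided voxel-level threshold; returns (mask, equivalent t cutoff).

    ``bonferroni`` divides p by the number of in-mask defined voxels;
    ``none`` uses p per voxel directly.
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    defined = stat_map.defined_mask
    if brain_mask is not None:
        defined = defined & brain_mask
    n_vox = int(defined.sum())
    if n_vox == 0:
        return np.zeros_like(defined), np.inf
    alpha = p / n_vox if correction == "bonferroni" else p
    t_cut = float(stats.t.isf(alpha, stat_map.df))
    mask = np.zeros_like(defined)
    with np.errstate(invalid="ignore"):
        mask[defined] = stat_map.t[defined] > t_cut
    return mask, t_cut


def cluster_filter(
    suprathreshold: np.ndarray,
    t_map: np.ndarray | None = None,
    min_cluster_voxels: int = 125,
    connectivity: int = 18,
    voxel_volume_mm3: float = 8.0,
) -> pd.DataFrame:
    """Connected-component decomposition with a minimum-extent filter.

    Components with fewer than ``min_cluster_voxels`` voxels are removed
    (the 125-voxel default equals 1 cm^3 at 2 mm isotropic voxels: a
    124-voxel blob is eliminated, a 125-voxel blob retained). Returns one
    row per surviving cluster - size_vox, size_cm3, peak_t, peak grid
    indices - sorted by peak t descending. An empty mask yields an empty
    table.
    """
    if connectivity not in CONNECTIVITY_STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(CONNECTIVITY_STRUCTURES)}")
    structure = ndimage.generate_binary_structure(3, CONNECTIVITY_STRUCTURES[connectivity])
    labeled, n_components = ndimage.label(suprathreshold, structure=structure)
    rows = []
    for comp in range(1, n_components + 1):
        comp_mask = labeled == comp
        size = int(comp_mask.sum())
        if size < min_cluster_voxels:
            continue
        if t_map is not None:
            vals = np.where(comp_mask, t_map, -np.inf)
            peak_flat = int(np.argmax(vals))
            peak = np.unravel_index(peak_flat, t_map.shape)
            peak_t = float(t_map[peak])
        else:
            peak = tuple(int(c[0]) for c in np.nonzero(comp_mask))
            peak_t = np.nan
        rows.append(
            dict(size_vox=size, size_cm3=size * voxel_volume_mm3 / 1000.0,
                 peak_t=peak_t, peak_i=peak[0], peak_j=peak[1], peak_k=peak[2])
        )
    table = pd.DataFrame(
        rows, columns=["size_vox", "size_cm3", "peak_t", "peak_i", "peak_j", "peak_k"]
    )
    if len(table):
        table = table.sort_values("peak_t", ascending=False, ignore_index=True)
    return table


def peak_report(cluster_table: pd.DataFrame, affine: np.ndarray) -> pd.DataFrame:
    """Add world (MNI-convention) peak coordinates to a cluster table."""
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine is singular")
    table = cluster_table.copy()
    if len(table) == 0:
        for c in ("peak_x_mm", "peak_y_mm", "peak_z_mm"):
            table[c] = pd.Series(dtype=float)
        return table
    grid = np.column_stack([table.peak_i, table.peak_j, table.peak_k,
                            np.ones(len(table))])
    world = (affine @ grid.T).T[:, :3]
    table[["peak_x_mm", "peak_y_mm", "peak_z_mm"]] = world
    return table
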