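"""Searchlight maps, ROI accuracy, and group-level cluster inference.

The cortical surface is abstracted to a geometry of units ("voxels") with
coordinates and per-unit surface areas; a searchlight selects for each
center its p=160 nearest units, runs the cross-validated LDA inside the
neighborhood, and assigns the accuracy to the center.  ROI accuracies use
the random-subspace scheme (repeatedly drawing 160-voxel subsets from the
top-800 most activated units and averaging accuracy over draws).  Group
maps are tested with per-unit one-sample t statistics and cluster-level
family-wise inference by sign-flip permutation of the subject maps, with
the cluster statistic being suprathreshold surface area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .mvpa import DEFAULT_REG_FRACTION, crossval_accuracy

DEFAULT_SEARCHLIGHT_P = 160
DEFAULT_TOP_ACTIVE = 800
DEFAULT_SUBSPACE_DRAWS = 5000
DEFAULT_CLUSTER_P = 0.002

__all__ = [
    "VoxelGeometry",
    "AccuracyMap",
    "GroupMapResult",
    "sheet_geometry",
    "build_neighborhoods",
    "searchlight_map",
    "select_top_active",
    "roi_random_subspace_accuracy",
    "suprathreshold_area",
    "group_map_test",
    "write_map_table",
]


@dataclass(frozen=True)
class VoxelGeometry:
    """Unit coordinates (mm) with per-unit surface areas (cm^2)."""

    coords: np.ndarray  # (n, dim)
    areas: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.coords, dtype=float))
        a = np.asarray(self.areas, dtype=float)
        if len(np.unique(c, axis=0)) != c.shape[0]:
            raise ValueError("coordinates must be unique")
        if a.shape[0] != c.shape[0] or np.any(a <= 0):
            raise ValueError("areas must be positive, one per unit")
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "areas", a)

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]


def sheet_geometry(nx: int, ny: int, spacing: float = 1.0, unit_area: float = 1.0) -> VoxelGeometry:
    """A flat nx x ny sheet of units with uniform spacing and areas."""
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    coords = np.column_stack([xx.ravel(), yy.ravel()]) * spacing
    return VoxelGeometry(coords, np.full(nx * ny, unit_area))


@dataclass(frozen=True)
class AccuracyMap:
    """Per-center searchlight accuracy (and z) aligned to a geometry."""

    accuracy: np.ndarray
    z: np.ndarray
    n_test: int


def build_neighborhoods(
    geometry: VoxelGeometry, p: int = DEFAULT_SEARCHLIGHT_P
) -> tuple[np.ndarray, np.ndarray]:
    """For each center, the indices of its p nearest units.

    Ties in distance are broken by unit index.  Returns (neighborhoods,
    radii): an (n, p) index array and the achieved radius per center.
    """
    n = geometry.n_voxels
    if n < p:
        raise ValueError(f"geometry has {n} units, need at least p={p}")
    dist = cdist(geometry.coords, geometry.coords)
    order = np.argsort(dist, axis=1, kind="stable")  # stable: ties -> lower index
    hoods = order[:, :p]
    radii = np.take_along_axis(dist, hoods[:, -1:], axis=1).ravel()
    return hoods, radii


def searchlight_map(
    betas: np.ndarray,
    neighborhoods: np.ndarray,
    reg_fraction: float = DEFAULT_REG_FRACTION,
) -> AccuracyMap:
    """Cross-validated accuracy per neighborhood, assigned to the center."""
    b = np.asarray(betas, dtype=float)
    accs = np.empty(neighborhoods.shape[0])
    zs = np.empty(neighborhoods.shape[0])
    n_test = 0
    for i, hood in enumerate(neighborhoods):
        res = crossval_accuracy(b[:, :, hood], reg_fraction)
        accs[i], zs[i], n_test = res.accuracy, res.z, res.n_test
    return AccuracyMap(accs, zs, n_test)


def select_top_active(activation: np.ndarray, n: int = DEFAULT_TOP_ACTIVE) -> np.ndarray:
    """Indices of the n most activated units; ties broken by index."""
    act = np.asarray(activation, dtype=float)
    if act.shape[0] < n:
        raise ValueError("fewer units than requested")
    return np.argsort(-act, kind="stable")[:n]


def roi_random_subspace_accuracy(
    roi_betas: np.ndarray,
    subset_size: int = DEFAULT_SEARCHLIGHT_P,
    n_draws: int = DEFAULT_SUBSPACE_DRAWS,
    rng_seed: int | None = None,
    reg_fraction: float = DEFAULT_REG_FRACTION,
) -> float:
    """Mean cross-validated accuracy over random voxel subsets of an ROI.

    Draws ``subset_size`` voxels without replacement ``n_draws`` times and
    averages the leave-one-run-out accuracy over draws; when the subset is
    the whole ROI the result is the direct ROI accuracy.
    """
    b = np.asarray(roi_betas, dtype=float)
    p = b.shape[2]
    if p < subset_size:
        raise ValueError(f"ROI has {p} voxels, need at least {subset_size}")
    if p == subset_size:
        return crossval_accuracy(b, reg_fraction).accuracy
    rng = np.random.default_rng(rng_seed)
    accs = np.empty(n_draws)
    for i in range(n_draws):
        sub = rng.choice(p, size=subset_size, replace=False)
        accs[i] = crossval_accuracy(b[:, :, sub], reg_fraction).accuracy
    return float(accs.mean())


def suprathreshold_area(
    acc_map: AccuracyMap, threshold_acc: float, geometry: VoxelGeometry
) -> float:
    """Total surface area (cm^2) of units with accuracy above threshold."""
    mask = acc_map.accuracy > threshold_acc
    return float(geometry.areas[mask].sum())


# -- group-level cluster inference ------------------------------------------


@dataclass(frozen=True)
class GroupMapResult:
    t_map: np.ndarray
    t_threshold: float
    cluster_labels: np.ndarray  # -1 for sub-threshold units
    clusters: pd.DataFrame  # cluster id, n_units, area_cm2, peak_t, p_fwe


def _adjacency(geometry: VoxelGeometry, connect_radius: float) -> csr_matrix:
    d = cdist(geometry.coords, geometry.coords)
    adj = (d > 0) & (d <= connect_radius)
    return csr_matrix(adj)


def _clusters_above(
    stat: np.ndarray, thresh: float, adj: csr_matrix, areas: np.ndarray
) -> tuple[np.ndarray, list[tuple[int, float, float]]]:
    """Connected suprathreshold components: labels plus (size, area, peak)."""
    mask = stat > thresh
    labels = np.full(stat.shape[0], -1)
    if not mask.any():
        return labels, []
    sub = adj[mask][:, mask]
    n_comp, comp = connected_components(sub, directed=False)
    labels[mask] = comp
    out = []
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        out.append((len(members), float(areas[members].sum()), float(stat[members].max())))
    return labels, out


def group_map_test(
    subject_maps: np.ndarray,
    geometry: VoxelGeometry,
    mu: float | np.ndarray = 0.0,
    cluster_forming_p: float = DEFAULT_CLUSTER_P,
    n_perm: int = 1000,
    connect_radius: float = 1.5,
    rng_seed: int | None = None,
) -> GroupMapResult:
    """One-sample t-map against ``mu`` with cluster-area FWE by permutation.

    The cluster-forming threshold is the one-sided critical t at
    ``cluster_forming_p`` with n_subjects - 1 degrees of freedom (p=0.002
    with 16 subjects gives t(15) > 3.39).  The family-wise p of each
    observed cluster is the fraction of sign-flip permutations whose
    maximum suprathreshold cluster area reaches the cluster's area.  For a
    paired contrast, pass the per-subject difference maps.
    """
    maps = np.asarray(subject_maps, dtype=float) - mu
    n_sub, n_vox = maps.shape
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    if n_vox != geometry.n_voxels:
        raise ValueError("maps not aligned to geometry")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values are coarse", stacklevel=2)

    df = n_sub - 1
    t_thresh = float(stats.t.isf(cluster_forming_p, df))

    def t_of(m: np.ndarray) -> np.ndarray:
        sd = m.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return m.mean(axis=0) / (sd / np.sqrt(n_sub))

    adj = _adjacency(geometry, connect_radius)
    t_map = t_of(maps)
    labels, clusters = _clusters_above(t_map, t_thresh, adj, geometry.areas)

    rng = np.random.default_rng(rng_seed)
    max_null = np.zeros(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_sub)[:, None]
        _, perm_clusters = _clusters_above(t_of(maps * signs), t_thresh, adj, geometry.areas)
        if perm_clusters:
            max_null[i] = max(a for _, a, _ in perm_clusters)

    rows = []
    for cid, (size, area, peak) in enumerate(clusters):
        p_fwe = (1 + np.sum(max_null >= area)) / (n_perm + 1)
        rows.append(
            {"cluster": cid, "n_units": size, "area_cm2": area, "peak_t": peak, "p_fwe": p_fwe}
        )
    table = pd.DataFrame(rows, columns=["cluster", "n_units", "area_cm2", "peak_t", "p_fwe"])
    return GroupMapResult(t_map, t_thresh, labels, table)


def write_map_table(acc_map: AccuracyMap, geometry: VoxelGeometry, path) -> None:
    """Flat-table map output: one row per unit with coordinates and stats."""
    cols = {f"coord_{ax}": geometry.coords[:, i] for i, ax in enumerate("xyz"[: geometry.coords.shape[1]])}
    cols["accuracy"] = acc_map.accuracy
    cols["z"] = acc_map.z
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
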