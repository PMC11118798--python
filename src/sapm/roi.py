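"""Region-of-interest extraction and balanced sub-region parcellation.

Voxels belonging to each labeled region are pulled from a 4-D image and
split into ``k`` near-equal-volume sub-regions by k-means on the voxel
coordinates, with greedy post-hoc balancing; sub-region mean time-courses
feed the network fitter through the shared tabular dialect.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "VoxelBlock",
    "SubRegionAssignment",
    "EmptyRegionError",
    "extract_region_voxels",
    "kmeans_subregions",
    "subregion_timecourses",
]


class EmptyRegionError(ValueError):
    """Raised when a region code selects no voxels."""


@dataclass
class VoxelBlock:
    """All voxels of one region: 0-based coordinates and their time-series."""

    region: str
    coords: np.ndarray  # (n_voxels, 3) int
    series: np.ndarray  # (n_voxels, n_volumes)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.series = np.asarray(self.series, dtype=float)
        if self.series.shape[0] != self.coords.shape[0]:
            raise ValueError("series row count must equal voxel count")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("voxel coordinates must be unique")

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]


@dataclass
class SubRegionAssignment:
    """Per-voxel cluster labels, 1-based, for one region."""

    region: str
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(np.unique(self.labels))
        if not present <= set(range(1, self.k + 1)):
            raise ValueError("labels must lie in 1..k")
        if len(present) != self.k:
            raise ValueError("all k clusters must be non-empty")

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


def _as_array(img):
    """Accept a numpy array or anything with ``get_fdata`` (nibabel image)."""
    if hasattr(img, "get_fdata"):
        return np.asarray(img.get_fdata())
    return np.asarray(img)


def extract_region_voxels(image4d, labelmap, region_code: int, region: str | None = None) -> VoxelBlock:
    """Voxels (0-based coordinates) and time-series where label == code."""
    data = _as_array(image4d)
    labels = _as_array(labelmap)
    if data.shape[:3] != labels.shape[:3]:
        raise ValueError(
            f"image grid {data.shape[:3]} does not match label grid {labels.shape[:3]}"
        )
    mask = labels.astype(int) == int(region_code)
    if not mask.any():
        raise EmptyRegionError(f"region code {region_code} not present in label map")
    coords = np.argwhere(mask)
    series = data[mask]
    return VoxelBlock(region=region or str(region_code), coords=coords, series=series)


def kmeans_subregions(
    block: VoxelBlock,
    k: int = 5,
    seed: int = 0,
    balance_tol: float = 0.25,
) -> SubRegionAssignment:
    """Near-equal-volume spatial clusters via k-means + greedy balancing.

    K-means runs on voxel coordinates; voxels are then moved from over-full
    clusters to the nearest under-full cluster centroid until
    ``max size <= (1 + balance_tol) * mean size``.  Deterministic for a
    given seed; nearest-centroid ties break toward the lowest index.
    """
    n = block.n_voxels
    if n < k:
        raise ValueError(f"{n} voxels cannot form {k} clusters")
    coords = block.coords.astype(float)
    if k == 1:
        return SubRegionAssignment(region=block.region, labels=np.ones(n, dtype=int), k=1)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(coords)
    # extra deterministic run seeded at quantiles along the principal axis;
    # finds the balanced optimum for elongated regions where k-means++ can
    # stall in an unequal local minimum
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    order = np.argsort(proj, kind="stable")
    init = np.array(
        [coords[chunk].mean(axis=0) for chunk in np.array_split(order, k)]
    )
    km_q = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed)
    km_q.fit(coords)
    if km_q.inertia_ < km.inertia_:
        km = km_q
    labels = km.labels_.copy()
    centroids = km.cluster_centers_.copy()

    limit = (1.0 + balance_tol) * (n / k)
    for _ in range(n * k):
        sizes = np.bincount(labels, minlength=k)
        over = np.flatnonzero(sizes > limit)
        if over.size == 0:
            break
        under = np.flatnonzero(sizes < n / k)
        if under.size == 0:
            break
        donor = int(over[np.argmax(sizes[over])])
        members = np.flatnonzero(labels == donor)
        # distance of each donor voxel to each under-full centroid
        d = np.linalg.norm(
            coords[members, None, :] - centroids[under][None, :, :], axis=2
        )
        flat = np.argmin(d, axis=None)
        vi, ci = np.unravel_index(flat, d.shape)
        labels[members[vi]] = int(under[ci])
        for c in (donor, int(under[ci])):
            labels_c = labels == c
            centroids[c] = coords[labels_c].mean(axis=0)
    return SubRegionAssignment(region=block.region, labels=labels + 1, k=k)


def subregion_timecourses(block: VoxelBlock, asg: SubRegionAssignment) -> np.ndarray:
    """(k x volumes) per-cluster voxel-mean series, mean-centered per cluster."""
    if asg.labels.shape[0] != block.n_voxels:
        raise ValueError("assignment does not match block")
    out = np.zeros((asg.k, block.series.shape[1]))
    for c in range(1, asg.k + 1):
        members = asg.labels == c
        mean = block.series[members].mean(axis=0)
        out[c - 1] = mean - mean.mean()
    return out


def block_to_frame(
    block: VoxelBlock,
    asg: SubRegionAssignment,
    participant: str = "sub-000",
    group: str = "NA",
    condition: str = "pain",
) -> pd.DataFrame:
    """Sub-region time-courses in the shared long-table dialect."""
    tc = subregion_timecourses(block, asg)
    vcols = [f"v{i + 1:03d}" for i in range(tc.shape[1])]
    rows = []
    for c in range(asg.k):
        row = {
            "participant": participant,
            "group": group,
            "condition": condition,
            "region": block.region,
            "subregion": c + 1,
        }
        row.update(dict(zip(vcols, tc[c])))
        rows.append(row)
    return pd.DataFrame(rows)
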