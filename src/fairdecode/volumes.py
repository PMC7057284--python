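"""Shared spatial operations on 3-D brain volumes.

Mask handling, connected-component labelling, Gaussian spatial smoothing and
searchlight sphere extraction.  All operations work in voxel space; physical
units enter only through the voxel size passed to :func:`gaussian_smooth`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "MaskVolume",
    "ClusterSet",
    "connected_components",
    "gaussian_smooth",
    "sphere_indices",
    "FWHM_TO_SIGMA",
]

# FWHM = 2 * sqrt(2 ln 2) * sigma for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class MaskVolume:
    """A binary 3-D mask with an optional name and voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    name: str = "mask"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.data.shape}")
        self.data = self.data.astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def indices(self) -> np.ndarray:
        """(n, 3) array of in-mask voxel indices in C order."""
        return np.argwhere(self.data)


@dataclass
class ClusterSet:
    """Connected components of a mask: an integer label volume plus summaries.

    Labels run contiguously from 1 (largest cluster) upward; 0 is background.
    """

    label_volume: np.ndarray
    sizes: np.ndarray
    peaks: np.ndarray  # (n_clusters, 3) representative voxel per cluster
    name: str = "clusters"

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume, dtype=int)
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.peaks = np.asarray(self.peaks, dtype=int).reshape(-1, 3)
        n = len(self.sizes)
        present = np.unique(self.label_volume)
        present = present[present > 0]
        if n and (present.min() < 1 or present.max() > n):
            raise ValueError("cluster labels must be contiguous from 1")

    def __len__(self) -> int:
        return len(self.sizes)

    def cluster_mask(self, label: int, affine: np.ndarray | None = None) -> MaskVolume:
        """Binary mask of a single cluster (labels start at 1)."""
        if not 1 <= label <= len(self):
            raise ValueError(f"no cluster with label {label}")
        aff = np.eye(4) if affine is None else affine
        return MaskVolume(self.label_volume == label, affine=aff,
                          name=f"{self.name}_{label:02d}")


def connected_components(
    mask: MaskVolume | np.ndarray,
    connectivity: int = 26,
    values: np.ndarray | None = None,
) -> ClusterSet:
    """Label maximal connected components of a binary mask.

    Parameters
    ----------
    mask : binary 3-D volume (or :class:`MaskVolume`)
    connectivity : 6 (faces), 18 (faces+edges) or 26 (faces+edges+corners)
    values : optional 3-D array; if given, each cluster's peak is its
        maximum-value voxel, otherwise the first in-cluster voxel in C order.

    Returns clusters sorted by size, descending; an empty mask yields an
    empty :class:`ClusterSet`.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6, 18, 26, got {connectivity}")
    name = mask.name if isinstance(mask, MaskVolume) else "clusters"
    data = mask.data if isinstance(mask, MaskVolume) else np.asarray(mask).astype(bool)
    if data.ndim != 3:
        raise ValueError("mask must be 3-D")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    raw_labels, n_raw = ndimage.label(data, structure=structure)
    if n_raw == 0:
        return ClusterSet(np.zeros(data.shape, dtype=int), np.zeros(0, dtype=int),
                          np.zeros((0, 3), dtype=int), name=name)
    raw_sizes = np.bincount(raw_labels.ravel())[1:]
    order = np.argsort(-raw_sizes, kind="stable")  # size-descending, stable ties
    relabel = np.zeros(n_raw + 1, dtype=int)
    relabel[order + 1] = np.arange(1, n_raw + 1)
    label_volume = relabel[raw_labels]
    sizes = raw_sizes[order]
    peaks = np.empty((n_raw, 3), dtype=int)
    for new_label in range(1, n_raw + 1):
        vox = np.argwhere(label_volume == new_label)
        if values is not None:
            vals = np.asarray(values)[tuple(vox.T)]
            peaks[new_label - 1] = vox[int(np.argmax(vals))]
        else:
            peaks[new_label - 1] = vox[0]
    return ClusterSet(label_volume, sizes, peaks, name=name)


def gaussian_smooth(
    volume: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: tuple[float, float, float] | np.ndarray = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Separable Gaussian smoothing of a 3-D volume.

    ``fwhm_mm`` is converted per axis to a sigma in voxel units via the
    header voxel size; ``fwhm_mm = 0`` is the identity.  Boundaries use
    half-sample symmetric reflection, which conserves the volume sum.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError("volume must be 3-D")
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return volume.copy()
    voxel_size = np.asarray(voxel_size_mm, dtype=float)
    if voxel_size.shape != (3,) or np.any(voxel_size <= 0):
        raise ValueError("voxel_size_mm must be 3 positive lengths")
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size
    return ndimage.gaussian_filter(volume, sigma=sigma_vox, mode="reflect")


def sphere_offsets(radius_voxels: float) -> np.ndarray:
    """Integer offsets (k, 3) within Euclidean distance ``radius`` of origin."""
    if radius_voxels < 0:
        raise ValueError("radius must be non-negative")
    r = int(np.floor(radius_voxels + 1e-9))
    grid = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(grid, grid, grid, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius_voxels**2 + 1e-9
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def sphere_indices(
    center: tuple[int, int, int] | np.ndarray,
    radius_voxels: float,
    mask: MaskVolume,
) -> np.ndarray:
    """In-mask voxel indices within ``radius_voxels`` of ``center``.

    Distances are Euclidean in voxel units; the center voxel is always
    included.  Raises if the center lies outside the mask.
    """
    center = np.asarray(center, dtype=int)
    if center.shape != (3,):
        raise ValueError("center must be a 3-D voxel index")
    shape = np.asarray(mask.data.shape)
    if np.any(center < 0) or np.any(center >= shape):
        raise ValueError(f"center {tuple(center)} outside volume of shape {tuple(shape)}")
    if not mask.data[tuple(center)]:
        raise ValueError(f"center {tuple(center)} is not inside the mask")
    pts = center[None, :] + sphere_offsets(radius_voxels)
    inside = np.all((pts >= 0) & (pts < shape[None, :]), axis=1)
    pts = pts[inside]
    in_mask = mask.data[pts[:, 0], pts[:, 1], pts[:, 2]]
    return pts[in_mask]
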