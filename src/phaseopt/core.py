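"""Volumetric domain types and binary-mask morphometrics.

Grids are plain numpy arrays indexed ``(i, j, k)``.  By convention axis 0 is
the patient left-right axis and axis 2 the cranio-caudal axis, but nothing in
this module depends on it; operations only use the per-axis physical spacing.
World coordinates are voxel centers: ``x = origin + index * spacing``.

Masks are strictly binary.  Anything arriving as a float or label grid is
thresholded at > 0.5 (see :func:`as_binary`), so masks stored as 0/255 or as
probabilities behave identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .errors import EmptyRoiError, GeometryError

__all__ = [
    "PhaseVolume",
    "RoiMaskSet",
    "PhaseSeries",
    "RoiMetrics",
    "ROI_NAMES",
    "as_binary",
    "mask_volume",
    "mask_centroid",
    "roi_metrics",
    "min_distance",
    "DistanceMode",
]

ROI_NAMES = ("gtv", "lung_left", "lung_right", "cord")

DistanceMode = Literal["min", "min_surface", "centroid_to_surface", "centroid_to_centroid"]


def as_binary(mask: np.ndarray) -> np.ndarray:
    """Return a boolean view of *mask*, thresholding non-boolean input at > 0.5."""
    if mask.dtype == bool:
        return mask
    return np.asarray(mask) > 0.5


def _check_spacing(spacing: Sequence[float]) -> np.ndarray:
    spacing = np.asarray(spacing, dtype=float)
    if spacing.ndim != 1 or np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise GeometryError(f"spacing components must be finite and > 0, got {spacing}")
    return spacing


@dataclass(frozen=True)
class PhaseVolume:
    """One 3D scalar grid (CT intensities) for a single respiratory phase.

    Parameters
    ----------
    phase_index
        Respiratory bin 0..9; bin *k* covers ``[10k, 10k+9]`` % of the cycle.
    values
        3D scalar grid (HU or arbitrary units).
    spacing
        Physical voxel size per axis, mm.
    origin
        World position of voxel (0, 0, 0), mm.
    """

    phase_index: int
    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 3 or min(values.shape) < 1:
            raise GeometryError(f"expected a 3D grid with >=1 voxel per axis, got shape {values.shape}")
        spacing = _check_spacing(self.spacing)
        if spacing.size != 3:
            raise GeometryError("spacing must have 3 components")
        origin = np.zeros(3) if self.origin is None else np.asarray(self.origin, dtype=float)
        if not 0 <= int(self.phase_index) <= 9:
            raise GeometryError(f"phase_index must be 0..9, got {self.phase_index}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass(frozen=True)
class RoiMaskSet:
    """The four delineated regions of interest on one phase's grid."""

    gtv: np.ndarray
    lung_left: np.ndarray
    lung_right: np.ndarray
    cord: np.ndarray

    def __post_init__(self):
        shape = None
        for name in ROI_NAMES:
            m = as_binary(np.asarray(getattr(self, name)))
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise GeometryError(f"ROI '{name}' shape {m.shape} differs from {shape}")
            object.__setattr__(self, name, m)

    @property
    def shape(self) -> tuple:
        return self.gtv.shape

    def lung(self, side: str) -> np.ndarray:
        if side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        return self.lung_left if side == "left" else self.lung_right


@dataclass(frozen=True)
class PhaseSeries:
    """Ordered collection of the ten (volume, mask set) pairs of a 4D-CT study.

    All grids must share shape, spacing and origin so that voxelwise
    operations (MIP, mask unions) are well defined.
    """

    phases: tuple

    def __post_init__(self):
        phases = tuple(self.phases)
        if len(phases) != 10:
            raise GeometryError(f"a phase series needs exactly 10 phases, got {len(phases)}")
        indices = [vol.phase_index for vol, _ in phases]
        if sorted(indices) != list(range(10)):
            raise GeometryError(f"phase indices must be 0..9 each once, got {indices}")
        ref_vol = phases[0][0]
        bad = []
        for vol, masks in phases:
            if (
                vol.shape != ref_vol.shape
                or not np.allclose(vol.spacing, ref_vol.spacing)
                or not np.allclose(vol.origin, ref_vol.origin)
                or masks.shape != vol.shape
            ):
                bad.append(vol.phase_index)
        if bad:
            raise GeometryError(f"phases {bad} do not share the series grid geometry")
        object.__setattr__(self, "phases", tuple(sorted(phases, key=lambda p: p[0].phase_index)))

    def __iter__(self):
        return iter(self.phases)

    def __getitem__(self, phase_index: int):
        return self.phases[phase_index]

    @property
    def spacing(self) -> np.ndarray:
        return self.phases[0][0].spacing

    @property
    def origin(self) -> np.ndarray:
        return self.phases[0][0].origin

    @property
    def shape(self) -> tuple:
        return self.phases[0][0].shape


@dataclass(frozen=True)
class RoiMetrics:
    """Morphometric summary of one ROI on one phase.

    ``defined`` is False for an empty mask, in which case centroid, inertia
    axes and densities are sentinel None values rather than silent NaNs.
    """

    volume_mm3: float
    surface_area_mm2: float
    centroid_mm: np.ndarray | None
    inertia_axes: np.ndarray | None       # columns are orthonormal axes
    inertia_eigenvalues: np.ndarray | None  # sorted descending, mm^2
    histogram_counts: np.ndarray | None
    histogram_edges: np.ndarray | None
    mean_density: float | None
    defined: bool = True


def mask_volume(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """Volume of a binary mask in mm^3: (true-voxel count) x (voxel volume)."""
    spacing = _check_spacing(spacing)
    mask = as_binary(np.asarray(mask))
    if mask.ndim != spacing.size:
        raise GeometryError(f"mask is {mask.ndim}D but spacing has {spacing.size} components")
    return float(np.count_nonzero(mask)) * float(np.prod(spacing))


def mask_centroid(mask: np.ndarray, spacing, origin=None) -> np.ndarray:
    """Centroid of foreground voxel centers in world mm; raises on empty mask."""
    mask = as_binary(np.asarray(mask))
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise EmptyRoiError("mask", "centroid undefined")
    spacing = _check_spacing(spacing)
    origin = np.zeros(mask.ndim) if origin is None else np.asarray(origin, dtype=float)
    return origin + idx.mean(axis=0) * spacing


def _surface_area(mask: np.ndarray, spacing: np.ndarray) -> float:
    # Exposed voxel faces: a face counts when its neighbour (or the grid
    # boundary) is background.  Face area along axis d is voxvol / spacing[d].
    voxvol = float(np.prod(spacing))
    total = 0.0
    for d in range(mask.ndim):
        face = voxvol / spacing[d]
        padded = np.pad(mask, [(1, 1) if a == d else (0, 0) for a in range(mask.ndim)])
        lo = [slice(None)] * mask.ndim
        hi = [slice(None)] * mask.ndim
        lo[d] = slice(0, -2)
        hi[d] = slice(2, None)
        exposed = np.count_nonzero(mask & ~padded[tuple(lo)]) + np.count_nonzero(mask & ~padded[tuple(hi)])
        total += exposed * face
    return total


def roi_metrics(image: PhaseVolume, mask: np.ndarray, histogram_bins: int = 64) -> RoiMetrics:
    """Compute volume, surface area, centroid, inertia axes and the density
    histogram of *mask* on *image*.

    The inertia axes are the eigenvectors of the covariance matrix of the
    foreground voxel centers (world mm); eigenvalues are returned in
    descending order.  An empty mask yields ``defined=False`` with zero
    volume/surface and None for every shape descriptor.
    """
    mask = as_binary(np.asarray(mask))
    if mask.shape != image.shape:
        raise GeometryError(f"mask shape {mask.shape} does not match image shape {image.shape}")
    spacing = image.spacing
    n = int(np.count_nonzero(mask))
    if n == 0:
        return RoiMetrics(0.0, 0.0, None, None, None, None, None, None, defined=False)

    volume = n * float(np.prod(spacing))
    surface = _surface_area(mask, spacing)
    coords = np.argwhere(mask) * spacing + image.origin
    centroid = coords.mean(axis=0)
    cov = np.cov(coords.T, bias=True) if n > 1 else np.zeros((3, 3))
    cov = np.atleast_2d(cov)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    inside = np.asarray(image.values)[mask]
    counts, edges = np.histogram(inside, bins=histogram_bins)
    return RoiMetrics(
        volume_mm3=volume,
        surface_area_mm2=surface,
        centroid_mm=centroid,
        inertia_axes=eigvecs,
        inertia_eigenvalues=eigvals,
        histogram_counts=counts,
        histogram_edges=edges,
        mean_density=float(inside.mean()),
        defined=True,
    )


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(mask.ndim, 1))
    return mask & ~eroded


def min_distance(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    spacing,
    mode: DistanceMode = "min",
    name_a: str = "mask_a",
    name_b: str = "mask_b",
    origin=None,
) -> float:
    """Distance in mm between two binary masks on the same grid.

    Modes
    -----
    ``min`` (default)
        Minimum Euclidean distance between any foreground voxel center of
        *mask_a* and any of *mask_b* (0 if the masks overlap).  Computed with
        an exact Euclidean distance transform of *mask_b* sampled at the
        foreground of *mask_a*; identical to the brute-force all-pairs
        minimum.
    ``min_surface``
        Same, restricted to boundary voxels of both masks.
    ``centroid_to_surface``
        Distance from the centroid of *mask_a* to the nearest voxel center of
        *mask_b*.
    ``centroid_to_centroid``
        Distance between the two centroids.

    Anisotropic spacing is respected in every mode.
    """
    spacing = _check_spacing(spacing)
    a = as_binary(np.asarray(mask_a))
    b = as_binary(np.asarray(mask_b))
    if a.shape != b.shape:
        raise GeometryError(f"masks have different shapes {a.shape} vs {b.shape}")
    if not a.any():
        raise EmptyRoiError(name_a, "distance undefined")
    if not b.any():
        raise EmptyRoiError(name_b, "distance undefined")

    if mode == "centroid_to_centroid":
        ca = mask_centroid(a, spacing, origin)
        cb = mask_centroid(b, spacing, origin)
        return float(np.linalg.norm(ca - cb))
    if mode == "centroid_to_surface":
        ca = mask_centroid(a, spacing, origin)
        origin_arr = np.zeros(a.ndim) if origin is None else np.asarray(origin, dtype=float)
        coords_b = np.argwhere(b) * spacing + origin_arr
        return float(np.min(np.linalg.norm(coords_b - ca, axis=1)))
    if mode == "min_surface":
        a, b = _boundary(a), _boundary(b)
    elif mode != "min":
        raise ValueError(f"unknown distance mode {mode!r}")

    # Exact EDT of the complement of b gives, at each voxel center, the
    # distance to the nearest foreground voxel center of b.
    dt = ndimage.distance_transform_edt(~b, sampling=spacing)
    return float(dt[a].min())
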