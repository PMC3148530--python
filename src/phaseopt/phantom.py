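"""Synthetic 4D breathing-thorax phantom with closed-form ground truth.

The phantom stands in for clinical 4D-CT data (none is publicly deposited
for this kind of study): two ellipsoidal lungs whose volume swells with
inspiration, a cylindrical spinal cord running cranio-caudally, and an
ellipsoidal tumor inside one lung that translates cranio-caudally (and
optionally antero-posteriorly, toward the cord) over the breathing cycle.

Geometry conventions match :mod:`phaseopt.core`: axis 0 is left-right,
axis 1 antero-posterior (cord posterior, at high axis-1 coordinates),
axis 2 cranio-caudal.

Motion model
------------
Displacement follows a raised-cosine over the ten phases,

    s(k) = (1 - cos(2*pi*(k - offset)/10)) / 2,

so the tumor rests at its baseline position at the cycle ends and reaches
peak displacement half a cycle after ``motion_phase_offset``.  The lung
volume scale is ``1 + expansion_fraction * (1 + cos(2*pi*(k - p)/10)) / 2``
with ``p = inspiration_phase``, i.e. maximal at the configured inspiration
phase.  Defaults reflect clinically reported motion: 12 mm cranio-caudal
amplitude, typical of lower-lobe tumors.

Every analytic quantity the image pipeline should recover (tumor volume,
per-phase lung volume, tumor-center-to-cord-axis distance and the implied
surface-to-surface clearance) is returned as :class:`GroundTruth`, and
:func:`expected_table` renders it as the closed-form counterpart of the
pipeline's per-phase parameter table.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

from .core import PhaseSeries, PhaseVolume, RoiMaskSet
from .errors import PhantomConfigError
from .parameters import PhaseParameterTable

__all__ = ["PhantomConfig", "GroundTruth", "generate", "expected_table"]

N_PHASES = 10

# CT-like intensities, HU
HU_BODY = 40.0
HU_LUNG = -750.0
HU_TUMOR = 30.0
HU_CORD = 20.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, motion and noise of the synthetic thorax.

    All lengths are mm; centers are world coordinates (origin at 0).
    The tumor's left-right and antero-posterior semi-axes must be equal so
    that the clearance to the (vertical) cord cylinder has the exact closed
    form ``d_axis - tumor_semi_axis_lr - cord_radius``.
    """

    shape: tuple = (128, 128, 128)
    spacing: tuple = (2.0, 2.0, 2.0)
    # lungs: ellipsoids mirrored about the mid-sagittal plane
    lung_semi_axes: tuple = (45.0, 60.0, 85.0)
    lung_center_right: tuple = (68.0, 128.0, 120.0)
    lung_center_left: tuple = (188.0, 128.0, 120.0)
    expansion_fraction: float = 0.15
    inspiration_phase: int = 0
    # spinal cord: cylinder along the cranio-caudal axis
    cord_radius: float = 6.0
    cord_center: tuple = (128.0, 196.0)  # (left-right, antero-posterior)
    # tumor: ellipsoid inside the right lung
    tumor_semi_axes: tuple = (10.0, 10.0, 14.0)
    tumor_center: tuple = (70.0, 160.0, 110.0)
    amplitude_mm: float = 12.0            # cranio-caudal, caudal at peak
    ap_amplitude_mm: float = 0.0          # antero-posterior, toward the cord
    motion_phase_offset: int = 0
    noise_sigma: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or min(self.shape) < 8:
            raise PhantomConfigError(f"shape must be 3D with >=8 voxels per axis, got {self.shape}")
        if min(self.spacing) <= 0:
            raise PhantomConfigError("spacing components must be > 0")
        if self.amplitude_mm < 0 or self.ap_amplitude_mm < 0:
            raise PhantomConfigError("motion amplitudes must be >= 0")
        if not np.isclose(self.tumor_semi_axes[0], self.tumor_semi_axes[1]):
            raise PhantomConfigError(
                "tumor left-right and antero-posterior semi-axes must be equal "
                "(required for the closed-form cord clearance)"
            )
        if not 0 <= self.inspiration_phase <= 9:
            raise PhantomConfigError("inspiration_phase must be 0..9")


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form per-phase quantities implied by a :class:`PhantomConfig`."""

    tumor_volume_mm3: float
    lung_volume_mm3: np.ndarray          # shape (10,), ipsilateral
    tumor_center_mm: np.ndarray          # shape (10, 3)
    center_to_cord_axis_mm: np.ndarray   # shape (10,)
    surface_clearance_mm: np.ndarray     # shape (10,): axis dist - a_lr - r_cord
    reference_phase: int
    laterality: str


def _displacement_schedule(cfg: PhantomConfig) -> np.ndarray:
    k = np.arange(N_PHASES)
    return (1.0 - np.cos(2.0 * np.pi * (k - cfg.motion_phase_offset) / N_PHASES)) / 2.0


def _lung_scale(cfg: PhantomConfig) -> np.ndarray:
    k = np.arange(N_PHASES)
    return 1.0 + cfg.expansion_fraction * (
        1.0 + np.cos(2.0 * np.pi * (k - cfg.inspiration_phase) / N_PHASES)
    ) / 2.0


def ground_truth(cfg: PhantomConfig) -> GroundTruth:
    """Evaluate every closed form of the phantom without voxelizing it."""
    a, b, c = cfg.tumor_semi_axes
    tumor_vol = 4.0 / 3.0 * np.pi * a * b * c
    la, lb, lc = cfg.lung_semi_axes
    lung_base = 4.0 / 3.0 * np.pi * la * lb * lc
    lung_vol = lung_base * _lung_scale(cfg)  # semi-axes scale by v^(1/3)

    s = _displacement_schedule(cfg)
    centers = np.tile(np.asarray(cfg.tumor_center, float), (N_PHASES, 1))
    centers[:, 2] -= cfg.amplitude_mm * s
    # antero-posterior motion moves the tumor toward the cord
    ap_sign = np.sign(cfg.cord_center[1] - cfg.tumor_center[1]) or 1.0
    centers[:, 1] += ap_sign * cfg.ap_amplitude_mm * s

    d_axis = np.hypot(centers[:, 0] - cfg.cord_center[0], centers[:, 1] - cfg.cord_center[1])
    clearance = d_axis - a - cfg.cord_radius

    lat = "right" if (
        abs(cfg.tumor_center[0] - cfg.lung_center_right[0])
        < abs(cfg.tumor_center[0] - cfg.lung_center_left[0])
    ) else "left"
    return GroundTruth(
        tumor_volume_mm3=tumor_vol,
        lung_volume_mm3=lung_vol,
        tumor_center_mm=centers,
        center_to_cord_axis_mm=d_axis,
        surface_clearance_mm=clearance,
        reference_phase=cfg.inspiration_phase,
        laterality=lat,
    )


def _grid_coords(cfg: PhantomConfig):
    sp = np.asarray(cfg.spacing, float)
    axes = [np.arange(n) * s for n, s in zip(cfg.shape, sp)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid(coords, center, semi_axes) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - center[0]) / semi_axes[0]) ** 2
        + ((y - center[1]) / semi_axes[1]) ** 2
        + ((z - center[2]) / semi_axes[2]) ** 2
    ) <= 1.0


def _cylinder(coords, center_xy, radius) -> np.ndarray:
    x, y, z = coords
    in_plane = (x - center_xy[0]) ** 2 + (y - center_xy[1]) ** 2 <= radius**2
    return in_plane & np.ones_like(z, dtype=bool)


def generate(cfg: PhantomConfig) -> tuple[PhaseSeries, GroundTruth]:
    """Voxelize the ten phases of the phantom.

    Masks are exact voxelizations (voxel center inside the analytic shape)
    and noise-free; Gaussian noise of ``noise_sigma`` HU is added to the
    intensity volumes only, from a generator seeded by ``cfg.seed``.  The
    tumor mask must remain inside the ipsilateral lung mask on every phase;
    a phase where it escapes (or leaves the grid) raises
    :class:`PhantomConfigError` naming the phase.
    """
    gt = ground_truth(cfg)
    coords = _grid_coords(cfg)
    scale = _lung_scale(cfg) ** (1.0 / 3.0)
    rng = np.random.default_rng(cfg.seed)
    extent = np.asarray(cfg.shape) * np.asarray(cfg.spacing)

    cord = _cylinder(coords, cfg.cord_center, cfg.cord_radius)
    phases = []
    bad = []
    for k in range(N_PHASES):
        semi = np.asarray(cfg.lung_semi_axes) * scale[k]
        lung_r = _ellipsoid(coords, cfg.lung_center_right, semi)
        lung_l = _ellipsoid(coords, cfg.lung_center_left, semi)
        center = gt.tumor_center_mm[k]
        if np.any(center - cfg.tumor_semi_axes < 0) or np.any(center + cfg.tumor_semi_axes > extent):
            bad.append(k)
            continue
        tumor = _ellipsoid(coords, center, cfg.tumor_semi_axes)
        ipsi = lung_r if gt.laterality == "right" else lung_l
        if np.any(tumor & ~ipsi):
            bad.append(k)
            continue

        values = np.full(cfg.shape, HU_BODY, dtype=np.float32)
        values[lung_r | lung_l] = HU_LUNG
        values[cord] = HU_CORD
        values[tumor] = HU_TUMOR
        if cfg.noise_sigma > 0:
            values += rng.normal(0.0, cfg.noise_sigma, size=cfg.shape).astype(np.float32)

        vol = PhaseVolume(phase_index=k, values=values, spacing=np.asarray(cfg.spacing, float))
        masks = RoiMaskSet(gtv=tumor, lung_left=lung_l, lung_right=lung_r, cord=cord)
        phases.append((vol, masks))
    if bad:
        raise PhantomConfigError(
            f"tumor leaves the grid or the ipsilateral lung at phases {bad}"
        )
    return PhaseSeries(tuple(phases)), gt


def expected_table(cfg: PhantomConfig) -> PhaseParameterTable:
    """Closed-form counterpart of the image pipeline's per-phase table.

    ``tl_ratio`` uses the analytic ellipsoid volumes; ``tc_dist_mm`` is the
    closed-form surface clearance matching the pipeline's default minimum-
    distance convention.
    """
    import pandas as pd

    gt = ground_truth(cfg)
    df = pd.DataFrame(
        {
            "tl_ratio": 100.0 * gt.tumor_volume_mm3 / gt.lung_volume_mm3,
            "tc_dist_mm": np.maximum(gt.surface_clearance_mm, 0.0),
            "ipsi_lung_volume_mm3": gt.lung_volume_mm3,
        },
        index=pd.Index(range(N_PHASES), name="phase_index"),
    )
    return PhaseParameterTable(
        df,
        laterality=gt.laterality,
        reference_phase=gt.reference_phase,
        patient_id="phantom",
    )
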