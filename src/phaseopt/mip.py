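"""Maximum-intensity projection across the ten respiratory phases.

The MIP composite takes, for every voxel, the maximum CT value over the ten
phase volumes.  It is a visualization / internal-target-volume product: the
phase optimizer itself works on per-phase masks, but the MIP is part of the
standard 4D-CT reporting output, together with the union ("envelope") mask of
a moving ROI which summarizes its motion extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PhaseSeries, ROI_NAMES
from .errors import GeometryError

__all__ = ["MipVolume", "build_mip", "union_mask"]


@dataclass(frozen=True)
class MipVolume:
    """Voxelwise maximum over the ten phases, on the shared series grid."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray


def build_mip(series: PhaseSeries) -> MipVolume:
    """Voxelwise maximum of the ten phase volumes.

    Grid consistency is enforced by :class:`PhaseSeries`; the result has the
    series' shape, spacing and origin and every voxel is >= the corresponding
    voxel of every phase.
    """
    stack = [vol.values for vol, _ in series]
    return MipVolume(
        values=np.maximum.reduce(stack),
        spacing=series.spacing,
        origin=series.origin,
    )


def union_mask(series: PhaseSeries, roi: str) -> np.ndarray:
    """Voxelwise OR of one ROI's mask across all ten phases.

    For a moving ROI this is the internal-target-volume-style envelope; its
    bounding box relative to a single phase reflects the motion amplitude.
    """
    if roi not in ROI_NAMES:
        raise GeometryError(f"unknown ROI {roi!r}; expected one of {ROI_NAMES}")
    out = np.zeros(series.shape, dtype=bool)
    for _, masks in series:
        out |= getattr(masks, roi)
    return out
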