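"""Per-phase comparison parameters for respiratory-phase optimization.

For each of the ten respiratory phases the pipeline computes:

* ``tl_ratio`` — tumor-to-ipsilateral-lung volume ratio on the percent scale,
  ``100 * V(GTV) / V(ipsilateral lung)``; smaller is better (a small ratio
  means a large healthy-lung reservoir relative to the target).
* ``tc_dist_mm`` — tumor-to-spinal-cord distance in mm; larger is better
  (cord dose constraints have the highest planning priority).
* ``ipsi_lung_volume_mm3`` — absolute ipsilateral lung volume, the
  inspiration surrogate used to locate the reference phase (maximal
  inspiration = maximal ipsilateral lung volume).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DistanceMode,
    PhaseSeries,
    RoiMaskSet,
    mask_centroid,
    mask_volume,
    min_distance,
)
from .errors import EmptyRoiError, GainError, LateralityError, ValidationError

__all__ = [
    "PhaseParameterTable",
    "detect_laterality",
    "tl_ratio",
    "compute_phase_table",
    "identify_reference",
]

log = logging.getLogger(__name__)

COLUMNS = ("tl_ratio", "tc_dist_mm", "ipsi_lung_volume_mm3")


@dataclass
class PhaseParameterTable:
    """The two comparison parameters (plus lung volume) for phases 0..9.

    ``data`` is a DataFrame indexed by phase_index 0..9 with columns
    ``tl_ratio``, ``tc_dist_mm``, ``ipsi_lung_volume_mm3`` (the last may be
    NaN in table mode).  ``reference_phase`` is None until identified or
    supplied.
    """

    data: pd.DataFrame
    laterality: str | None = None
    reference_phase: int | None = None
    patient_id: str = ""
    flags: list = field(default_factory=list)

    def __post_init__(self):
        df = self.data.copy()
        missing = [c for c in ("tl_ratio", "tc_dist_mm") if c not in df.columns]
        if missing:
            raise ValidationError([f"missing column {c}" for c in missing])
        if "ipsi_lung_volume_mm3" not in df.columns:
            df["ipsi_lung_volume_mm3"] = np.nan
        df = df[list(COLUMNS)]
        df.index = df.index.astype(int)
        df = df.sort_index()
        if list(df.index) != list(range(10)):
            raise ValidationError(
                [f"expected phase indices 0..9 exactly once, got {list(df.index)}"]
            )
        if (df["tl_ratio"] < 0).any() or (df["tc_dist_mm"] < 0).any():
            raise ValidationError(["tl_ratio and tc_dist_mm must be >= 0"])
        df.index.name = "phase_index"
        self.data = df
        if self.reference_phase is not None:
            self.reference_phase = int(self.reference_phase)
            if not 0 <= self.reference_phase <= 9:
                raise ValidationError([f"reference_phase {self.reference_phase} not in 0..9"])

    @property
    def tl_values(self) -> np.ndarray:
        return self.data["tl_ratio"].to_numpy(dtype=float)

    @property
    def tc_values(self) -> np.ndarray:
        return self.data["tc_dist_mm"].to_numpy(dtype=float)

    @property
    def lung_volumes(self) -> np.ndarray:
        return self.data["ipsi_lung_volume_mm3"].to_numpy(dtype=float)


def detect_laterality(masks: RoiMaskSet, spacing, lr_axis: int = 0) -> str:
    """Return 'left' or 'right': the lung whose centroid is nearer the GTV
    centroid along the left-right axis.

    Works regardless of whether the axis increases toward the patient's left
    or right.  Raises :class:`LateralityError` on an exact tie or when both
    lung masks are empty, prompting an explicit override.
    """
    if not masks.gtv.any():
        raise EmptyRoiError("gtv", "laterality undefined")
    if not masks.lung_left.any() and not masks.lung_right.any():
        raise LateralityError("both lung masks are empty; set laterality explicitly")
    gtv_c = mask_centroid(masks.gtv, spacing)[lr_axis]
    dists = {}
    for side in ("left", "right"):
        lung = masks.lung(side)
        if lung.any():
            dists[side] = abs(mask_centroid(lung, spacing)[lr_axis] - gtv_c)
    if len(dists) == 1:
        return next(iter(dists))
    if np.isclose(dists["left"], dists["right"]):
        raise LateralityError(
            "GTV centroid equidistant from both lung centroids; set laterality explicitly"
        )
    return min(dists, key=dists.get)


def tl_ratio(gtv_vol: float, ipsi_lung_vol: float, phase_index: int | None = None) -> float:
    """Tumor-to-ipsilateral-lung volume ratio, percent scale."""
    if ipsi_lung_vol <= 0:
        where = "" if phase_index is None else f" at phase {phase_index}"
        raise GainError(f"ipsilateral lung volume is {ipsi_lung_vol}{where}; ratio undefined")
    return 100.0 * gtv_vol / ipsi_lung_vol


def identify_reference(table: PhaseParameterTable) -> int:
    """Phase of maximal ipsilateral lung volume (= maximal inspiration).

    Ties break to the lowest phase index.  In table mode without a lung
    volume column the reference cannot be derived and must be supplied.
    """
    vols = table.lung_volumes
    if np.isnan(vols).any():
        raise ValidationError(
            ["lung volumes unavailable; supply reference_phase explicitly"]
        )
    return int(np.argmax(vols))  # argmax takes the first maximum


def compute_phase_table(
    series: PhaseSeries,
    distance_mode: DistanceMode = "min",
    laterality: str | None = None,
    reference_phase: int | None = None,
    lr_axis: int = 0,
    patient_id: str = "",
) -> PhaseParameterTable:
    """Compute both comparison parameters and the lung volume for every phase.

    Validation problems (empty GTV/cord/lung on any phase) are collected
    across all phases and raised together as one :class:`ValidationError`.
    """
    spacing = series.spacing
    first_masks = series[0][1]
    if laterality is None:
        laterality = detect_laterality(first_masks, spacing, lr_axis=lr_axis)
    elif laterality not in ("left", "right"):
        raise LateralityError(f"laterality must be 'left' or 'right', got {laterality!r}")

    problems = []
    rows = {}
    for vol, masks in series:
        k = vol.phase_index
        lung = masks.lung(laterality)
        for name, m in (("gtv", masks.gtv), ("cord", masks.cord), (f"lung_{laterality}", lung)):
            if not m.any():
                problems.append(f"phase {k}: ROI '{name}' is empty")
        if problems and problems[-1].startswith(f"phase {k}"):
            continue
        gtv_vol = mask_volume(masks.gtv, spacing)
        lung_vol = mask_volume(lung, spacing)
        dist = min_distance(
            masks.gtv, masks.cord, spacing, mode=distance_mode,
            name_a="gtv", name_b="cord", origin=vol.origin,
        )
        ratio = tl_ratio(gtv_vol, lung_vol, phase_index=k)
        rows[k] = (ratio, dist, lung_vol)
        log.info(
            "phase %d: gtv=%.1f mm3 lung_%s=%.1f mm3 T/L=%.4f T-C=%.2f mm",
            k, gtv_vol, laterality, lung_vol, ratio, dist,
        )
    if problems:
        raise ValidationError(problems)

    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(COLUMNS))
    table = PhaseParameterTable(df, laterality=laterality, patient_id=patient_id)
    table.reference_phase = (
        int(reference_phase) if reference_phase is not None else identify_reference(table)
    )
    return table
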