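"""Readers and writers: NIfTI phase series, parameter CSVs, run outputs.

Image-mode directories follow the naming convention
``phase{k}_{image|gtv|lung_l|lung_r|cord}.nii.gz`` for k = 0..9 (plain
``.nii`` is also accepted).  Table mode uses a long-format CSV with columns
``patient_id, phase_index, tl_ratio, tc_dist_mm`` and optionally
``ipsi_lung_volume_mm3`` and ``reference_phase`` — exactly sufficient to
encode a published per-phase parameter table.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import PhaseSeries, PhaseVolume, RoiMaskSet
from .errors import GeometryError, ValidationError
from .parameters import PhaseParameterTable

__all__ = [
    "read_series",
    "write_series",
    "read_parameter_csv",
    "write_parameter_csv",
    "write_mip",
    "write_outputs",
]

log = logging.getLogger(__name__)

ROI_FILES = {"gtv": "gtv", "lung_left": "lung_l", "lung_right": "lung_r", "cord": "cord"}


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _save_nifti(path: Path, values: np.ndarray, spacing, origin) -> None:
    img = nib.Nifti1Image(np.asarray(values), _affine(spacing, origin))
    nib.save(img, str(path))


def _load_nifti(path: Path):
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise GeometryError(f"{path.name}: only axis-aligned (diagonal) affines are supported")
    spacing = np.abs(np.diag(aff[:3, :3]))
    return np.asarray(img.get_fdata()), spacing, aff[:3, 3].copy()


def _find(directory: Path, stem: str) -> Path | None:
    for suffix in (".nii.gz", ".nii"):
        p = directory / f"{stem}{suffix}"
        if p.exists():
            return p
    return None


def write_series(series: PhaseSeries, out_dir) -> Path:
    """Write a phase series as NIfTI volumes under the naming convention.

    Masks are written as uint8 0/1 volumes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for vol, masks in series:
        k = vol.phase_index
        _save_nifti(out / f"phase{k}_image.nii.gz", vol.values, vol.spacing, vol.origin)
        for roi, fname in ROI_FILES.items():
            _save_nifti(
                out / f"phase{k}_{fname}.nii.gz",
                getattr(masks, roi).astype(np.uint8),
                vol.spacing,
                vol.origin,
            )
    return out


def read_series(directory) -> PhaseSeries:
    """Read and validate a ten-phase series from a directory.

    Missing phases or ROI files are collected and reported together; mask
    volumes containing values other than 0/1 (e.g. 0/255 exports) are
    thresholded at > 0.5 with a logged warning.
    """
    directory = Path(directory)
    problems = []
    phases = []
    for k in range(10):
        image_path = _find(directory, f"phase{k}_image")
        roi_paths = {roi: _find(directory, f"phase{k}_{fn}") for roi, fn in ROI_FILES.items()}
        missing = [f"phase{k}_image"] if image_path is None else []
        missing += [f"phase{k}_{ROI_FILES[r]}" for r, p in roi_paths.items() if p is None]
        if missing:
            problems.append(f"missing files: {', '.join(missing)}")
            continue
        values, spacing, origin = _load_nifti(image_path)
        masks = {}
        for roi, path in roi_paths.items():
            data, m_spacing, m_origin = _load_nifti(path)
            if data.shape != values.shape:
                problems.append(
                    f"{path.name}: shape {data.shape} differs from image {values.shape}"
                )
                continue
            if not np.allclose(m_spacing, spacing) or not np.allclose(m_origin, origin):
                problems.append(f"{path.name}: spacing/origin differ from the phase image")
                continue
            unique = np.unique(data)
            if not np.all(np.isin(unique, (0.0, 1.0))):
                log.warning(
                    "%s: non-binary mask values %s; thresholding at > 0.5",
                    path.name, unique[:5],
                )
            masks[roi] = data > 0.5
        if len(masks) == 4:
            vol = PhaseVolume(phase_index=k, values=values, spacing=spacing, origin=origin)
            if masks["cord"].any() and ((masks["lung_left"] | masks["lung_right"]) & masks["cord"]).any():
                warnings.warn(f"phase {k}: lung and cord masks overlap", stacklevel=2)
            phases.append((vol, RoiMaskSet(**masks)))
    if problems:
        raise ValidationError(problems)
    return PhaseSeries(tuple(phases))


def write_mip(mip, out_dir, name: str = "mip.nii.gz") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / name
    _save_nifti(path, mip.values, mip.spacing, mip.origin)
    return path


CSV_REQUIRED = ("patient_id", "phase_index", "tl_ratio", "tc_dist_mm")


def read_parameter_csv(path) -> list[tuple]:
    """Parse a long-format parameter CSV into per-patient tables.

    Returns ``[(patient_id, PhaseParameterTable), ...]`` in file order.
    Every patient needs exactly ten phases; non-numeric cells are reported
    with their row and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError([f"{path}: file is empty"]) from None
    missing = [c for c in CSV_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError([f"{path}: missing columns {missing}"])

    problems = []
    numeric_cols = [c for c in df.columns if c != "patient_id"]
    required_numeric = set(CSV_REQUIRED) - {"patient_id"}
    for col in numeric_cols:
        raw = df[col].str.strip()
        converted = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = converted.isna() & ((raw != "") if col not in required_numeric else True)
        for row in df.index[bad]:
            problems.append(f"row {row + 2}, column '{col}': non-numeric value {df.at[row, col]!r}")
        df[col] = converted
    if problems:
        raise ValidationError(problems)

    out = []
    for pid, group in df.groupby("patient_id", sort=False):
        if len(group) != 10 or sorted(group["phase_index"].astype(int)) != list(range(10)):
            problems.append(
                f"patient {pid}: expected phases 0..9 exactly once, got "
                f"{sorted(group['phase_index'].tolist())}"
            )
            continue
        group = group.set_index(group["phase_index"].astype(int)).sort_index()
        data = {
            "tl_ratio": group["tl_ratio"],
            "tc_dist_mm": group["tc_dist_mm"],
        }
        if "ipsi_lung_volume_mm3" in group:
            data["ipsi_lung_volume_mm3"] = group["ipsi_lung_volume_mm3"]
        ref = None
        if "reference_phase" in group and group["reference_phase"].notna().all():
            refs = set(group["reference_phase"].astype(int))
            if len(refs) != 1:
                problems.append(f"patient {pid}: inconsistent reference_phase values {refs}")
                continue
            ref = refs.pop()
        out.append((pid, PhaseParameterTable(pd.DataFrame(data), reference_phase=ref, patient_id=pid)))
    if problems:
        raise ValidationError(problems)
    return out


def write_parameter_csv(tables, path) -> Path:
    """Inverse of :func:`read_parameter_csv` (long format, one row per phase)."""
    frames = []
    for table in tables:
        df = table.data.reset_index()
        df.insert(0, "patient_id", table.patient_id)
        if table.reference_phase is not None:
            df["reference_phase"] = table.reference_phase
        frames.append(df)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def write_outputs(tables, results, out_dir, summary=None, mip=None, make_charts=True) -> dict:
    """Write the complete run output: JSON report, CSVs, charts, optional MIP."""
    from .optimize import render_report

    out = Path(out_dir)
    report = render_report(tables, results, out, summary=summary, make_charts=make_charts)
    write_parameter_csv(tables, out / "phase_tables.csv")
    if mip is not None:
        write_mip(mip, out)
    return report
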