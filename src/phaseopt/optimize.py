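"""Decision core: optimal-phase selection, gain percentages, cutoff
classification and cohort summaries.

For each comparison parameter the ten per-phase values are reduced to an
optimal phase (argmin for the tumor/lung ratio, argmax for the tumor-cord
distance; ties break to the lowest phase index), a worst phase (the opposite
extreme), and two relative gains::

    gain_vs_ref   = 100 * |v_ref  - v_opt| / v_ref
    gain_vs_worst = 100 * |v_worst - v_opt| / v_worst

i.e. the denominator is always the value being improved upon.  A patient
benefits from gating when any of the four gains exceeds the cutoff (20% by
default); otherwise gating offers no advantage over treating at the
reference phase (maximal inspiration).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import GainError, PhaseOptError

__all__ = [
    "GainResult",
    "PatientClassification",
    "PatientResult",
    "CohortSummary",
    "gain",
    "classify",
    "summarize",
    "render_report",
    "round_half_away",
    "format_ratio",
]

Parameter = Literal["TL", "TC"]

LABELS = ("no_benefit", "max_inspiration_optimal", "other_phase_optimal", "inconclusive")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (display rule)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def format_ratio(x: float) -> str:
    """Table display precision: two significant figures below 1, one decimal above."""
    if x < 1.0:
        return f"{float(f'{x:.2g}'):g}"
    return f"{x:.1f}"


@dataclass(frozen=True)
class GainResult:
    """Gain analysis of one parameter's ten per-phase values."""

    parameter: Parameter
    values: tuple
    optimal_phase: int
    reference_phase: int
    worst_phase: int
    gain_vs_ref_pct: float
    gain_vs_worst_pct: float
    opt_equals_ref: bool

    @property
    def optimal_value(self) -> float:
        return self.values[self.optimal_phase]


@dataclass(frozen=True)
class PatientClassification:
    label: str
    driving_parameter: str  # "TL", "TC" or "none"
    notes: str = ""


@dataclass(frozen=True)
class PatientResult:
    """Everything the optimizer decided for one patient."""

    patient_id: str
    tl: GainResult
    tc: GainResult
    classification: PatientClassification


@dataclass(frozen=True)
class CohortSummary:
    """Mean / population SD / range of each gain column plus label counts."""

    stats: dict           # {"TL": {"vs_ref": {...}, "vs_worst": {...}}, "TC": ...}
    label_counts: dict    # label -> number of patients
    n_patients: int


def gain(parameter: Parameter, values: Sequence[float], reference_phase: int) -> GainResult:
    """Gain analysis for one parameter.

    The tumor/lung ratio ("TL") is minimized, the tumor-cord distance
    ("TC") maximized.  Both the gain versus the reference phase and versus
    the worst phase are always computed.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (10,):
        raise GainError(f"expected 10 per-phase values, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise GainError("non-finite per-phase value")
    if not 0 <= int(reference_phase) <= 9:
        raise GainError(f"reference phase {reference_phase} not in 0..9")
    reference_phase = int(reference_phase)

    if parameter == "TL":
        opt = int(np.argmin(v))   # first occurrence = lowest phase on ties
        worst = int(np.argmax(v))
    elif parameter == "TC":
        opt = int(np.argmax(v))
        worst = int(np.argmin(v))
    else:
        raise GainError(f"unknown parameter {parameter!r}")

    def _rel_gain(baseline: float) -> float:
        if baseline == 0:
            raise GainError(f"{parameter} baseline value is 0; gain undefined")
        return 100.0 * abs(baseline - v[opt]) / baseline

    return GainResult(
        parameter=parameter,
        values=tuple(v),
        optimal_phase=opt,
        reference_phase=reference_phase,
        worst_phase=worst,
        gain_vs_ref_pct=_rel_gain(v[reference_phase]),
        gain_vs_worst_pct=_rel_gain(v[worst]),
        opt_equals_ref=bool(v[opt] == v[reference_phase]),
    )


def classify(
    tl: GainResult,
    tc: GainResult,
    cutoff_pct: float = 20.0,
    strict_concordance: bool = False,
) -> PatientClassification:
    """Apply the no-gain cutoff and label the patient.

    * ``no_benefit`` — none of the four gains exceeds the cutoff.
    * otherwise the driving parameter is the one with a gain above the
      cutoff, the tumor/lung ratio taking precedence when both qualify;
      the label is ``max_inspiration_optimal`` if that parameter's optimal
      phase is the reference phase, ``other_phase_optimal`` otherwise.
    * ``inconclusive`` (only with ``strict_concordance``) — both parameters
      exceed the cutoff but point at optima that disagree by more than one
      phase, neither being the reference.
    """
    if tl.reference_phase != tc.reference_phase:
        raise PhaseOptError(
            f"mismatched reference phases: TL {tl.reference_phase} vs TC {tc.reference_phase}"
        )
    gains = {
        "TL": (tl.gain_vs_ref_pct, tl.gain_vs_worst_pct),
        "TC": (tc.gain_vs_ref_pct, tc.gain_vs_worst_pct),
    }
    exceeds = {p: max(g) > cutoff_pct for p, g in gains.items()}
    if not any(exceeds.values()):
        return PatientClassification("no_benefit", "none",
                                     f"all gains <= {cutoff_pct:g}% cutoff")

    if (
        strict_concordance
        and exceeds["TL"]
        and exceeds["TC"]
        and tl.optimal_phase != tl.reference_phase
        and tc.optimal_phase != tc.reference_phase
        and abs(tl.optimal_phase - tc.optimal_phase) > 1
    ):
        return PatientClassification(
            "inconclusive", "none",
            f"TL optimum phase {tl.optimal_phase} and TC optimum phase "
            f"{tc.optimal_phase} disagree under strict concordance",
        )

    driving = "TL" if exceeds["TL"] else "TC"
    result = tl if driving == "TL" else tc
    if result.optimal_phase == result.reference_phase:
        return PatientClassification("max_inspiration_optimal", driving)
    return PatientClassification(
        "other_phase_optimal", driving,
        f"{driving} optimum at phase {result.optimal_phase}, "
        f"reference phase {result.reference_phase}",
    )


def summarize(results: Iterable[PatientResult]) -> CohortSummary:
    """Cohort statistics: mean, population SD (divisor N), min and max of
    each of the four gain columns, plus patient counts per label."""
    results = list(results)
    if not results:
        raise PhaseOptError("empty cohort")

    stats: dict = {}
    for param in ("TL", "TC"):
        stats[param] = {}
        for comp, attr in (("vs_ref", "gain_vs_ref_pct"), ("vs_worst", "gain_vs_worst_pct")):
            col = np.array([getattr(getattr(r, param.lower()), attr) for r in results])
            stats[param][comp] = {
                "mean_pct": float(col.mean()),
                "sd_pct": float(col.std()),  # population SD
                "min_pct": float(col.min()),
                "max_pct": float(col.max()),
            }
    counts = {label: 0 for label in LABELS}
    for r in results:
        counts[r.classification.label] += 1
    return CohortSummary(stats=stats, label_counts=counts, n_patients=len(results))


# ---------------------------------------------------------------------------
# reporting


def _gain_record(g: GainResult) -> dict:
    d = asdict(g)
    d["values"] = list(g.values)
    return d


def render_report(
    tables,
    results: Sequence[PatientResult],
    out_dir,
    summary: CohortSummary | None = None,
    make_charts: bool = True,
) -> dict:
    """Write the machine-readable and graphical report for a cohort.

    Produces ``report.json`` (schema-versioned), one CSV of the per-phase
    parameter table per patient, per-patient bar charts of both comparison
    parameters and the lung-volume curve, and a one-page synoptic summary.
    Returns the report dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {t.patient_id or f"patient{i}": t for i, t in enumerate(tables)}

    report = {
        "schema_version": 1,
        "patients": {},
        "summary": None,
    }
    for res in results:
        report["patients"][res.patient_id] = {
            "tl": _gain_record(res.tl),
            "tc": _gain_record(res.tc),
            "classification": asdict(res.classification),
        }
        table = tables.get(res.patient_id)
        if table is not None:
            table.data.to_csv(out / f"{res.patient_id}_phase_table.csv")
    if summary is not None:
        report["summary"] = {
            "stats": summary.stats,
            "label_counts": summary.label_counts,
            "n_patients": summary.n_patients,
        }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    if make_charts:
        for res in results:
            _patient_chart(res, tables.get(res.patient_id), out / f"{res.patient_id}_summary.png")
    return report


def _patient_chart(res: PatientResult, table, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    phases = np.arange(10)
    n_panels = 3 if table is not None and np.isfinite(table.lung_volumes).all() else 2
    fig, axes = plt.subplots(1, n_panels, figsize=(4 * n_panels, 3.2))
    specs = [
        (res.tl, "T/L ratio (100·Vt/Vl)", "tab:blue"),
        (res.tc, "T-C distance (mm)", "tab:orange"),
    ]
    for ax, (g, title, color) in zip(axes, specs):
        ax.bar(phases, g.values, color=color)
        ax.bar([g.optimal_phase], [g.values[g.optimal_phase]], color="tab:green")
        ax.axvline(g.reference_phase, color="k", ls="--", lw=1)
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("phase")
    if n_panels == 3:
        axes[2].bar(phases, table.lung_volumes / 1e3, color="tab:gray")
        axes[2].set_title("ipsilateral lung volume (cm³)", fontsize=9)
        axes[2].set_xlabel("phase")
    fig.suptitle(
        f"{res.patient_id}: {res.classification.label} "
        f"(driving: {res.classification.driving_parameter})",
        fontsize=10,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
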