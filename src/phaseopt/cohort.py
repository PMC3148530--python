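"""The bundled 14-patient reference cohort and its evaluation.

A published clinical study of fourteen lung-cancer patients reported, for
every patient, the two comparison parameters across all ten respiratory
phases together with the derived gain columns and an "optimal phase equals
reference" flag.  Those tables are bundled here (``data/cohort_tl.csv``,
``data/cohort_tc.csv``, ``data/cohort_meta.csv``) as the package's
reference input: they exercise the complete decision core at desk scale
and pin down the conventions (gain denominators, population SD, rounding)
that reproduce every printed cell.

Reference-phase inference
-------------------------
The published tables never print the per-patient reference phase (the
phase of maximal inspiration), only gains measured against it.  It is
recovered here by constraint propagation:

1. a candidate phase ``r`` must reproduce, after rounding half away from
   zero, the printed gain-vs-reference in *both* tables;
2. a printed "opt = ref" flag is binding only when it is internally
   consistent with its own printed gain (a "yes" next to a non-zero gain
   contradicts itself and is dropped); a binding "yes" forces ``r`` to be
   the optimal phase index, a binding "no" excludes it.

A unique surviving candidate is the inferred reference.  The cohort
metadata additionally carries a *stated* reference phase where the study
declared one explicitly (patient 9, phase 6).  When the stated phase
conflicts with the inferred one the patient's baseline is ambiguous: gains
are still computed against the inferred reference (the only baseline
consistent with the printed numbers), but the patient is classified
``inconclusive``.  Under this rule set the cohort splits 4 / 7 / 2 / 1
(maximal-inspiration optimal / other phase optimal / no benefit /
inconclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .optimize import (
    CohortSummary,
    PatientResult,
    classify,
    gain,
    round_half_away,
    summarize,
)

__all__ = [
    "CohortPatient",
    "PatientEvaluation",
    "load_cohort",
    "infer_reference_phase",
    "evaluate_cohort",
    "recomputed_gain_cells",
]


@dataclass(frozen=True)
class CohortPatient:
    patient_id: str
    tl_values: tuple
    tc_values: tuple
    printed: dict  # {"TL": (opt_eq_ref, gain_ref, gain_worst), "TC": ...}
    stated_reference: int | None
    site: str = ""


@dataclass
class PatientEvaluation:
    patient: CohortPatient
    reference_phase: int
    reference_candidates: tuple
    reference_conflict: bool
    result: PatientResult
    flags: list = field(default_factory=list)


def _read(name: str) -> pd.DataFrame:
    with resources.files("phaseopt.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype={"patient_id": str})


def load_cohort() -> list[CohortPatient]:
    """Load the bundled reference cohort (14 patients, both parameters)."""
    tl = _read("cohort_tl.csv").set_index("patient_id")
    tc = _read("cohort_tc.csv").set_index("patient_id")
    meta = _read("cohort_meta.csv").set_index("patient_id")
    cols = [f"p{k}" for k in range(10)]
    patients = []
    for pid in tl.index:
        stated = meta.loc[pid, "stated_reference_phase"]
        patients.append(
            CohortPatient(
                patient_id=pid,
                tl_values=tuple(tl.loc[pid, cols].astype(float)),
                tc_values=tuple(tc.loc[pid, cols].astype(float)),
                printed={
                    "TL": (
                        tl.loc[pid, "opt_eq_ref"] == "yes",
                        int(tl.loc[pid, "gain_ref_pct"]),
                        int(tl.loc[pid, "gain_worst_pct"]),
                    ),
                    "TC": (
                        tc.loc[pid, "opt_eq_ref"] == "yes",
                        int(tc.loc[pid, "gain_ref_pct"]),
                        int(tc.loc[pid, "gain_worst_pct"]),
                    ),
                },
                stated_reference=None if pd.isna(stated) else int(stated),
                site=str(meta.loc[pid, "site"]),
            )
        )
    return patients


def infer_reference_phase(patient: CohortPatient) -> tuple:
    """Candidate reference phases consistent with the printed gain columns.

    Returns ``(candidates, flags)`` where *candidates* is a tuple of phase
    indices and *flags* a list of noted inconsistencies (e.g. a printed
    opt=ref flag contradicting its own printed gain).
    """
    tl = np.asarray(patient.tl_values)
    tc = np.asarray(patient.tc_values)
    opts = {"TL": int(np.argmin(tl)), "TC": int(np.argmax(tc))}
    best = {"TL": tl.min(), "TC": tc.max()}
    flags = []

    binding = {}
    for param in ("TL", "TC"):
        eq_ref, gain_ref, _ = patient.printed[param]
        binding[param] = not (eq_ref and gain_ref != 0)
        if not binding[param]:
            flags.append(
                f"{param}: printed opt=ref flag contradicts its printed gain "
                f"({gain_ref}%); flag ignored for inference"
            )

    candidates = []
    for r in range(10):
        ok = True
        for param, values in (("TL", tl), ("TC", tc)):
            eq_ref, gain_ref, _ = patient.printed[param]
            recomputed = round_half_away(100.0 * abs(values[r] - best[param]) / values[r])
            if recomputed != gain_ref:
                ok = False
                break
            if binding[param] and eq_ref != (r == opts[param]):
                ok = False
                break
        if ok:
            candidates.append(r)
    return tuple(candidates), flags


def _resolve_reference(patient: CohortPatient) -> tuple:
    """(reference, candidates, conflict, flags) for one patient."""
    candidates, flags = infer_reference_phase(patient)
    conflict = False
    if len(candidates) == 1:
        ref = candidates[0]
        if patient.stated_reference is not None and patient.stated_reference != ref:
            conflict = True
            flags.append(
                f"stated reference phase {patient.stated_reference} conflicts with "
                f"the phase {ref} inferred from the printed gains; baseline ambiguous"
            )
    elif patient.stated_reference is not None:
        ref = patient.stated_reference
        conflict = len(candidates) == 0
        if conflict:
            flags.append("no inferred reference consistent with the printed gains")
    else:
        raise ValueError(
            f"patient {patient.patient_id}: reference phase not derivable "
            f"({len(candidates)} candidates) and none stated"
        )
    return ref, candidates, conflict, flags


def evaluate_cohort(cutoff_pct: float = 20.0) -> list[PatientEvaluation]:
    """Run the full decision core on the bundled cohort."""
    evaluations = []
    for patient in load_cohort():
        ref, candidates, conflict, flags = _resolve_reference(patient)
        tl_gain = gain("TL", patient.tl_values, ref)
        tc_gain = gain("TC", patient.tc_values, ref)
        cls = classify(tl_gain, tc_gain, cutoff_pct=cutoff_pct)
        if conflict and cls.label != "no_benefit":
            from .optimize import PatientClassification

            cls = PatientClassification(
                "inconclusive", "none",
                "reference phase ambiguous: " + "; ".join(flags),
            )
        evaluations.append(
            PatientEvaluation(
                patient=patient,
                reference_phase=ref,
                reference_candidates=candidates,
                reference_conflict=conflict,
                result=PatientResult(patient.patient_id, tl_gain, tc_gain, cls),
                flags=flags,
            )
        )
    return evaluations


def cohort_summary(evaluations=None, cutoff_pct: float = 20.0) -> CohortSummary:
    if evaluations is None:
        evaluations = evaluate_cohort(cutoff_pct=cutoff_pct)
    return summarize([e.result for e in evaluations])


def rounded_gain_summary(evaluations=None) -> dict:
    """Cohort statistics of the display-rounded gain columns.

    The published summary statistics are taken over the printed (integer)
    gain columns, so this summary rounds each recomputed gain half away
    from zero first, then reports mean, population SD, min and max per
    parameter x comparison.
    """
    cells = recomputed_gain_cells(evaluations)
    out: dict = {}
    for (param, comp), group in cells.groupby(["parameter", "comparison"]):
        col = group["rounded_pct"].to_numpy(dtype=float)
        out.setdefault(param, {})[comp] = {
            "mean_pct": float(col.mean()),
            "sd_pct": float(col.std()),
            "min_pct": float(col.min()),
            "max_pct": float(col.max()),
        }
    return out


def recomputed_gain_cells(evaluations=None) -> pd.DataFrame:
    """Every printed gain cell next to its recomputed, display-rounded value.

    One row per patient x parameter x comparison (56 cells); the
    ``matches`` column marks agreement with the printed integer.
    """
    if evaluations is None:
        evaluations = evaluate_cohort()
    rows = []
    for ev in evaluations:
        for param in ("TL", "TC"):
            g = getattr(ev.result, param.lower())
            _, printed_ref, printed_worst = ev.patient.printed[param]
            for comp, printed, exact in (
                ("vs_ref", printed_ref, g.gain_vs_ref_pct),
                ("vs_worst", printed_worst, g.gain_vs_worst_pct),
            ):
                rounded = round_half_away(exact)
                rows.append(
                    {
                        "patient_id": ev.patient.patient_id,
                        "parameter": param,
                        "comparison": comp,
                        "printed_pct": printed,
                        "recomputed_pct": exact,
                        "rounded_pct": rounded,
                        "matches": rounded == printed,
                        "reference_conflict": ev.reference_conflict,
                    }
                )
    return pd.DataFrame(rows)
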