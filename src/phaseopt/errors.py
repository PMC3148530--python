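"""Exception hierarchy for the phase-optimization pipeline."""


class PhaseOptError(Exception):
    """Base class for all package errors."""


class GeometryError(PhaseOptError):
    """Invalid or mismatched grid geometry (spacing, shape, origin)."""


class EmptyRoiError(PhaseOptError):
    """An operation required a non-empty region of interest."""

    def __init__(self, roi_name: str, detail: str = ""):
        self.roi_name = roi_name
        msg = f"ROI '{roi_name}' is empty"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class LateralityError(PhaseOptError):
    """Ipsilateral lung could not be determined automatically."""


class GainError(PhaseOptError):
    """Gain computation is undefined (zero reference, non-finite values)."""


class ValidationError(PhaseOptError):
    """Input validation failed; carries a list of individual problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "validation failed:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


class PhantomConfigError(PhaseOptError):
    """Synthetic-phantom configuration is geometrically inconsistent."""
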