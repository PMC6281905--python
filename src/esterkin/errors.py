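"""Exception hierarchy shared across the package."""


class EsterkinError(Exception):
    """Base class for all package-specific errors."""


class ParseError(EsterkinError):
    """Malformed structure file (bad count, unknown element, bad number)."""


class EmptyStructureError(ParseError):
    """No ATOM/HETATM records found."""


class NotAnEsterError(EsterkinError):
    """Structure lacks the As/P centre every ester operation requires."""


class ConfigurationError(EsterkinError):
    """Invalid option value or missing tabulated data for a request."""


class GeometryError(EsterkinError):
    """Degenerate or invalid geometric measurement request."""


class UnsupportedEsterError(EsterkinError):
    """Linkage pattern outside the supported classification."""


class SubstitutionError(EsterkinError):
    """As-for-P substitution requested at a non-phosphorus position."""


class ConsistencyError(EsterkinError):
    """Mutually contradictory inputs (e.g. both k and ΔG‡ given, incompatible)."""


class InvalidTransitionStateError(EsterkinError):
    """Frequency set flagged as TS does not have exactly one imaginary mode."""


class ReferenceMismatchError(EsterkinError):
    """Activation-strain reference energy inconsistent with fragment sum."""
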