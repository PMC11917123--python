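"""Exception hierarchy for ligandkit."""


class LigandKitError(Exception):
    """Base class for all ligandkit errors."""


class ParseError(LigandKitError):
    """A table or block could not be parsed; the message names the offending row."""


class IntegrityError(LigandKitError):
    """A record violates a referential invariant (e.g. a bond to an unknown atom)."""


class EmptyStructureError(LigandKitError):
    """An assembly contains no atom sites."""


class EmptyMoleculeError(LigandKitError):
    """An operation that needs atoms was handed an empty molecule."""


class MissingCoordinatesError(LigandKitError):
    """A coordinate-dependent export or score was requested without coordinates."""


class SanitizationError(LigandKitError):
    """Sanitization failed to converge; carries the partial report."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class UnidentifiedMoleculeError(LigandKitError):
    """InChIKey computation failed for a bound molecule; carries its components."""

    def __init__(self, message, component_multiset=None):
        super().__init__(message)
        self.component_multiset = component_multiset


class ProtonationModeError(LigandKitError):
    """Angle-dependent contact typing was requested on an unprotonated structure."""
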