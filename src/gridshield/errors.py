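"""Exception and warning hierarchy."""


class GridShieldError(Exception):
    """Base class for all package errors."""


class StructureParseError(GridShieldError):
    """Input structure could not be parsed."""


class NonStandardResidueError(StructureParseError):
    """A polymer residue outside the canonical 20 was encountered."""


class InsertionCodeError(StructureParseError):
    """Insertion codes are unsupported."""


class MissingAtomError(GridShieldError):
    """A required atom is absent from a residue."""


class ShiftTableError(GridShieldError):
    """Malformed experimental shift or random-coil table."""


class MissingChiError(GridShieldError):
    """A grid axis needs a chi angle the structure cannot define (strict mode)."""


class UndefinedTorsionError(GridShieldError):
    """Torsion requested for (near-)collinear points."""


class GridBundleError(GridShieldError):
    """Grid bundle is corrupt or inconsistent with its manifest."""


class InterpolationError(GridShieldError):
    """Bad coordinates handed to a grid lookup."""


class ConfigurationError(GridShieldError):
    """Library or mask configuration contradicts the model's contracts."""


class DegenerateFitError(GridShieldError):
    """Regression input has zero variance or too few pairs."""


class GridShieldWarning(UserWarning):
    """Base class for package warnings (chain breaks, skipped rings...)."""
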