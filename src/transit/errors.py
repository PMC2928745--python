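"""Exception hierarchy shared across the package."""


class TransitError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(TransitError):
    """A PDB record could not be parsed; the message names the offending line."""


class EmptyInputError(TransitError):
    """An input contained no usable records (e.g. a PDB with zero atoms)."""


class SelectionError(TransitError):
    """A selection expression is malformed or references unknown labels."""


class DegenerateGeometryError(TransitError):
    """Point sets too degenerate (collinear/coincident) for a rigid fit."""


class AlignmentError(TransitError):
    """An alignment map violates its invariants or an edit would break them."""


class AnalysisError(TransitError):
    """An analysis operation received inputs that make its criterion undefined."""


class DynamicsError(TransitError):
    """Numerical failure during dynamics (e.g. NaN coordinates)."""


class ConfigError(TransitError):
    """Run configuration is invalid or references missing files."""
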