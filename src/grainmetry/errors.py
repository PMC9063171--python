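"""Exception hierarchy used across the package."""


class GrainmetryError(Exception):
    """Base class for all package-specific errors."""


class InputError(GrainmetryError):
    """An input file is missing, unreadable, or undecodable."""


class ParameterError(GrainmetryError, ValueError):
    """A parameter value is outside its documented domain."""


class TableParseError(GrainmetryError):
    """A measurement table could not be parsed as CSV."""


class DegenerateRegionError(GrainmetryError):
    """A region is too small or too thin for the requested measurement."""


class LookupError_(GrainmetryError, KeyError):
    """A published-coefficient lookup failed; the message lists valid keys."""


class PlacementError(GrainmetryError):
    """Synthetic grain placement could not satisfy the no-contact constraint."""
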