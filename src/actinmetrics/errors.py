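"""Exception hierarchy.

Every analysis stage raises a subclass of :class:`ActinMetricsError`, so
callers (and the CLI) can distinguish input problems from analysis problems.
"""


class ActinMetricsError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(ActinMetricsError):
    """A coordinate file could not be parsed."""


class FormatError(ActinMetricsError):
    """Unknown or unsupported file format."""


class ChainLookupError(ActinMetricsError, KeyError):
    """Requested chain id is not present in the structure/frame."""


class DegenerateGeometryError(ActinMetricsError):
    """Geometry is degenerate (collinear torsion points, rank-deficient
    point sets, empty atom collections)."""


class MatchingError(ActinMetricsError):
    """Too few residues in common to superpose two chains."""


class PartitionError(ActinMetricsError):
    """A subdomain has no modeled residues on the given chain."""


class GateMetricError(ActinMetricsError):
    """A required atom for a gate/contact metric is missing."""


class SpecError(ActinMetricsError):
    """Invalid synthetic-generator specification."""


class WriteError(ActinMetricsError):
    """A structure cannot be serialized (e.g. residue number overflow)."""
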