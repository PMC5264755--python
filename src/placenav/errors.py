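"""Exception hierarchy for placenav."""


class PlacenavError(Exception):
    """Base class for all placenav-specific errors."""


class ConfigurationError(PlacenavError, ValueError):
    """A simulation parameter violates its constraint; message names the field."""


class NumericInputError(PlacenavError, ValueError):
    """A coordinate or scalar input is non-finite."""


class WeightDomainError(PlacenavError, ValueError):
    """A synaptic weight or weight increment is outside its domain (< 0)."""


class SelfSynapseError(PlacenavError, ValueError):
    """A transition from a cell to itself cannot strengthen a synapse."""


class ShapeError(PlacenavError, ValueError):
    """An array is not dimensioned to the lattice."""


class UndefinedDirectionError(PlacenavError, RuntimeError):
    """Zero gradient with zero noise: the next step direction is undefined."""


class UndefinedOptimalityError(PlacenavError, ValueError):
    """Path optimality is undefined for an unterminated trajectory."""


class TargetNotFoundError(PlacenavError, RuntimeError):
    """The first (random) trial never reached the target; learning cannot start."""
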