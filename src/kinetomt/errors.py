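"""Exception hierarchy shared by all kinetomt modules."""


class KinetoMTError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(KinetoMTError, ValueError):
    """An argument is outside its documented domain (zero axis, n_fold < 1, ...)."""


class DegenerateInputError(KinetoMTError, ValueError):
    """A point set is too small or collinear for a unique superposition."""


class ParseError(KinetoMTError, ValueError):
    """A coordinate file or selection string could not be parsed."""


class ChainCollisionError(KinetoMTError, ValueError):
    """Duplicate chain ids encountered under the strict merge policy."""


class SelectionError(KinetoMTError, KeyError):
    """A selection resolved to no atoms where atoms were required."""


class MatchError(KinetoMTError, ValueError):
    """Atom matching between two structures failed; carries the unmatched keys."""

    def __init__(self, message: str, unmatched=()):
        super().__init__(message)
        self.unmatched = tuple(unmatched)


class PlacementError(KinetoMTError, ValueError):
    """A requested geometric placement could not be achieved."""

    def __init__(self, message: str, achieved_angle: float | None = None):
        super().__init__(message)
        self.achieved_angle = achieved_angle


class InsufficientDataError(KinetoMTError, ValueError):
    """Too few lattice sites to estimate the requested parameters."""


class ConfigurationError(KinetoMTError, ValueError):
    """A required annotation (e.g. a dimer body frame) is missing."""


class ValidationError(KinetoMTError, ValueError):
    """An input violates a semantic precondition (e.g. non-Ser/Thr phospho site)."""
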