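"""Exception hierarchy for trajkit.

All trajkit errors derive from :class:`TrajkitError` so callers can catch the
whole family with one clause.  The concrete classes mirror the distinct
failure modes of the container, tree, storage and runner layers.
"""


class TrajkitError(Exception):
    """Base class for all trajkit errors."""


# --- container layer -------------------------------------------------------

class LockedError(TrajkitError):
    """Mutation attempted on a locked parameter."""


class UnsupportedTypeError(TrajkitError):
    """Value kind is not covered by any registered type tag."""


class HeterogeneousRangeError(TrajkitError):
    """Exploration range elements do not share a single type tag."""


class EmptyRangeError(TrajkitError):
    """Exploration range (or Cartesian factor) is empty."""


class DuplicateTagError(TrajkitError):
    """A type tag was registered twice."""


class UnknownTagError(TrajkitError):
    """A stored type tag has no registered codec."""


# --- tree layer ------------------------------------------------------------

class RunPhaseError(TrajkitError):
    """Operation only allowed before any run has executed."""


class NameCollisionError(TrajkitError):
    """A node already exists at the requested path."""


class NotFoundError(TrajkitError):
    """No node matches the requested path or query."""


class AmbiguousNameError(TrajkitError):
    """Two distinct nodes match a shortcut query at the same minimal depth."""


class LinkDepthError(TrajkitError):
    """Link chain exceeded the chasing cap (guards against link cycles)."""


class LengthMismatchError(TrajkitError):
    """Exploration sequences do not all share one length."""


class ExplorationMismatchError(TrajkitError):
    """Expand named a different parameter set than the existing exploration."""


class UnexploredParameterError(TrajkitError):
    """Predicate filtering referenced a parameter without a range."""


class SpaceMismatchError(TrajkitError):
    """Trajectories to merge do not live in the same parameter space."""


# --- storage layer ---------------------------------------------------------

class UnsupportedOperationError(TrajkitError):
    """Deleting or replacing data already on disk is not supported."""


# --- runner layer ----------------------------------------------------------

class NoExplorationError(TrajkitError):
    """Run requested on a trajectory without pending explored runs."""


class SerializationError(TrajkitError):
    """An object shipped to a worker process could not be pickled."""


class RunFailedError(TrajkitError):
    """Wraps the first exception raised inside a single run.

    Attributes
    ----------
    run_index : int
        Index of the failing run.
    """

    def __init__(self, run_index: int, message: str):
        super().__init__(message)
        self.run_index = run_index
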