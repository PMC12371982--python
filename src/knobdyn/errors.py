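"""Exception hierarchy for knobdyn.

All package-specific failures derive from :class:`KnobdynError` so callers
can catch pipeline problems without masking programming errors.
"""


class KnobdynError(Exception):
    """Base class for all knobdyn errors."""


class PDBParseError(KnobdynError):
    """A PDB file could not be parsed (malformed record)."""


class EmptyStructureError(KnobdynError):
    """A structure file contained no ATOM/HETATM records."""


class TrajectoryConsistencyError(KnobdynError):
    """Models of a multi-model file do not share an identical atom list."""


class PartitionError(KnobdynError):
    """A domain partition violates disjointness or ordering constraints."""


class UnknownResidueError(PartitionError):
    """A configured residue does not exist in the topology."""


class IncompleteBackboneError(KnobdynError):
    """A residue lacks one of the backbone atoms N, CA, C."""


class FitError(KnobdynError):
    """A rigid-body fit is impossible (too few or degenerate points)."""


class DimensionError(KnobdynError):
    """Coordinate arrays have incompatible shapes."""


class DihedralUndefinedError(KnobdynError):
    """Three consecutive dihedral points are collinear."""


class ParameterAssignmentError(KnobdynError):
    """One or more atoms have no Lennard-Jones parameter entry."""


class SyntheticSpecError(KnobdynError):
    """A synthetic-trajectory specification is internally inconsistent."""


class AggregationError(KnobdynError):
    """Per-run results cannot be aggregated (mismatched systems)."""


class StageError(KnobdynError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
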