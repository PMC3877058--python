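"""Exception hierarchy for pockalign."""


class PockalignError(Exception):
    """Base class for all pockalign errors."""


class FormatError(PockalignError):
    """Input file could not be parsed as PDB."""


class MissingLigandError(PockalignError):
    """No non-water HETATM group available as reference ligand."""


class UnknownElementError(PockalignError):
    """Element symbol absent from the atomic-mass table."""


class EmptyProteinError(PockalignError):
    """Structure contains no protein atoms."""


class PocketDetectionError(PockalignError):
    """No buried spheres survive, so no pocket can be grown."""


class EmptyPocketSurfaceError(PockalignError):
    """No surface atom lies near the pocket or ligand bounding box."""


class GridError(PockalignError):
    """Occupancy grid could not be built (no atoms to place)."""


class UndefinedScoreError(PockalignError):
    """Similarity score undefined (no surface atoms or no pocket spheres)."""


class AlignmentError(PockalignError):
    """Sequence alignment impossible (empty sequence)."""


class MissingSecondaryStructureError(PockalignError):
    """Secondary-structure classes unavailable; supply DSSP output or use
    the built-in simplified assigner."""


class UndefinedAUCError(PockalignError):
    """ROC AUC undefined (labels contain a single class)."""


class FixtureSpecError(PockalignError):
    """Synthetic-fixture specification is geometrically infeasible."""
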