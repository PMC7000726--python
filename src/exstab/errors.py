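"""Exception hierarchy for exstab."""


class ExstabError(Exception):
    """Base class for all package errors."""


class FastaFormatError(ExstabError):
    """FASTA input violates the format contract (bad header or alphabet)."""


class PDBParseError(ExstabError):
    """PDB input has no usable coordinate records."""


class MissingChainError(ExstabError, KeyError):
    """Requested chain id not present in the structure."""


class UndefinedCompositionError(ExstabError):
    """Composition undefined (no standard residues in the sequence)."""


class InsufficientDataError(ExstabError):
    """A statistical comparison was requested with too few observations."""


class InsufficientPairsError(ExstabError):
    """Fewer than three atom pairs available for superposition."""


class DegenerateGeometryError(ExstabError):
    """Point geometry does not determine a unique rigid superposition."""


class UndefinedTorsionError(ExstabError):
    """Torsion angle undefined (collinear or coincident points)."""


class BackboneSpecError(ExstabError):
    """Backbone specification rows inconsistent with the residue sequence."""


class PlacementError(ExstabError):
    """Requested synthetic atom placement is geometrically impossible."""


class EmptyReportError(ExstabError):
    """No manifest row survived validation; nothing to report."""
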