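"""Exception and warning taxonomy for the PDB -> SHELX conversion pipeline.

Errors mirror the defect classes a conversion run can hit: structural
problems in the coordinate file, unusable symmetry, element bookkeeping,
incomplete reflection data, and fixed-format overflow.
"""


class ShelxBridgeError(Exception):
    """Base class for all conversion errors."""

    #: short machine-readable defect label used in run reports
    label = "error"


class MultiModelError(ShelxBridgeError):
    """More than one coordinate MODEL in the input; refinement needs one."""

    label = "multiple models"


class MissingCellError(ShelxBridgeError):
    """No CRYST1 record: cell and space group are mandatory."""

    label = "missing cell"


class DuplicateAtomError(ShelxBridgeError):
    """Two atoms share chain, residue, altLoc and name."""

    label = "duplicate atom"


class ChainExhaustionError(ShelxBridgeError):
    """More distinct chains than the 63 legal one-character identifiers."""

    label = "chain identifiers exhausted"


class CapacityError(ShelxBridgeError):
    """A chain cannot be renumbered into the legal residue-number range."""

    label = "residue capacity exceeded"


class UnknownSpaceGroupError(ShelxBridgeError):
    """Space-group symbol not in the Sohncke-group dictionary."""

    label = "unknown space group"


class CentrosymmetricError(ShelxBridgeError):
    """Symbol implies inversion or other improper symmetry; chiral
    macromolecules can only crystallize in the 65 Sohncke groups."""

    label = "non-Sohncke space group"


class DivergenceError(ShelxBridgeError):
    """Generator closure exceeded the largest possible group order."""

    label = "symmetry divergence"


class SingularCellError(ShelxBridgeError):
    """Cell angles admit no positive-volume parallelepiped."""

    label = "singular cell"


class NegativeBError(ShelxBridgeError):
    """Negative isotropic displacement parameter."""

    label = "negative B"


class UnknownElementError(ShelxBridgeError):
    """Element symbol outside the first 98 elements."""

    label = "unknown element"


class NoTabulationError(ShelxBridgeError):
    """No dispersion tabulation for this element/wavelength."""

    label = "no dispersion tabulation"


class IncompleteDataError(ShelxBridgeError):
    """Reflection loop unusable: sigmas missing or only one Friedel branch."""

    label = "incomplete reflection data"


class HklOverflowError(ShelxBridgeError):
    """A reflection value cannot fit its fixed-format field."""

    label = "hkl format overflow"


class AssemblyError(ShelxBridgeError):
    """Instruction-file invariant violated during assembly."""

    label = "assembly error"


class NotFoundError(ShelxBridgeError):
    """Accession code not present in the archive."""

    label = "entry not found"


class NetworkError(ShelxBridgeError):
    """Archive unreachable."""

    label = "network error"


class UnknownDefectError(ShelxBridgeError):
    """Fixture defect-injection tag not recognized."""

    label = "unknown defect"


class NoRestraintsWarning(UserWarning):
    """Residue type absent from the restraint library; atoms will refine
    without stereochemical restraints."""


class ConversionWarning(UserWarning):
    """Non-fatal conversion issue (automated mode continues)."""
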