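"""Exception hierarchy used across the package."""


class RinscanError(Exception):
    """Base class for all package-specific errors."""


class StructureFormatError(RinscanError, ValueError):
    """A structure file could not be parsed as the declared format."""


class EmptyStructureError(RinscanError, ValueError):
    """No atoms remain after filtering (waters, hydrogens, ligands)."""


class ChainNotFoundError(RinscanError, LookupError):
    """A requested chain identifier is absent from the model."""


class ResidueNotFoundError(RinscanError, LookupError):
    """A requested residue key is absent from the model."""


class ResidueMatchError(RinscanError, ValueError):
    """Complex and reference models share no matchable receptor residues."""
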