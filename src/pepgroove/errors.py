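"""Exception hierarchy shared across the package."""


class PepgrooveError(Exception):
    """Base class for all package errors."""


class PdbParseError(PepgrooveError):
    """A PDB coordinate record could not be parsed."""


class EmptyStructureError(PepgrooveError):
    """The coordinate section of the input contained no atoms."""


class SelectionError(PepgrooveError):
    """A selection expression is syntactically invalid."""


class NoReceptorError(PepgrooveError):
    """The ligand selection leaves no receptor atoms behind."""


class InvalidPairingError(PepgrooveError):
    """A residue pairing map is not one-to-one."""


class UnknownElementError(PepgrooveError):
    """An atom's element has no entry in the van der Waals radius table."""


class UnderdeterminedError(PepgrooveError):
    """Fewer than three atom pairs were available for superposition."""


class NoChiError(PepgrooveError):
    """The residue type has no chi angle of the requested index."""


class MissingAtomError(PepgrooveError):
    """Atoms required for a dihedral are absent from the residue."""


class CollinearError(PepgrooveError):
    """Three consecutive dihedral points are collinear; the angle is undefined."""


class LadderError(PepgrooveError):
    """Replica-ladder parameters are inconsistent."""


class FitError(PepgrooveError):
    """A nonlinear fit failed to converge from every start."""


class GenerationError(PepgrooveError):
    """A synthetic-data request is geometrically infeasible."""
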