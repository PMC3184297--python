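"""Exception hierarchy for the loco package."""


class LocoError(Exception):
    """Base class for all loco errors."""


class FormatError(LocoError):
    """Input text is not parsable PDB (no usable ATOM records)."""


class EmptyStructureError(LocoError):
    """No residue with a complete N/CA/C main chain was found."""


class EmptySetError(LocoError):
    """A decoy set ended up with no accepted members."""


class SequenceMismatchError(LocoError):
    """Two structures that must share a sequence do not."""


class DegenerateGeometryError(LocoError):
    """N/CA/C are collinear or coincident; no local frame exists."""


class DatabaseError(LocoError):
    """Potential database is unreadable, corrupt, or version-incompatible."""


class BinRangeError(LocoError):
    """A bin outside the cutoff range was requested from the database."""
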