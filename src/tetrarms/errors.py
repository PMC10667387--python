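"""Exception hierarchy."""


class TetrarmsError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TetrarmsError, ValueError):
    """Malformed input file (FASTA, primer table, band table, report)."""


class TableStructureError(ParseError):
    """A primer table whose rows do not form well-formed four-primer assays."""


class DesignError(TetrarmsError):
    """No primer/assay placement satisfies the design constraints.

    ``violations`` lists the constraint names that could not be met.
    """

    def __init__(self, message: str, violations: list[str] | None = None):
        super().__init__(message)
        self.violations = list(violations or [])
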