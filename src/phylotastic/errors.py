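"""Exception hierarchy shared across the toolkit."""


class PhylotasticError(Exception):
    """Base class for all errors raised by this package."""


class NewickParseError(PhylotasticError):
    """Malformed Newick/NEXUS input (unbalanced parentheses, bad tokens, ...)."""


class TreeInvariantError(PhylotasticError):
    """A tree violates a structural invariant (duplicate tips, negative lengths)."""


class LabelLookupError(PhylotasticError, KeyError):
    """One or more requested labels are not tips of the tree."""

    def __init__(self, missing, message=None):
        self.missing = sorted(missing)
        super().__init__(message or f"labels not found: {', '.join(self.missing)}")

    def __str__(self):  # KeyError quotes its arg; keep a readable message
        return self.args[0]


class PruneError(PhylotasticError):
    """Pruning query cannot be satisfied (e.g. no queried taxon in the tree)."""


class CalibrationError(PhylotasticError):
    """Inconsistent or insufficient node-age calibrations for bladj."""


class StoreError(PhylotasticError):
    """Chronogram/path store construction or query failure."""


class TNRSError(PhylotasticError):
    """Name-resolution submission/retrieval failure."""


class FormatError(PhylotasticError):
    """Malformed non-tree input (taxon paths, calibration files, tables)."""
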