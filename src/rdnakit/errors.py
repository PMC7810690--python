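"""Exception hierarchy shared across the package."""


class RdnakitError(Exception):
    """Base class for all package errors."""


class InvalidFeatureError(RdnakitError, ValueError):
    """A feature combination violates the barcode grammar."""


class CodeParseError(RdnakitError, ValueError):
    """A barcode string does not match the expected grammar."""


class InvalidInputError(RdnakitError, ValueError):
    """An operation received input outside its contract."""


class OrientationConflictError(RdnakitError):
    """Anchor matches on both strands: head-to-tail assumption violated."""


class FingerprintTooShortError(RdnakitError, ValueError):
    """A fingerprint needs at least two reference points."""


class ContigConflictError(RdnakitError):
    """Overlap matches imply inconsistent placements within one contig."""


class InternalConsistencyError(RdnakitError):
    """Counts and marginals disagree; indicates a bookkeeping bug upstream."""


class UndefinedCorrelationError(RdnakitError, ValueError):
    """Pearson correlation is undefined for a zero-variance vector."""


class CoordinateMismatchError(RdnakitError, ValueError):
    """Two variant call sets refer to different reference sequences."""


class ConfigError(RdnakitError, ValueError):
    """A simulation or pipeline configuration is infeasible or invalid."""


class CatalogParseError(CodeParseError):
    """A unit catalog file contains a malformed token."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        where = ""
        if line is not None:
            where = f" (line {line}" + (f", column {column}" if column is not None else "") + ")"
        super().__init__(message + where)
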