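"""Exception hierarchy.

Every error raised by the package derives from :class:`GwasDecompError`, so
callers (and the CLI, which maps these onto exit codes) can catch one base
class.  Validation problems and convergence failures are distinguished
because they call for different remedies.
"""


class GwasDecompError(Exception):
    """Base class for all package errors."""


class FormatError(GwasDecompError):
    """A file or table does not conform to the expected layout."""


class EmptyInputError(GwasDecompError):
    """No rows survived validation."""


class ValidationError(GwasDecompError):
    """A precondition on values or configuration is violated."""


class AlleleMismatchError(GwasDecompError):
    """Effect/other alleles neither match nor swap against the registry."""


class MissingSnpError(GwasDecompError):
    """A requested SNP is absent from one or more tables (strict mode)."""


class LdCoverageError(GwasDecompError):
    """A within-window SNP pair has no known r2 (strict mode)."""


class ConvergenceError(GwasDecompError):
    """Iterative estimation failed to converge.

    Carries per-restart iteration diagnostics in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class UndefinedCorrelationError(GwasDecompError):
    """Pearson correlation undefined because a vector is constant."""


class RegistryMismatchError(GwasDecompError):
    """Two objects that must share a SNP/trait registry do not."""
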