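"""Typed exceptions shared across the package."""


class ApascopeError(Exception):
    """Base class for all package errors."""


class AnnotationParseError(ApascopeError):
    """Malformed annotation record; carries the offending line number."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class NoUTRError(ApascopeError):
    """The transcript has a zero-length annotated 3'UTR."""


class CoverageError(ApascopeError):
    """Invalid coverage input (overlapping bedGraph intervals, bad library size...)."""


class DegeneratePWMError(ApascopeError):
    """PWM whose maximal and minimal attainable scores coincide."""


class SchemaError(ApascopeError):
    """A tabular input is missing required columns."""


class PipelineError(ApascopeError):
    """A pipeline stage failed; carries stage name and gene context."""

    def __init__(self, stage, message, gene_id=None):
        self.stage = stage
        self.gene_id = gene_id
        ctx = f" [gene {gene_id}]" if gene_id else ""
        super().__init__(f"stage '{stage}'{ctx}: {message}")
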