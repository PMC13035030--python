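"""Exception taxonomy shared across the pipeline.

Exit-code mapping used by the command line: validation/configuration
problems exit 1, I/O problems exit 2 (plain :class:`OSError` is used for
those and is not wrapped here).
"""

from __future__ import annotations


class SeednetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SeednetError):
    """A run configuration, schema map or lexicon is invalid."""


class ValidationError(SeednetError):
    """Input data violates a documented invariant (e.g. duplicate doc_id)."""


class NoSeedSentencesError(SeednetError):
    """The corpus contains no sentence with a seed lemma.

    Distinct from an empty co-occurrence table: downstream stages must
    fail loudly rather than emit an empty but well-formed result.
    """


class EmptyNetworkError(SeednetError):
    """Every node/edge was removed by the frequency or weight thresholds."""


class PipelineStageError(SeednetError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
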