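"""Exception hierarchy shared across the pipeline.

Every error the library raises on bad user input derives from
:class:`AnchorPipeError`, so callers (and the CLI) can distinguish data
problems (exit 1) from usage problems (exit 2) with one ``except``.
"""


class AnchorPipeError(Exception):
    """Base class for all anchorpipe data and parameter errors."""


class ParameterError(AnchorPipeError, ValueError):
    """A numeric or structural parameter is outside its valid domain."""


class AlignmentFormatError(AnchorPipeError):
    """Sequences that should form an alignment have unequal lengths."""


class DuplicateTaxonError(AnchorPipeError):
    """Two rows carry the same taxon label."""


class ManifestSchemaError(AnchorPipeError):
    """A locus manifest table is missing columns or holds unparseable values."""


class PartitionSchemeError(AnchorPipeError):
    """A partition scheme violates its invariants (overlap, coverage, bounds)."""


class DegenerateSpanError(AnchorPipeError):
    """A probe span is empty where a non-empty one is required."""
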