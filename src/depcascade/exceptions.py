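"""Package-wide exception types."""


class SchemaError(ValueError):
    """A table, fixture or config does not match its declared schema."""


class ValidationError(ValueError):
    """A loaded object violates one of its invariants."""


class LeakageError(RuntimeError):
    """A fitting step would read data it must not see (held-out rows,
    in-fold member predictions, ...)."""
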