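"""Exception hierarchy shared by all pipeline stages."""


class ZmGrasError(Exception):
    """Base class for every error raised by this package."""


class FormatError(ZmGrasError):
    """A file could not be parsed as its declared format."""


class ValidationError(ZmGrasError):
    """Parsed content violates an invariant (duplicate ids, bad coordinates...)."""


class MissingRecordError(ZmGrasError, KeyError):
    """A referenced record (protein, gene model, transcript) is absent."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep messages readable
        return Exception.__str__(self)


class PackagingError(ZmGrasError):
    """A packaged data file is missing or corrupted."""
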