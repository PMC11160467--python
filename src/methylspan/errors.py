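"""Exception types shared across the package."""


class MethylspanError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(MethylspanError, ValueError):
    """An argument violates a documented precondition."""


class InvalidTreeError(MethylspanError, ValueError):
    """A phylogeny is malformed (e.g. missing branch lengths)."""


class InsufficientDataError(MethylspanError, ValueError):
    """Too few observations to fit or evaluate a model."""


class DegenerateResponseError(MethylspanError, ValueError):
    """The response (or a predictor summary) carries no variance."""


class LeakageError(MethylspanError, ValueError):
    """A held-out unit would leak into its own training set."""


class UndefinedCorrelationError(MethylspanError, ValueError):
    """A correlation is requested on a zero-variance vector."""
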