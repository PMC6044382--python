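"""Exception hierarchy shared by all pipeline stages."""


class InDepthError(Exception):
    """Base class for all package errors."""


class ValidationError(InDepthError, ValueError):
    """An input violates a documented contract (bad enum, duplicate id, ...)."""


class DimensionError(InDepthError, ValueError):
    """Matrix/metadata shapes or index sets do not agree."""


class NoOverlapError(InDepthError, ValueError):
    """Neither query tag set overlaps the reference gene universe."""


class EmptySelectionError(InDepthError, ValueError):
    """A filter (e.g. cell line) matched zero reference records."""
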