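"""Exception hierarchy."""


class TritrophError(Exception):
    """Base class for package errors."""


class ConfigurationError(TritrophError, ValueError):
    """Invalid or inconsistent generator configuration (empty/inverted ranges...)."""


class DegenerateCommunityError(TritrophError, ValueError):
    """A community cannot support the requested operation (e.g. no resources)."""


class EmptyNetworkError(TritrophError, ValueError):
    """A network has no interaction events, so matrix metrics are undefined."""
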