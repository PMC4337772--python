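"""Exception hierarchy for envtrack."""


class EnvTrackError(Exception):
    """Base class for all envtrack errors."""


class ValidationError(EnvTrackError):
    """Input data or configuration violates a contract."""


class OutOfDomainError(EnvTrackError):
    """A query point lies outside a variable's spatial or temporal domain."""


class ProjectionDomainError(EnvTrackError):
    """A point lies outside a projection's valid domain."""


class UndefinedBearingError(EnvTrackError):
    """Bearing requested between coincident points."""


class RequestError(EnvTrackError):
    """An annotation request failed validation.

    Carries the full list of failures, not just the first.
    """

    def __init__(self, failures):
        if isinstance(failures, str):
            failures = [failures]
        self.failures = list(failures)
        super().__init__("; ".join(self.failures))


class FetchError(EnvTrackError):
    """A scene provider failed after the configured retries."""

    def __init__(self, key, cause=None):
        self.key = key
        self.cause = cause
        super().__init__(f"could not materialize scene {key!r}: {cause}")
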