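"""Exception types shared across the package."""


class EcochgError(Exception):
    """Base class for all package-specific errors."""


class DegenerateCycleError(EcochgError):
    """Raised when a cycle is constant or has no usable fundamental."""


class InsufficientSteadyStateError(EcochgError):
    """Raised when a tone burst is too short for the steady-state window."""


class ManifestError(EcochgError):
    """Raised for missing or inconsistent recording/cohort manifests."""
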