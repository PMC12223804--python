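"""Exception hierarchy for weighted-ensemble bookkeeping errors."""


class MablweError(Exception):
    """Base class for all package errors."""


class ConservationError(MablweError):
    """Total walker weight drifted away from 1.

    Carries the observed sum and, when known, the iteration at which the
    violation was detected.
    """

    def __init__(self, observed_sum: float, iteration: int | None = None):
        self.observed_sum = observed_sum
        self.iteration = iteration
        where = f" at iteration {iteration}" if iteration is not None else ""
        super().__init__(
            f"walker weights sum to {observed_sum!r}{where}, expected 1"
        )


class ConfigError(MablweError):
    """Invalid or inconsistent run configuration."""


class PropagationError(MablweError):
    """Propagator payload incompatible with the walkers handed to it."""


class LookupError_(MablweError):
    """Unknown walker id or coordinate name in a run record."""


class ArchiveFormatError(MablweError):
    """Run archive has an unsupported schema version or layout."""
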