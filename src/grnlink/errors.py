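"""Exception hierarchy; the CLI maps these onto exit codes."""


class GrnlinkError(Exception):
    """Base class for all package errors."""


class ParseError(GrnlinkError):
    """A file could not be parsed in its declared format."""


class StructuralError(GrnlinkError):
    """Inputs parse but violate a structural invariant (dimensions, duplicates,
    conflicting labels, empty intersections, exhausted candidate sets...)."""


class UsageError(GrnlinkError):
    """The caller violated an API contract (mismatched shapes, unknown genes,
    untrained model...)."""


class ConfigError(GrnlinkError):
    """An invalid hyperparameter configuration."""


class TrainingError(GrnlinkError):
    """Optimization failed numerically (non-finite loss)."""


class SimulationError(GrnlinkError):
    """The synthetic dynamics produced non-finite values."""


class UndefinedMetricError(GrnlinkError):
    """A metric is undefined for the given labels (e.g. single-class AUROC)."""
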