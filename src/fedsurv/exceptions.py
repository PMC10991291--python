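"""Exception hierarchy for fedsurv.

Every error raised deliberately by the package derives from
:class:`FedsurvError`, so callers can catch the package's failures without
swallowing programming errors.
"""


class FedsurvError(Exception):
    """Base class for all fedsurv errors."""


class SchemaError(FedsurvError):
    """A required column is missing or misnamed in an input table."""


class DataValidationError(FedsurvError):
    """A row violates a dataset invariant (e.g. non-positive survival time)."""


class EmptyDatasetError(FedsurvError):
    """No usable rows remain after loading/filtering."""


class ParameterError(FedsurvError):
    """An argument is outside its documented domain."""


class SizeError(FedsurvError):
    """An input is too small (or too large) for the requested operation."""


class MergeError(FedsurvError):
    """Aggregates with incompatible shapes or encodings cannot be merged."""


class DispatchError(FedsurvError):
    """A federated task name is not registered with the orchestrator."""


class RoundError(FedsurvError):
    """A node failed during a federated round; carries the node id."""

    def __init__(self, node_id: str, message: str):
        self.node_id = node_id
        super().__init__(f"node '{node_id}': {message}")


class DegenerateNodeError(FedsurvError):
    """A node has no observed events and cannot contribute to a Cox fit."""


class ConvergenceError(FedsurvError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        self.trace = trace if trace is not None else []
        super().__init__(message)


class MonotoneLikelihoodError(FedsurvError):
    """Coefficients diverged, the classic signature of monotone likelihood."""


class CollinearityError(FedsurvError):
    """The information matrix is singular (collinear features)."""


class UndefinedMetricError(FedsurvError):
    """A metric has no defined value (e.g. no comparable survival pairs)."""


class SelectionError(FedsurvError):
    """No candidate feature set could be evaluated successfully."""


class ConfigError(FedsurvError):
    """A simulation or pipeline configuration is invalid or unattainable."""
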