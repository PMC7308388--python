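"""Exception hierarchy shared across the package."""


class NumsenseError(Exception):
    """Base class for package-specific failures."""


class InvalidArgumentError(NumsenseError, ValueError):
    """A caller violated a documented precondition."""


class PlacementInfeasibleError(NumsenseError, RuntimeError):
    """Dot placement failed after the configured number of retries."""


class SamplingInfeasibleError(NumsenseError, RuntimeError):
    """A trial-pair quota cannot be satisfied from the available stimuli."""


class FitFailureError(NumsenseError, RuntimeError):
    """Choice-model optimisation did not converge."""


class DivergenceError(NumsenseError, RuntimeError):
    """Network weights became non-finite during training."""


class UndefinedAcuityError(NumsenseError, ValueError):
    """Weber fraction requested for a non-positive numerosity coefficient."""


class InvalidComparisonError(NumsenseError, ValueError):
    """Readout protocols differ between conditions that must share one."""


class DependencyError(NumsenseError, RuntimeError):
    """A pipeline stage is missing an upstream artifact."""
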