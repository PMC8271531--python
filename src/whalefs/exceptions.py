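"""Exception hierarchy for whalefs.

All argument-contract violations derive from :class:`ValueError` so callers
can treat them uniformly; the more specific classes exist so that failure
modes the library documents (zero-probability categories, degenerate splits,
undefined metric denominators) are distinguishable in tests and pipelines.
"""


class WhaleFSError(Exception):
    """Base class for whalefs-specific errors."""


class DimensionMismatchError(WhaleFSError, ValueError):
    """Vectors that must share a dimension do not."""


class EvaluationError(WhaleFSError, RuntimeError):
    """An objective function returned a non-finite value."""


class UndefinedMetricError(WhaleFSError, ZeroDivisionError):
    """A metric's denominator is zero; the value is undefined, not 0."""


class ZeroProbabilityError(WhaleFSError, ValueError):
    """A categorical value has zero likelihood and smoothing is disabled.

    This is the classic naive-Bayes failure: a category present at predict
    time but absent from the training frequency table makes every posterior
    zero and prediction impossible.
    """


class DegenerateVarianceError(WhaleFSError, ValueError):
    """A continuous feature is constant within every class and the variance
    floor is disabled."""


class SplitError(WhaleFSError, ValueError):
    """A train/test split cannot honour its contract (e.g. singleton class
    under stratification, or a class absent from the training part)."""


class DatasetParseError(WhaleFSError, ValueError):
    """A CSV dataset could not be parsed into a valid Dataset."""
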