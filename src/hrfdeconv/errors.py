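"""Exception and warning hierarchy.

Recoverable per-channel failures (conditioning, time limit) raise
:class:`ChannelDroppedError` so a caller iterating over a montage can drop the
channel and continue; everything else derives from :class:`HrfError`.
"""


class HrfError(Exception):
    """Base class for all package errors."""


class ValidationError(HrfError, ValueError):
    """Input violates a documented precondition."""


class DimensionError(ValidationError):
    """Array shapes are incompatible (e.g. kernel longer than signal)."""


class ConditioningError(HrfError):
    """The regularized normal equations are singular or ill-conditioned."""


class ChannelDroppedError(HrfError):
    """Channel excluded: deconvolution failed to converge (conditioning or
    time limit). Recoverable — the caller skips the channel."""


class NoEventsError(ValidationError):
    """Event train is empty, or all events fell off the scan after shifting."""


class DegenerateHRFError(HrfError):
    """Kernel has no usable extremum (all zero) and cannot be peak-scaled."""


class UndefinedMomentsError(HrfError):
    """Skewness/kurtosis requested for a zero-variance signal."""


class DuplicateEntryError(HrfError):
    """A (doi, channel_id) key is already present in the store."""


class MergeConflictError(HrfError):
    """Key collision while merging two stores under the 'error' policy."""

    def __init__(self, keys):
        self.keys = list(keys)
        super().__init__(f"merge conflict on keys: {self.keys}")


class FormatError(HrfError):
    """A serialized store violates the JSON schema.

    The message carries the path to the offending field.
    """


class DegenerateSignalWarning(UserWarning):
    """Zero-variance signal z-scored to all zeros."""


class EdgeClipWarning(UserWarning):
    """Events shifted to negative indices during edge expansion were dropped."""


class ExtrapolationWarning(UserWarning):
    """Resampling grid extends beyond the source support; clamped to endpoint."""


class ShortSignalWarning(UserWarning):
    """Signal too short to resolve the lowest band frequency reliably."""
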