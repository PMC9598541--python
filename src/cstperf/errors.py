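"""Exception hierarchy for the cstperf pipeline.

Every error raised on a user-facing code path derives from
:class:`CstperfError` so callers can catch pipeline failures wholesale.
"""


class CstperfError(Exception):
    """Base class for all cstperf errors."""


class LabelTableError(CstperfError):
    """A label volume contains ids that the label table does not describe."""


class FormatError(CstperfError):
    """A volume on disk is not in the expected NIfTI layout."""


class ConfigurationError(CstperfError):
    """A merge rule set or preset is incomplete or inconsistent."""


class GeometryError(CstperfError):
    """Two volumes that must share a grid/affine do not."""


class EmptyRoiError(CstperfError):
    """A compartment contains no voxels."""


class PairingError(CstperfError):
    """Ictal/inter-ictal volumes do not belong to the same subject/grid."""


class InsufficientControlsError(CstperfError):
    """The control pool cannot satisfy the matching policy."""


class DegenerateCohortError(CstperfError):
    """Control values have zero variance; the t statistic is undefined."""


class InsufficientDataError(CstperfError):
    """Too few control values for a single-case comparison."""


class CompletenessError(CstperfError):
    """A status table does not cover all 36 compartments (x2 measures)."""


class InsufficientEventsError(CstperfError):
    """Not enough events (EMG onsets / complexes) for the requested analysis."""
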