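"""Exception hierarchy for rhythmkit.

All errors derive from :class:`RhythmkitError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
bad inputs (parsing, schema, validation) from requests the data cannot
support (too few onsets/IOIs) and from bad analysis settings.
"""


class RhythmkitError(Exception):
    """Base class for all rhythmkit errors."""


class InsufficientDataError(RhythmkitError, ValueError):
    """A sequence is too short for the requested statistic."""


class ParseError(RhythmkitError, ValueError):
    """A label file or table could not be parsed; carries row context."""


class SchemaError(RhythmkitError, ValueError):
    """An input table is missing required columns."""


class ValidationError(RhythmkitError, ValueError):
    """Input values violate a domain invariant (e.g. non-positive IOI)."""


class ConfigurationError(RhythmkitError, ValueError):
    """Analysis settings are incompatible with the data (e.g. f_max > Nyquist)."""
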