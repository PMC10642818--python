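"""Exception hierarchy for hapstruct."""


class HapstructError(Exception):
    """Base class for all package-specific errors."""


class InputError(HapstructError, ValueError):
    """Malformed or inconsistent user input (files, metadata, tables)."""


class AlignmentError(InputError):
    """Sequences that do not form a valid alignment (e.g. ragged rows)."""


class CleaningError(HapstructError):
    """Alignment cleaning left nothing usable."""


class MissingDataError(HapstructError):
    """No comparable sites between two sequences."""


class SaturationError(HapstructError):
    """Substitution saturation: the distance formula's log argument is <= 0."""


class InsufficientSampleError(HapstructError):
    """A region or group has too few samples for the requested statistic."""
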