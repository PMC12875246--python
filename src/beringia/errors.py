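"""Exception hierarchy shared across the package."""


class BeringiaError(Exception):
    """Base class for all package-specific errors."""


class InputError(BeringiaError):
    """Malformed or out-of-domain user input (files, values, names)."""


class AlignmentError(InputError):
    """Sequences that should form an alignment do not (length mismatch etc.)."""


class ConfigError(BeringiaError):
    """Invalid or incomplete run configuration (missing rates, bad bounds)."""


class StatisticError(BeringiaError):
    """A statistic is undefined on the given data (e.g. < 2 sequences)."""


class SaturationError(StatisticError):
    """Observed divergence beyond the range a distance correction can invert."""
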