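"""Exception hierarchy.

All package-specific failures derive from :class:`MitomixerError` so callers
can catch one base class; parameter problems additionally derive from
``ValueError`` and file-content problems from ``RuntimeError`` where that is
the idiomatic builtin.
"""


class MitomixerError(Exception):
    """Base class for all mitomixer errors."""


class InvalidParameterError(MitomixerError, ValueError):
    """A numeric or structural parameter violates its documented domain."""


class ConfigurationError(MitomixerError, ValueError):
    """A run/simulation configuration is inconsistent or incomplete."""


class FormatError(MitomixerError, RuntimeError):
    """An input file does not conform to the expected format."""


class ContentError(MitomixerError, RuntimeError):
    """An input file parses but contains disallowed content (e.g. N bases)."""


class AlignmentRequiredError(MitomixerError, ValueError):
    """Haplotypes of unequal length: substitution-only comparison impossible."""


class ReferenceMismatchError(MitomixerError, ValueError):
    """Alignment header does not match the supplied reference genome."""


class SaturationError(MitomixerError, ValueError):
    """Every dPCR partition is positive; Poisson occupancy is undefined."""


class UndefinedHeteroplasmyError(MitomixerError, ZeroDivisionError):
    """Total copy number is zero; deletion heteroplasmy is undefined."""


class UndefinedFractionError(MitomixerError, ZeroDivisionError):
    """Both dual-probe channels are empty; allele fraction is undefined."""


class NoInformativeSitesError(MitomixerError, ValueError):
    """No SNP passed filters; the mixture fraction cannot be estimated."""


class CalibrationError(MitomixerError, ValueError):
    """The fluorescence panel lacks usable fully-exogenous calibration cells."""
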