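"""Exception types shared across the pipeline."""


class VigimrError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VigimrError):
    """An invalid simulation or analysis configuration."""


class NoInstrumentsError(VigimrError):
    """Instrument selection retained zero SNPs."""


class HarmonizationError(VigimrError):
    """Allele harmonization retained zero SNPs."""


class FitError(VigimrError):
    """A model fit failed or was refused (too few observations, no convergence)."""


class EmptyInputError(VigimrError):
    """An operation whose result is undefined on empty input received one."""
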