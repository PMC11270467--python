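"""Exception hierarchy.

All readers and statistical entry points raise subclasses of
:class:`MethylzygError`; invalid values are rejected, never repaired.
"""


class MethylzygError(Exception):
    """Base class for all package errors."""


class FormatError(MethylzygError):
    """A file does not conform to its declared format."""


class ValidationError(MethylzygError):
    """A value violates a domain invariant (range, uniqueness, role)."""


class ConfigError(MethylzygError):
    """An infeasible or inconsistent configuration."""


class DegenerateMixtureError(MethylzygError):
    """The bulk-mixture denominator is zero (no tumour and no normal DNA)."""


class UndefinedCorrectionError(MethylzygError):
    """Purity/copy-number correction is undefined (rho = 0 or n_t = 0)."""


class UndefinedTestError(MethylzygError):
    """A statistical test is undefined on the given data (e.g. all ties)."""
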