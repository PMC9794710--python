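"""Exception hierarchy shared across the toolkit."""


class ChalqsarError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ChalqsarError):
    """An input table or file does not match its declared schema."""


class StructureError(ChalqsarError):
    """A SMILES/SDF record could not be parsed into a valid molecule."""


class CensoringError(ChalqsarError):
    """An arithmetic operation cannot honour a censored (">") value."""


class DomainError(ChalqsarError):
    """An argument lies outside the mathematical domain of an operation."""


class DescriptorError(ChalqsarError):
    """A molecular descriptor is undefined for the given structure."""


class CollinearityError(ChalqsarError):
    """The design matrix is rank deficient."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class SizeError(ChalqsarError):
    """Not enough rows/levels for the requested fit or split."""


class DesignError(ChalqsarError):
    """An experimental design lacks required levels (e.g. no I=0 series)."""


class ResidualActivityError(ChalqsarError):
    """Dose-response screening rule: no point falls below half of the top."""


class SaturationError(ChalqsarError):
    """PAMPA acceptor concentration at/above equilibrium; Pe undefined."""
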