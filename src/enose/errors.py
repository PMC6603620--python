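"""Exception hierarchy shared across the pipeline stages."""


class EnoseError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(EnoseError):
    """A table or feature matrix does not match the expected schema."""


class ConfigError(EnoseError):
    """A configuration value is out of its admissible range."""


class DomainError(EnoseError):
    """An input value lies outside the mathematical domain of an operation."""


class AmbientEnvelopeError(EnoseError):
    """Ambient (temperature, humidity) conditions fall outside the range where
    the polynomial compensation denominator stays positive."""


class InvalidReadingError(EnoseError):
    """A voltage or resistance reading is physically impossible for the
    load-resistor divider (e.g. v_out outside the open interval (0, v_cc))."""


class DegenerateFeatureError(EnoseError):
    """A feature column is constant, so min-max normalization is undefined."""


class CollinearityError(EnoseError):
    """The regression design matrix is numerically rank-deficient."""


class EmptyOutputError(EnoseError):
    """An operation (e.g. warm-up trimming) would leave no data."""
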