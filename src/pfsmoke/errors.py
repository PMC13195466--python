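"""Exception hierarchy used across the pipeline."""


class PFSmokeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PFSmokeError, ValueError):
    """A parameter or configuration value is invalid."""


class InputError(PFSmokeError, ValueError):
    """Input data are malformed or mutually inconsistent."""


class DegenerateInputError(PFSmokeError, ValueError):
    """Input data are formally valid but leave the operation undefined."""
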