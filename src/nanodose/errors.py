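"""Exception types shared across the package."""


class NanodoseError(Exception):
    """Base class for all package errors."""


class InvalidConfigurationError(NanodoseError, ValueError):
    """A user-supplied configuration value is out of range or unknown."""


class InvalidStateError(NanodoseError, RuntimeError):
    """An object is in a state in which the requested operation is undefined."""


class InvalidInputError(NanodoseError, ValueError):
    """Inputs to an operation are inconsistent with each other."""


class EnergyRangeError(InvalidInputError):
    """A photon energy falls outside the tabulated 1-300 keV coverage."""
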