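"""Exception types shared across the package."""


class AudiomotorError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AudiomotorError, ValueError):
    """A generator or analysis parameter is outside its valid range."""


class InvalidInputError(AudiomotorError, ValueError):
    """An input signal or table violates a precondition."""


class NoPeakError(AudiomotorError, RuntimeError):
    """No spectral peak exists in the requested frequency range."""


class NumericalError(AudiomotorError, RuntimeError):
    """A numerical routine (quadrature, rotation) failed to converge."""
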