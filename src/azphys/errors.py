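"""Exception types shared across the package."""


class AzphysError(Exception):
    """Base class for all azphys errors."""


class InvalidParameterError(AzphysError, ValueError):
    """A physical parameter is outside its valid domain."""


class WindowError(AzphysError, ValueError):
    """An analysis window is empty, misaligned, or collides with an
    invalid region (pulse, stimulus artifact, dead time)."""


class FitError(AzphysError, RuntimeError):
    """A least-squares fit failed to converge or is degenerate."""


class NonPhysicalError(AzphysError, ValueError):
    """Measured admittance admits no physical three-element circuit."""


class GenerationError(AzphysError, RuntimeError):
    """A synthetic scene could not be realised under its constraints."""
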