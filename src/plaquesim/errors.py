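"""Exception types shared across the simulator."""


class PlaqueSimError(Exception):
    """Base class for all simulator errors."""


class InvalidParameterError(PlaqueSimError, ValueError):
    """A physical parameter is out of its admissible range."""


class DomainError(PlaqueSimError, ValueError):
    """A geometric specification falls outside the computational domain."""


class FormatError(PlaqueSimError, ValueError):
    """An imported file violates the expected tabular layout."""


class ConfigurationError(PlaqueSimError, ValueError):
    """A configuration file is malformed or inconsistent."""


class SolverError(PlaqueSimError, RuntimeError):
    """A numerical solve failed to converge or blew up."""
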