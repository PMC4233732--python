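"""Exception hierarchy.

Distinct classes let the CLI map failure kinds to exit codes: configuration
problems, malformed input files, degenerate geometry, and simulation set-up
errors are separate failure modes.
"""


class JawsimError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(JawsimError, ValueError):
    """A numeric argument violates its physical precondition."""


class ConfigError(JawsimError, ValueError):
    """A run configuration is inconsistent or incomplete."""


class SchemaError(JawsimError, ValueError):
    """An input table violates the documented column/row schema."""


class GeometryError(JawsimError, ValueError):
    """Degenerate geometry: zero-length segments, non-watertight meshes, ..."""


class SimulationSetupError(JawsimError, RuntimeError):
    """A simulation cannot be assembled (e.g. the jaw never contacts the bolus)."""
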