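"""Exception hierarchy shared by all biomag modules.

``ConfigError`` marks invalid user input (bad geometry, units, missing fields);
``DomainError`` marks a mathematically invalid evaluation (elliptic modulus out
of range, dipole field at z <= 0, ...); ``SingularityError`` marks evaluation on
or too close to a current filament.  The CLI maps ``ConfigError`` to exit code 2
and the numerical errors to exit code 3.
"""


class BiomagError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(BiomagError, ValueError):
    """Invalid configuration value or file."""


class DomainError(BiomagError, ValueError):
    """Evaluation requested outside the mathematical domain of an operation."""


class SingularityError(DomainError):
    """Field evaluation on (or within one wire diameter of) a current filament."""


class NonConvergenceError(DomainError):
    """An iterative simulation failed to reach its target state."""
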