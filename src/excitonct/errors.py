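"""Exception hierarchy.

All package errors derive from ExcitonCTError so callers (and the CLI exit-code
mapping) can distinguish input problems from numerical failures.
"""


class ExcitonCTError(Exception):
    """Base class for all package errors."""


class InputError(ExcitonCTError):
    """Malformed or inconsistent user input (CLI exit code 2)."""


class InvalidParameterError(InputError):
    """A parameter outside its mathematical domain (e.g. non-positive exponent)."""


class ConfigurationError(InputError):
    """A label, role or option that cannot be resolved."""


class ParseError(InputError):
    """Malformed file content; carries a line number where possible."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NumericalError(ExcitonCTError):
    """Numerical failure (CLI exit code 3)."""


class NearLinearDependenceError(NumericalError):
    """Union basis close to linear dependence; names the offending orbital pair."""


class SingularityError(NumericalError):
    """Coincident points where a Coulomb kernel diverges."""


class OverlapDomainError(NumericalError):
    """|S01| >= 1 in a two-state Marcus expression."""


class MetricError(NumericalError):
    """Diabatic overlap matrix not positive definite."""


class PolarizationCatastropheError(NumericalError):
    """Singular induced-dipole response matrix; suggests enabling Thole damping."""


class SizeError(InputError):
    """Orbital space too large for a combinatorial oracle."""


class AssemblyError(InputError):
    """Missing block entry during diabatic-matrix assembly; names the block."""
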