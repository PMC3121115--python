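"""Exception hierarchy shared across the package."""


class SsimodError(Exception):
    """Base class for all package errors."""


class StructuralError(SsimodError):
    """A module definition contains unresolvable references or malformed pieces.

    Distinct from a validation-clause violation: a structurally broken module
    cannot even be checked against the module-definition clauses.
    """


class DomainError(SsimodError, ValueError):
    """A kinetic quantity lies outside its admissible domain (negative
    concentration, non-positive constant, Hill coefficient < 1)."""


class ConfigurationError(SsimodError):
    """A parameter required by the model is missing or inconsistent."""


class UnsupportedModuleError(SsimodError):
    """The module falls outside the scope of the implemented theory
    (e.g. a reaction with more than one inhibitor, or an inhibitor that is
    an input/output node)."""


class ModuleValidationError(SsimodError):
    """Raised when a module fails validation; carries the report."""

    def __init__(self, report):
        self.report = report
        super().__init__(str(report))
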