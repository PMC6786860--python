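"""Exception hierarchy shared across the package."""


class EqspikeError(Exception):
    """Base class for all errors raised by eqspike."""


class DimensionMismatch(EqspikeError):
    """Two quantities with incompatible physical dimensions were combined."""

    def __init__(self, message, dim_a=None, dim_b=None):
        super().__init__(message)
        self.dim_a = dim_a
        self.dim_b = dim_b


class UnknownUnit(EqspikeError):
    """A unit name not present in the registry was used."""


class EquationError(EqspikeError):
    """Malformed model description text."""


class DuplicateDefinition(EquationError):
    """The same variable was defined twice, or shadows a unit/function."""


class IllegalFlag(EquationError):
    """A flag was used on an entry kind that does not admit it."""


class UnresolvedIdentifier(EqspikeError):
    """An expression references a name that nothing in scope defines."""

    def __init__(self, names, context=""):
        self.names = sorted(set(names))
        msg = "unresolved identifier(s): " + ", ".join(self.names)
        if context:
            msg += f" (in {context})"
        super().__init__(msg)


class CyclicDependency(EquationError):
    """Subexpressions depend on each other in a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("cyclic subexpression dependency: " + " -> ".join(self.cycle))


class IllegalNoise(EquationError):
    """The noise symbol xi appears where it is not allowed."""


class AssignmentToConstant(EqspikeError):
    """A statement tried to write a constant or read-only variable."""


class WriteToLinked(EqspikeError):
    """A linked variable was written through the target group."""


class NameCollision(EqspikeError):
    """A function/variable name is already bound."""


class IntegrationError(EqspikeError):
    """State became non-finite (or the update could not be computed)."""


class RestoreWithoutStore(EqspikeError):
    """restore() called for a snapshot name that was never stored."""


class SummedTargetCollision(EqspikeError):
    """Two synapse populations sum into the same target variable."""
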