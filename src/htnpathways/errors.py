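"""Exception hierarchy shared across the package."""


class HtnPathwaysError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HtnPathwaysError):
    """A simulation or pipeline configuration field is invalid."""


class BundleValidationError(HtnPathwaysError):
    """A table bundle violates the format contract (bad enum token, orphan id, ...)."""

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(str(v) for v in self.violations[:5])
        if len(self.violations) > 5:
            msg += f"; ... ({len(self.violations)} violations total)"
        super().__init__(msg)


class IntegrityError(HtnPathwaysError):
    """An internal consistency contract was broken (should be unreachable)."""


class SeparationError(HtnPathwaysError):
    """A logistic fit failed due to (quasi-)complete separation."""

    def __init__(self, message, terms=()):
        self.terms = tuple(terms)
        super().__init__(message)


class RareEventError(HtnPathwaysError):
    """A 2x2 table has an empty cell and no continuity correction was requested."""
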