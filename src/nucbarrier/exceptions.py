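"""Exception hierarchy shared by all analysis stages."""


class NucbarrierError(Exception):
    """Base class for package-specific failures."""


class DomainError(NucbarrierError, ValueError):
    """Input outside the physically meaningful domain (e.g. negative force)."""


class ValidationError(NucbarrierError, ValueError):
    """Malformed parameters, records, or incompatible array shapes."""


class FitError(NucbarrierError, RuntimeError):
    """Nonlinear fit failed or the problem is under-determined."""


class AlignmentError(NucbarrierError, RuntimeError):
    """Trace alignment/registration could not be established."""


class ConvergenceError(NucbarrierError, RuntimeError):
    """Numerical routine (quadrature, optimizer, EM) failed to converge."""
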