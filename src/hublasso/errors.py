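"""Exception types shared across the package."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to converge within its iteration budget.

    Parameters
    ----------
    message : str
        Human-readable description.
    n_iter : int, optional
        Number of iterations performed before giving up.
    trace : list of float, optional
        Objective values recorded per iteration, when available.
    """

    def __init__(self, message, n_iter=None, trace=None, fatal=False):
        super().__init__(message)
        self.n_iter = n_iter
        self.trace = trace
        #: True when retrying (or continuing to harder problems) cannot help,
        #: e.g. the solution is provably infeasible rather than unconverged
        self.fatal = fatal


class InvalidPrecisionError(ValueError):
    """A precision matrix violates positive-definiteness requirements."""
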