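"""Solver exceptions shared across the equilibrium modules."""


class NoEquilibriumError(RuntimeError):
    """No equilibrium exists for the requested pressure (beyond a limit point)."""


class SolverError(RuntimeError):
    """A root-finding or bracketing step failed to converge."""
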