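"""Exception hierarchy.

All package errors derive from :class:`MCTBenchError` so callers can catch one
base class; input-shape problems and degenerate data are distinguished because
simulation code treats them differently (a bad design is a bug, a zero-variance
draw is a loggable event).
"""


class MCTBenchError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MCTBenchError, ValueError):
    """Input violates a precondition (group counts, probability ranges, ...)."""


class DegenerateVarianceError(MCTBenchError, ValueError):
    """Within-group variance is zero; pairwise tests are undefined."""


class InvalidConfigError(MCTBenchError, ValueError):
    """Study configuration violates the design-grid invariants."""
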