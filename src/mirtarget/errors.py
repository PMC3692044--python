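"""Exception hierarchy.

``DataError`` marks problems in user-supplied data (bad FASTA, malformed
newick, inconsistent tables); the CLI maps it to exit code 3. ``UsageError``
style problems are left to click (exit code 2).
"""


class MirtargetError(Exception):
    """Base class for all package errors."""


class DataError(MirtargetError, ValueError):
    """Invalid or inconsistent input data."""


class OptimizationError(MirtargetError, RuntimeError):
    """A numerical optimizer failed to converge; carries diagnostics."""
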