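"""Exception hierarchy for fepbench.

All validation problems raise :class:`InputError` (a ``ValueError``), so user
code can catch one type for malformed inputs regardless of the stage.
"""


class FepbenchError(Exception):
    """Base class for all fepbench errors."""


class InputError(FepbenchError, ValueError):
    """Invalid or malformed input data."""


class ConvergenceError(FepbenchError, RuntimeError):
    """An iterative solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PathError(FepbenchError):
    """No path between two ligands within the allowed number of edges."""


class ConfigurationError(FepbenchError):
    """A request that is undefined for the given data (e.g. an ambiguous
    conformer-selection rule or a reference ligand without experimental
    data)."""


class UndefinedMetricError(FepbenchError, ValueError):
    """A quality metric is undefined for the given data (zero variance,
    all-tied ranks, ...)."""


class DataCorruptionError(FepbenchError):
    """A packaged fixture file does not match its recorded checksum."""
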