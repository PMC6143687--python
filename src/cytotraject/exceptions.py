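"""Exception hierarchy.

Two broad families matter to callers (and to the CLI exit codes):
``ConfigError`` for problems in parameters, rules or configuration files,
and ``DataError`` for problems in the data itself.
"""


class CytotrajectError(Exception):
    """Base class for all package errors."""


class ConfigError(CytotrajectError):
    """Invalid parameter, rule, cutpoint or configuration file."""


class DataError(CytotrajectError):
    """Invalid, inconsistent or insufficient input data."""


class SchemaError(DataError):
    """Panel / column structure does not match expectations."""


class TransformStateError(DataError):
    """Operation incompatible with the table's transform state."""


class EmptySelectionError(DataError):
    """A selection (e.g. by population label) matched no cells."""


class InsufficientDataError(DataError):
    """Too few cells (or time-points) for the requested operation."""


class DegenerateInputError(DataError):
    """Zero-variance or otherwise degenerate numeric input."""


class IsolatedPointError(DataError):
    """Cells with no kernel connectivity to the rest of the graph."""

    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(
            f"{len(self.indices)} isolated cell(s) with all-zero kernel rows: "
            f"{self.indices[:10]}{'...' if len(self.indices) > 10 else ''}"
        )
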