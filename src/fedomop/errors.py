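"""Exception hierarchy shared across the toolkit.

Disclosure errors are deliberately terse: they may name the object that was
withheld but never the sub-threshold counts or person identifiers behind the
refusal.
"""


class FedOmopError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(FedOmopError):
    """A table or column does not exist, or the schema is malformed/empty."""


class UnreachableTableError(SchemaError):
    """No join path connects the two requested tables."""


class DatabaseConnectionError(FedOmopError):
    """The database could not be opened or queried at connection time."""


class RetrievalError(FedOmopError):
    """A read query failed; the message names the offending table."""


class UsageError(FedOmopError):
    """The operation was invoked with arguments that cannot be honoured."""


class ConfigurationError(FedOmopError):
    """Invalid generator or run configuration, raised before any side effect."""


class DisclosureError(FedOmopError):
    """Output withheld by disclosure control.

    Messages name the refused object only — never counts below the subset
    threshold and never person identifiers.
    """


class DataError(FedOmopError):
    """Row-level content violates the operation's contract (bad dates,
    non-binary outcome, ...)."""


class StructuralError(FedOmopError):
    """A person-keyed table breaks the one-row-per-person contract."""


class RankDeficiencyError(FedOmopError):
    """The summed information matrix is singular; names the collinear
    design columns."""

    def __init__(self, columns):
        self.columns = tuple(columns)
        super().__init__(
            "singular information matrix; collinear columns: "
            + ", ".join(self.columns)
        )
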