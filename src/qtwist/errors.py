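"""Exception hierarchy for trial-data validation and analysis errors."""


class QTwistError(ValueError):
    """Base class for all qtwist errors."""


class SchemaError(QTwistError):
    """A required column is missing or a cell cannot be parsed."""


class ReferentialError(QTwistError):
    """An adverse-event row references a subject that does not exist."""


class ConsistencyError(QTwistError):
    """Cross-field or cross-table constraint violated (e.g. PFS > OS)."""
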