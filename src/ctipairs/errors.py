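"""Exception hierarchy for store access and pipeline consistency failures."""


class CtipairsError(Exception):
    """Base class for all package-specific errors."""


class StoreError(CtipairsError, IOError):
    """The store file cannot be opened (missing, unreadable, not a database)."""


class SchemaError(CtipairsError):
    """The store is missing a table required by the pipeline."""


class VersionError(CtipairsError):
    """The requested ChEMBL release is not supported."""


class ConsistencyError(CtipairsError):
    """Source data violates a structural assumption (e.g. two parents)."""


class DataError(CtipairsError):
    """A value in the store is outside its documented domain."""
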