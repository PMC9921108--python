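"""Exception and warning types shared across the package."""


class MtqsarError(Exception):
    """Base class for all package errors."""


class MalformedSmilesError(MtqsarError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = "", row_id: str | None = None):
        self.smiles = smiles
        self.detail = detail
        self.row_id = row_id
        ctx = f" (row {row_id!r})" if row_id is not None else ""
        super().__init__(f"unparsable SMILES {smiles!r}{ctx}: {detail or 'invalid syntax'}")


class FormatError(MtqsarError):
    """A tabular input file violates the expected layout (columns, extension)."""


class RowError(MtqsarError):
    """A single table row is invalid; collected, not fatal."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class ConflictError(MtqsarError):
    """The same (compound, enzyme subclass) key carries contradictory labels."""

    def __init__(self, keys):
        self.keys = list(keys)
        super().__init__(f"conflicting labels for {len(self.keys)} key(s): {self.keys[:5]}")


class EmptyClassError(MtqsarError):
    """A requested enzyme subclass has no contributing records."""


class DegenerateInputError(MtqsarError):
    """Feature selection received only constant candidates."""


class LengthMismatchError(MtqsarError):
    """Paired sequences (labels, scores) differ in length."""


class DegenerateLabelsError(MtqsarError):
    """A ROC curve needs both classes present."""


class UnknownDescriptorError(MtqsarError):
    """Descriptor name not present in the registry."""


class UnknownColumnError(MtqsarError):
    """Requested table column does not exist."""


class VersionMismatchError(MtqsarError):
    """A model bundle was written with an incompatible schema or registry version."""


class InfeasibleConfigError(MtqsarError):
    """A synthetic-data configuration cannot be realized (e.g. pool too small)."""


class TruncationWarning(UserWarning):
    """A SMILES batch exceeded the row cap and was truncated."""


class DescriptorApplicabilityWarning(UserWarning):
    """A descriptor was not applicable to a molecule and a fill value was used."""
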