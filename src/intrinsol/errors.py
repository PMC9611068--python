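"""Exception hierarchy for intrinsol.

Every error raised by the package derives from :class:`IntrinsolError` so
callers (and the CLI) can distinguish domain failures from programming bugs.
"""


class IntrinsolError(Exception):
    """Base class for all intrinsol errors."""


class SmilesParseError(IntrinsolError, ValueError):
    """A SMILES string could not be parsed into a molecular graph."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"unparseable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class SchemaError(IntrinsolError, ValueError):
    """A tabular input violates the declared column schema."""


class UnitConversionError(IntrinsolError, ValueError):
    """A raw solubility entry cannot be converted to log molar units."""


class DescriptorUndefinedError(IntrinsolError, ValueError):
    """A descriptor is undefined for a molecule (recorded in the missing mask)."""

    def __init__(self, descriptor: str, reason: str):
        self.descriptor = descriptor
        self.reason = reason
        super().__init__(f"descriptor {descriptor} undefined: {reason}")


class MissingDescriptorError(IntrinsolError, KeyError):
    """A model prediction was requested without one of its descriptors."""

    def __init__(self, descriptor: str, model: str = ""):
        self.descriptor = descriptor
        where = f" for model {model}" if model else ""
        super().__init__(f"missing descriptor {descriptor!r}{where}")


class SingularDesignError(IntrinsolError, ValueError):
    """The regression design matrix is rank deficient."""

    def __init__(self, columns=(), detail: str = ""):
        self.columns = tuple(columns)
        msg = "singular design matrix"
        if self.columns:
            msg += f"; linearly dependent columns: {list(self.columns)}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class UndefinedStatisticError(IntrinsolError, ValueError):
    """A correlation statistic is undefined (e.g. zero variance)."""


class EmptySelectionError(IntrinsolError, ValueError):
    """A descriptor-selection workflow has no admissible descriptor."""


class RankError(IntrinsolError, ValueError):
    """Requested model size exceeds the rank of the descriptor matrix."""


class EmptyMatrixError(IntrinsolError, ValueError):
    """All descriptor columns were removed by prefiltering."""


class ConsensusUndefinedError(IntrinsolError, ValueError):
    """No consensus member could produce a prediction."""


class ArchiveError(IntrinsolError, ValueError):
    """A model archive is malformed or has an unknown schema version."""


class SyntheticSpecError(IntrinsolError, ValueError):
    """A synthetic-data specification is internally inconsistent."""
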