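"""Exception hierarchy shared across the package."""


class DrugRepoError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(DrugRepoError):
    """A tabular input file is structurally unusable (missing column, no valid rows)."""


class SmilesParseError(DrugRepoError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class FingerprintLengthError(DrugRepoError):
    """Two fingerprints of different fold lengths were compared."""


class EmptyTargetSetError(DrugRepoError):
    """An overlap score was requested for an empty target set."""


class EmptyGeneSetError(DrugRepoError):
    """Network proximity was requested for an empty gene set."""


class NoApprovedDrugError(DrugRepoError):
    """A disease has no approved drug usable for scoring."""

    def __init__(self, disease_id: str, reason: str = ""):
        self.disease_id = disease_id
        msg = f"no usable approved drug for disease {disease_id}"
        if reason:
            msg += f" ({reason})"
        super().__init__(msg)


class FixtureSpecError(DrugRepoError):
    """A synthetic-fixture specification cannot be satisfied."""
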