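"""Exception types shared across the pipeline stages."""


class PlantSdrError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(PlantSdrError):
    """A synthetic family/genome specification is inconsistent."""


class InvalidInputError(PlantSdrError):
    """An operation received an input violating its preconditions."""


class DegenerateModelError(PlantSdrError):
    """A seed alignment yields no usable match states."""


class CalibrationError(PlantSdrError):
    """Positive and decoy score ranges overlap; no cutoff separates them."""

    def __init__(self, min_positive: float, max_decoy: float):
        self.min_positive = min_positive
        self.max_decoy = max_decoy
        super().__init__(
            f"cannot calibrate: max decoy score {max_decoy:.2f} >= "
            f"min positive score {min_positive:.2f}"
        )


class SaturationError(PlantSdrError):
    """A p-distance of 1 cannot be Poisson-corrected."""


class MissingDistanceError(PlantSdrError):
    """A distance matrix entry needed for tree building is undefined."""


class EmptyFamilyError(PlantSdrError):
    """A family with an all-zero distribution row has no occurrence class."""


class DegenerateVarianceError(PlantSdrError):
    """PCA of a constant matrix is undefined."""


class ConfigurationError(PlantSdrError):
    """Whitelist/exclusion or pipeline configuration is contradictory."""


class FastaParseError(PlantSdrError):
    """Malformed FASTA record; carries the offending line number."""

    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"line {line}: {message}")
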