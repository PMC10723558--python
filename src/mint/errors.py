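"""Named exception types raised across the package."""


class MintError(Exception):
    """Base class for all package errors."""


class UnknownNutrientError(MintError, KeyError):
    """A nutrient key is not one of the 11 tracked nutrients."""


class NegativeAmountError(MintError, ValueError):
    """A nutrient amount is negative."""


class MissingNutrientError(MintError, ValueError):
    """A required nutrient is absent and no imputation policy is active."""


class UndefinedDenominatorError(MintError, ZeroDivisionError):
    """The mean restricted %DV is zero, so the density ratio is undefined."""


class EmptyCorpusError(MintError, ValueError):
    """An embedding training corpus contains no usable documents."""


class EmptyNameError(MintError, ValueError):
    """A food-item name is empty after text normalization."""


class EmptyVocabularyError(MintError, ValueError):
    """A synthetic category vocabulary or ingredient pool is empty."""


class UnknownBackendError(MintError, KeyError):
    """A sentence-encoder backend name is not registered."""


class TooFewPointsError(MintError, ValueError):
    """Not enough points to fit the clustering model."""


class SingleCategoryError(MintError, ValueError):
    """Category-predictor training needs at least two categories."""


class DimensionMismatchError(MintError, ValueError):
    """An input vector's dimension does not match the model's."""


class LengthMismatchError(MintError, ValueError):
    """Two paired sequences have different lengths."""


class EmptyInputError(MintError, ValueError):
    """An operation received an empty collection."""


class ZeroVarianceError(MintError, ValueError):
    """R^2 is undefined because the true values have zero variance."""


class ConfigError(MintError, ValueError):
    """A pipeline configuration failed validation."""


class StageError(MintError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
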