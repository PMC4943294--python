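"""Exception hierarchy for the PCNL blood-loss pipeline."""


class PCNLError(Exception):
    """Base class for all package errors."""


class SchemaError(PCNLError):
    """Input table does not match the documented CSV schema."""


class CohortValidationError(PCNLError):
    """One or more cohort rows violate a record invariant.

    Carries row-indexed diagnostics in ``.diagnostics`` (list of strings).
    """

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        super().__init__(
            "invalid cohort rows:\n" + "\n".join(self.diagnostics)
        )


class DomainError(PCNLError):
    """A numeric argument is outside its physiological/mathematical domain."""


class EstimationError(PCNLError):
    """Blood-loss estimation impossible for a patient (e.g. missing 72-h draw)."""


class UndefinedRatioError(PCNLError):
    """CT ratio requested for a cohort with zero transfused volume."""


class UndefinedCorrelationError(PCNLError):
    """Correlation requested against a constant (zero-variance) variable."""


class UnitMisuseError(PCNLError):
    """A hematocrit was passed on the wrong scale (fraction where percent expected)."""


class RankDeficiencyError(PCNLError):
    """Regression design matrix is rank deficient (collinear candidates)."""


class ConfigError(PCNLError):
    """Invalid configuration value."""
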