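"""Blood-loss prediction: bivariate screening, stepwise OLS, published model.

The modelling workflow mirrors common clinical-epidemiology practice:
candidate predictors are first screened one at a time against total
blood loss (Pearson for approximately normal variables, Spearman for
skewed ones) with a liberal entry rule p < 0.25, and survivors enter a
forward stepwise ordinary-least-squares fit (entry α = 0.05, removal
α = 0.10, both configurable).

The fixed published predictor for PCNL perioperative blood loss is

    TBL (mL) = −153.379 + 0.229 × stone burden (mm²)
                        + 0.203 × baseline serum hematocrit (%)

with hematocrit on the *percent* scale. :func:`predict_published`
guards that convention: a hematocrit in (0, 1) is rejected as a
fraction passed by mistake.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    DomainError,
    RankDeficiencyError,
    UndefinedCorrelationError,
    UnitMisuseError,
)

__all__ = [
    "PUBLISHED_INTERCEPT",
    "PUBLISHED_COEFFICIENTS",
    "SCREEN_ENTRY_P",
    "DEFAULT_SCREEN_METHODS",
    "ScreeningResult",
    "RegressionModel",
    "published_model",
    "predict_published",
    "bivariate_screen",
    "fit_ols",
    "fit_stepwise",
]

PUBLISHED_INTERCEPT = -153.379
#: Slopes of the published model: mL per mm² and mL per hematocrit percentage point.
PUBLISHED_COEFFICIENTS = {
    "stone_burden_mm2": 0.229,
    "baseline_hct_percent": 0.203,
}

#: Liberal bivariate entry rule for stepwise candidacy.
SCREEN_ENTRY_P = 0.25

#: Correlation method per candidate variable. Hematocrit and age are
#: treated as approximately normal (Pearson); the skewed counts and
#: chemistries use Spearman. Caller-overridable per variable.
DEFAULT_SCREEN_METHODS = {
    "stone_burden_mm2": "spearman",
    "n_stones": "spearman",
    "creatinine": "spearman",
    "rbc_count": "spearman",
    "baseline_hct_percent": "pearson",
    "hemoglobin": "spearman",
    "bmi": "spearman",
    "age": "pearson",
    "operative_time": "spearman",
}


@dataclass(frozen=True)
class ScreeningResult:
    """Bivariate correlation of one candidate with total blood loss."""

    variable: str
    method: str  # "pearson" | "spearman"
    r: float
    p: float

    @property
    def passes_entry(self) -> bool:
        return self.p < SCREEN_ENTRY_P


@dataclass(frozen=True)
class RegressionModel:
    """An affine TBL predictor with per-term inference.

    ``pvalues``, ``stderrs``, ``n`` and ``r_squared`` are ``None`` for
    the fixed published model (its inference is not reproducible
    without the raw study data).
    """

    intercept: float
    coefficients: Mapping[str, float]
    pvalues: Optional[Mapping[str, float]] = None
    stderrs: Optional[Mapping[str, float]] = None
    n: Optional[int] = None
    df_resid: Optional[int] = None
    r_squared: Optional[float] = None
    excluded: tuple[str, ...] = ()

    def conf_int(self, variable: str, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided (1 − alpha) t-based confidence interval for a slope."""
        if self.stderrs is None or self.df_resid is None:
            raise ValueError("confidence intervals require a fitted model")
        beta = self.coefficients[variable]
        half = stats.t.ppf(1 - alpha / 2, self.df_resid) * self.stderrs[variable]
        return beta - half, beta + half

    def predict(self, **covariates: float) -> float:
        """Evaluate the affine predictor; all model terms must be supplied."""
        missing = set(self.coefficients) - set(covariates)
        if missing:
            raise KeyError(f"missing covariates: {sorted(missing)}")
        return self.intercept + sum(
            beta * covariates[name] for name, beta in self.coefficients.items()
        )

    def equation(self, decimals: int = 3) -> str:
        terms = [f"{self.intercept:.{decimals}f}"]
        for name, beta in self.coefficients.items():
            terms.append(f"{beta:+.{decimals}f} × {name}")
        return "TBL (mL) = " + " ".join(terms)


def published_model() -> RegressionModel:
    """The fixed published PCNL blood-loss predictor."""
    return RegressionModel(
        intercept=PUBLISHED_INTERCEPT, coefficients=dict(PUBLISHED_COEFFICIENTS)
    )


def predict_published(stone_burden_mm2: float, baseline_hct_percent: float) -> float:
    """Predicted perioperative TBL (mL) from the published model.

    ``baseline_hct_percent`` must be on the percent scale; a value in
    (0, 1) looks like a fraction and raises :class:`UnitMisuseError`.
    Hematocrit exactly 0 is accepted as an out-of-domain extrapolation
    (the prediction degenerates toward the intercept). Full precision
    is returned; round to 2 decimals for reporting.
    """
    if stone_burden_mm2 < 0:
        raise DomainError(f"stone burden must be >= 0, got {stone_burden_mm2!r}")
    if 0.0 < baseline_hct_percent < 1.0:
        raise UnitMisuseError(
            f"baseline hematocrit {baseline_hct_percent!r} looks like a fraction; "
            "the published model expects percent (e.g. 40, not 0.40)"
        )
    if baseline_hct_percent < 0 or baseline_hct_percent >= 100:
        raise DomainError(
            f"baseline hematocrit must be in [0, 100) percent, got {baseline_hct_percent!r}"
        )
    return published_model().predict(
        stone_burden_mm2=stone_burden_mm2, baseline_hct_percent=baseline_hct_percent
    )


def bivariate_screen(
    df: pd.DataFrame,
    outcome: str = "tbl_ml",
    methods: Optional[Mapping[str, str]] = None,
) -> list[ScreeningResult]:
    """Screen each candidate column against the outcome, one at a time.

    ``methods`` maps variable → "pearson" | "spearman"; unspecified
    variables fall back to :data:`DEFAULT_SCREEN_METHODS`, then to
    Spearman. Every numeric column other than the outcome is screened.
    Rows with a missing value in a pair are dropped pairwise.
    """
    if outcome not in df.columns:
        raise KeyError(f"outcome column {outcome!r} not in frame")
    methods = {**DEFAULT_SCREEN_METHODS, **(methods or {})}
    results: list[ScreeningResult] = []
    for col in df.columns:
        if col == outcome or not pd.api.types.is_numeric_dtype(df[col]):
            continue
        pair = df[[col, outcome]].dropna()
        if len(pair) < 3:
            raise ValueError(f"variable {col!r}: need >= 3 complete pairs, have {len(pair)}")
        x = pair[col].to_numpy(dtype=float)
        y = pair[outcome].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise UndefinedCorrelationError(
                f"variable {col!r} is constant; correlation undefined"
            )
        method = methods.get(col, "spearman")
        if method == "pearson":
            r, p = stats.pearsonr(x, y)
        elif method == "spearman":
            r, p = stats.spearmanr(x, y)
        else:
            raise ValueError(f"unknown method {method!r} for variable {col!r}")
        results.append(ScreeningResult(variable=col, method=method, r=float(r), p=float(p)))
    return results


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def fit_ols(
    df: pd.DataFrame,
    outcome: str = "tbl_ml",
    terms: Optional[Sequence[str]] = None,
) -> RegressionModel:
    """Plain multivariable OLS of the outcome on the given terms."""
    if terms is None:
        terms = [
            c for c in df.columns if c != outcome and pd.api.types.is_numeric_dtype(df[c])
        ]
    terms = list(terms)
    data = df[[outcome, *terms]].dropna()
    fit = _ols(data[outcome].to_numpy(dtype=float), data[terms])
    return RegressionModel(
        intercept=float(fit.params["const"]),
        coefficients={c: float(fit.params[c]) for c in terms},
        pvalues={c: float(fit.pvalues[c]) for c in terms},
        stderrs={c: float(fit.bse[c]) for c in terms},
        n=len(data),
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
    )


def fit_stepwise(
    df: pd.DataFrame,
    outcome: str = "tbl_ml",
    candidates: Optional[Sequence[str]] = None,
    entry_alpha: float = 0.05,
    removal_alpha: float = 0.10,
) -> RegressionModel:
    """Forward stepwise OLS with backward pruning.

    At each step the candidate with the smallest p-value (given the
    current model) enters if p ≤ ``entry_alpha``; after each entry any
    included term with p > ``removal_alpha`` is pruned, worst first.
    Candidates that never enter are reported in ``excluded``. With no
    entering candidate the result is the intercept-only model.
    """
    if candidates is None:
        candidates = [
            c for c in df.columns if c != outcome and pd.api.types.is_numeric_dtype(df[c])
        ]
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate variables supplied")
    data = df[[outcome, *candidates]].dropna()
    n = len(data)
    if n <= len(candidates) + 1:
        raise ValueError(
            f"need n > n_candidates + 1, have n={n} for {len(candidates)} candidates"
        )
    X_full = data[candidates].to_numpy(dtype=float)
    design = np.column_stack([np.ones(n), X_full])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        offenders = _collinear_variables(data, candidates)
        raise RankDeficiencyError(
            f"candidate design is rank deficient (rank {rank} < {design.shape[1]}); "
            f"offending variables: {offenders}"
        )

    y = data[outcome].to_numpy(dtype=float)
    selected: list[str] = []
    while True:
        remaining = [c for c in candidates if c not in selected]
        if not remaining:
            break
        best, best_p = None, np.inf
        for cand in remaining:
            fit = _ols(y, data[selected + [cand]])
            p = fit.pvalues[cand]
            if p < best_p:
                best, best_p = cand, p
        if best is None or best_p > entry_alpha:
            break
        selected.append(best)
        # backward pruning of terms that lost significance
        while selected:
            fit = _ols(y, data[selected])
            pvals = fit.pvalues[selected]
            worst = pvals.idxmax()
            if pvals[worst] > removal_alpha:
                selected.remove(worst)
            else:
                break

    excluded = tuple(c for c in candidates if c not in selected)
    if not selected:
        fit = sm.OLS(y, np.ones((n, 1))).fit()
        return RegressionModel(
            intercept=float(fit.params[0]),
            coefficients={},
            pvalues={},
            n=n,
            r_squared=0.0,
            excluded=excluded,
        )
    fit = _ols(y, data[selected])
    return RegressionModel(
        intercept=float(fit.params["const"]),
        coefficients={c: float(fit.params[c]) for c in selected},
        pvalues={c: float(fit.pvalues[c]) for c in selected},
        stderrs={c: float(fit.bse[c]) for c in selected},
        n=n,
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        excluded=excluded,
    )


def _collinear_variables(data: pd.DataFrame, candidates: Sequence[str]) -> list[str]:
    """Name the candidates involved in the rank deficiency."""
    offenders = []
    for cand in candidates:
        x = data[cand].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            offenders.append(cand)
            continue
        others = [c for c in candidates if c != cand]
        if others:
            X = np.column_stack(
                [np.ones(len(data)), data[others].to_numpy(dtype=float)]
            )
            resid = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
            if np.allclose(resid, 0, atol=1e-8 * max(1.0, float(np.abs(x).max()))):
                offenders.append(cand)
    return offenders or list(candidates)
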