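"""Nested model comparison by likelihood-ratio tests.

The independent, additive and full observer models form a nested chain,
so twice the log-likelihood improvement of the richer model is
asymptotically chi-square distributed under the null with degrees of
freedom equal to the difference in free-parameter counts (4 for additive
vs independent and 16 for full vs additive on a 5x5 lattice).  Decisions
across a family of observers use a Bonferroni-corrected per-test level
(alpha / n_observers; 0.05 over six observers gives 0.0083).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import InvalidParameterError, NonNestedModelsError, OptimizationError
from .fitting import FitResult, fit
from .models import ModelSpec

_MODEL_ORDER = {"independent": 0, "additive": 1, "full": 2}

#: Log-likelihood slack allowed before a "worse alternative" is treated as
#: an optimization failure rather than round-off.
_LL_TOLERANCE = 1e-6


@dataclass
class LRTResult:
    """One nested likelihood-ratio test."""

    statistic: float
    df: int
    p_value: float
    reject_at: float | None = None

    @property
    def reject(self) -> bool | None:
        if self.reject_at is None:
            return None
        return self.p_value < self.reject_at


def likelihood_ratio_test(
    null_fit: FitResult, alt_fit: FitResult, reject_at: float | None = None
) -> LRTResult:
    """Test a null model against a richer alternative on the same data.

    The statistic is 2 (l_alt - l_null) referred to chi-square with
    df = the difference in free-parameter counts.
    """
    if null_fit.spec.judged != alt_fit.spec.judged:
        raise NonNestedModelsError("fits judge different attributes")
    if _MODEL_ORDER[null_fit.spec.model] >= _MODEL_ORDER[alt_fit.spec.model]:
        raise NonNestedModelsError(
            f"{null_fit.spec.model!r} is not nested in {alt_fit.spec.model!r}"
        )
    if null_fit.n_trials != alt_fit.n_trials:
        raise NonNestedModelsError("fits use different numbers of trials")
    improvement = alt_fit.log_likelihood - null_fit.log_likelihood
    if improvement < -_LL_TOLERANCE:
        raise OptimizationError(
            "alternative model fits worse than the null "
            f"(delta log-likelihood = {improvement:.3g}); optimization failed"
        )
    statistic = max(2.0 * improvement, 0.0)
    df = alt_fit.n_free_params - null_fit.n_free_params
    p = float(chi2.sf(statistic, df))
    return LRTResult(statistic=float(statistic), df=df, p_value=p, reject_at=reject_at)


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha / n (display at four decimals)."""
    if not 0 < family_alpha < 1:
        raise InvalidParameterError(f"family_alpha must be in (0, 1), got {family_alpha}")
    if n_tests < 1:
        raise InvalidParameterError(f"n_tests must be >= 1, got {n_tests}")
    return family_alpha / n_tests


def per_observer_decisions(
    trial_tables,
    null_spec: ModelSpec,
    alt_spec: ModelSpec,
    family_alpha: float = 0.05,
    n_gloss: int = 5,
    n_lightness: int = 5,
) -> pd.DataFrame:
    """Fit both models per observer and tabulate Bonferroni-corrected LRTs.

    ``trial_tables`` maps observer ids to trial tables (a dict, or a list
    enumerated from 0).  The Bonferroni family size is the number of
    observers tested.  Returns one row per observer with the statistic,
    df, p-value, corrected level, and reject flag.
    """
    if isinstance(trial_tables, dict):
        items = list(trial_tables.items())
    else:
        items = list(enumerate(trial_tables))
    if not items:
        raise InvalidParameterError("at least one observer is required")
    level = bonferroni_alpha(family_alpha, len(items))
    rows = []
    for obs_id, trials in items:
        null_fit = fit(trials, null_spec, n_gloss, n_lightness, compute_std_errors=False)
        alt_fit = fit(trials, alt_spec, n_gloss, n_lightness, compute_std_errors=False)
        lrt = likelihood_ratio_test(null_fit, alt_fit, reject_at=level)
        rows.append(
            {
                "observer": obs_id,
                "statistic": lrt.statistic,
                "df": lrt.df,
                "p_value": lrt.p_value,
                "corrected_alpha": level,
                "reject": lrt.reject,
            }
        )
    return pd.DataFrame(rows)
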