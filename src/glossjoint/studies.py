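"""Simulation studies: parameter recovery, type-I error, and power.

These routines wrap the simulate -> fit -> test pipeline into repeatable
Monte-Carlo experiments at the canonical design size (a 5x5 lattice, 300
unordered pairs, 3 repetitions = 900 trials per observer).  They are used
both to validate the estimator (does the additive fit recover a known
contamination weight?) and to characterize the nested likelihood-ratio
test (false-positive rate under an independent observer, power against a
contaminated one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import build_lattice, build_schedule, enumerate_pairs
from .fitting import contamination_index, fit, normalize_scales
from .inference import likelihood_ratio_test
from .models import ModelSpec
from .observers import DEFAULT_STRENGTH, make_observer, simulate_responses


def _child_seeds(seed: int | None, n: int) -> list[int]:
    """Independent per-replicate seeds derived from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def simulate_observer_trials(
    kind: str,
    w: float,
    seed: int,
    task: str | None = None,
    n_levels: int = 5,
    repetitions: int = 3,
    strength: float = DEFAULT_STRENGTH,
):
    """One observer's full experiment: schedule plus simulated responses."""
    observer = make_observer(
        kind, w=w, task=task, n_levels=n_levels, strength=strength, seed=seed
    )
    lattice = build_lattice(n_levels, n_levels)
    pairs = enumerate_pairs(lattice)
    schedule = build_schedule(pairs, repetitions, seed=seed, task=observer.spec.judged)
    return simulate_responses(observer, schedule), observer


@dataclass
class RecoveryStudy:
    """Outcome of a contamination-recovery simulation."""

    w_true: float
    indices: np.ndarray  # recovered contamination index per observer
    rmse_normalized: float  # RMSE of normalized additive estimates vs truth

    @property
    def mean_index(self) -> float:
        return float(self.indices.mean())


def recovery_study(
    w: float,
    n_observers: int = 200,
    task: str = "gloss",
    repetitions: int = 3,
    n_levels: int = 5,
    strength: float = DEFAULT_STRENGTH,
    seed: int | None = 0,
) -> RecoveryStudy:
    """Fit the additive model to data from additive observers with known
    contamination ``w`` and measure how well the index and the normalized
    scale profile are recovered."""
    spec = ModelSpec("additive", task)
    anchor = spec.anchor_level - 1
    lin = np.linspace(0.0, 1.0, n_levels)
    true_primary = strength * (lin - lin[anchor])
    true_secondary = w * true_primary
    peak = max(np.abs(true_primary).max(), np.abs(true_secondary).max())
    true_primary_n, true_secondary_n = true_primary / peak, true_secondary / peak

    indices = np.empty(n_observers)
    sq_errors = []
    for i, s in enumerate(_child_seeds(seed, n_observers)):
        trials, _ = simulate_observer_trials(
            "additive_contaminated", w, s, task=task,
            n_levels=n_levels, repetitions=repetitions, strength=strength,
        )
        result = fit(trials, spec, n_levels, n_levels, compute_std_errors=False)
        indices[i] = contamination_index(result)
        norm = normalize_scales(result)
        est_primary = norm.psi_gloss if task == "gloss" else norm.psi_lightness
        est_secondary = norm.psi_lightness if task == "gloss" else norm.psi_gloss
        sq_errors.append(np.concatenate([
            (est_primary - true_primary_n) ** 2,
            (est_secondary - true_secondary_n) ** 2,
        ]))
    rmse = float(np.sqrt(np.mean(np.concatenate(sq_errors))))
    return RecoveryStudy(w_true=w, indices=indices, rmse_normalized=rmse)


@dataclass
class LRTStudy:
    """Empirical distribution of the additive-vs-independent LRT."""

    statistics: np.ndarray
    p_values: np.ndarray
    df: int

    def rejection_rate(self, alpha: float) -> float:
        return float((self.p_values < alpha).mean())

    def ks_distance_chi2(self) -> float:
        """Kolmogorov distance between the empirical statistic
        distribution and its asymptotic chi-square reference."""
        from scipy.stats import chi2

        stats = np.sort(self.statistics)
        n = stats.size
        cdf = chi2.cdf(stats, self.df)
        upper = np.abs(np.arange(1, n + 1) / n - cdf)
        lower = np.abs(cdf - np.arange(0, n) / n)
        return float(np.maximum(upper, lower).max())


def lrt_study(
    w: float = 0.0,
    n_reps: int = 500,
    task: str = "gloss",
    repetitions: int = 3,
    n_levels: int = 5,
    strength: float = DEFAULT_STRENGTH,
    seed: int | None = 0,
) -> LRTStudy:
    """Monte-Carlo distribution of the additive-vs-independent LRT.

    With ``w = 0`` the generating observer is independent and the study
    measures the false-positive rate; with ``w != 0`` it measures power.
    """
    kind = "independent_" + task if w == 0.0 else "additive_contaminated"
    null_spec = ModelSpec("independent", task)
    alt_spec = ModelSpec("additive", task)
    stats = np.empty(n_reps)
    pvals = np.empty(n_reps)
    df = -1
    for i, s in enumerate(_child_seeds(seed, n_reps)):
        trials, _ = simulate_observer_trials(
            kind, w, s, task=task,
            n_levels=n_levels, repetitions=repetitions, strength=strength,
        )
        null_fit = fit(trials, null_spec, n_levels, n_levels, compute_std_errors=False)
        alt_fit = fit(trials, alt_spec, n_levels, n_levels, compute_std_errors=False)
        lrt = likelihood_ratio_test(null_fit, alt_fit)
        stats[i], pvals[i], df = lrt.statistic, lrt.p_value, lrt.df
    return LRTStudy(statistics=stats, p_values=pvals, df=df)
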