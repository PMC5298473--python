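"""Maximum-likelihood estimation of perceptual scales from choice data.

The decision models are linear in their parameters, so each trial maps to
a signed-indicator row of a design matrix X (+1 for the first stimulus's
parameters, -1 for the second's) and the Bernoulli likelihood of the
responses is exactly a probit regression through the origin with
coefficient vector psi / sigma.  Identifiability is resolved the standard
way: sigma is fixed at 1 (estimates are therefore in noise units) and one
scale value per dimension — level ``anchor_level``, default 3 — is pinned
at zero (for the full model, the single anchor cell
(anchor_level, anchor_level)).

Free-parameter counts on an n x n lattice (anchor + sigma removed):
independent n - 1, additive 2(n - 1), full n^2 - 1; e.g. 4 / 8 / 24 for
n = 5.

Estimation maximizes the log-likelihood by BFGS from a zero start with an
analytic gradient (gradient tolerance 1e-8), which is deterministic given
the data.  Complete separation (a level always preferred) sends estimates
to infinity; these are clamped at +/-10 with a warning rather than
penalized, keeping the estimator exactly maximum likelihood on
well-behaved data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr
from scipy.stats import norm

from .errors import (
    DataError,
    InvalidParameterError,
    NormalizationError,
    OptimizationError,
    SeparationWarning,
)
from .models import ModelSpec, PerceptualScales, choice_probability, decision_values

#: Absolute bound applied to diverging estimates under separation.
ESTIMATE_CLAMP = 10.0

_GTOL = 1e-8


@dataclass
class DesignMatrix:
    """Signed-indicator encoding of a trial table for one model.

    ``X`` has one row per trial and one column per free parameter, with
    entries in {-1, 0, +1}; ``columns`` labels each free parameter as
    ``("g", level)``, ``("l", level)`` or ``("cell", g, l)``.
    """

    X: np.ndarray
    columns: list[tuple]

    @property
    def n_free_params(self) -> int:
        return len(self.columns)


def free_param_columns(
    spec: ModelSpec, n_gloss: int = 5, n_lightness: int = 5
) -> list[tuple]:
    """Labels of the model's free parameters, anchors excluded."""
    a = spec.anchor_level
    if a > max(n_gloss, n_lightness):
        raise InvalidParameterError(
            f"anchor level {a} outside lattice {n_gloss}x{n_lightness}"
        )
    if spec.model == "independent":
        if spec.judged == "gloss":
            return [("g", lev) for lev in range(1, n_gloss + 1) if lev != a]
        return [("l", lev) for lev in range(1, n_lightness + 1) if lev != a]
    if spec.model == "additive":
        return [("g", lev) for lev in range(1, n_gloss + 1) if lev != a] + [
            ("l", lev) for lev in range(1, n_lightness + 1) if lev != a
        ]
    return [
        ("cell", g, l)
        for g in range(1, n_gloss + 1)
        for l in range(1, n_lightness + 1)
        if not (g == a and l == a)
    ]


def count_free_params(spec: ModelSpec, n_gloss: int = 5, n_lightness: int = 5) -> int:
    """Closed-form free-parameter count after anchoring (sigma fixed at 1)."""
    if spec.model == "independent":
        n = n_gloss if spec.judged == "gloss" else n_lightness
        return n - 1
    if spec.model == "additive":
        return (n_gloss - 1) + (n_lightness - 1)
    return n_gloss * n_lightness - 1


def count_params_unanchored(
    spec: ModelSpec, n_gloss: int = 5, n_lightness: int = 5
) -> int:
    """Parameter count before identifiability constraints, sigma included.

    Independent: n + 1; additive: n_g + n_l + 1 (11 on a 5x5 lattice);
    full (per-cell parameterization): n_g * n_l + 1.
    """
    if spec.model == "independent":
        n = n_gloss if spec.judged == "gloss" else n_lightness
        return n + 1
    if spec.model == "additive":
        return n_gloss + n_lightness + 1
    return n_gloss * n_lightness + 1


def build_design_matrix(
    trials: pd.DataFrame, spec: ModelSpec, n_gloss: int = 5, n_lightness: int = 5
) -> DesignMatrix:
    """Encode a long-format trial table as a signed-indicator matrix.

    The probit regression of the responses on this matrix (no intercept,
    unit residual scale) has a likelihood identical to evaluating the
    decision model trial by trial.
    """
    for col, bound in (
        ("first_g", n_gloss),
        ("second_g", n_gloss),
        ("first_l", n_lightness),
        ("second_l", n_lightness),
    ):
        levels = trials[col].to_numpy(dtype=int)
        if levels.min(initial=1) < 1 or levels.max(initial=1) > bound:
            raise DataError(f"column {col} has levels outside 1..{bound}")

    columns = free_param_columns(spec, n_gloss, n_lightness)
    col_index = {label: j for j, label in enumerate(columns)}
    n = len(trials)
    X = np.zeros((n, len(columns)))
    fg = trials["first_g"].to_numpy(dtype=int)
    fl = trials["first_l"].to_numpy(dtype=int)
    sg = trials["second_g"].to_numpy(dtype=int)
    sl = trials["second_l"].to_numpy(dtype=int)
    rows = np.arange(n)

    def scatter(labels_first, labels_second):
        for labels, sign in ((labels_first, 1.0), (labels_second, -1.0)):
            for r, label in zip(rows, labels):
                j = col_index.get(label)
                if j is not None:
                    X[r, j] += sign

    if spec.model == "independent":
        if spec.judged == "gloss":
            scatter([("g", v) for v in fg], [("g", v) for v in sg])
        else:
            scatter([("l", v) for v in fl], [("l", v) for v in sl])
    elif spec.model == "additive":
        scatter([("g", v) for v in fg], [("g", v) for v in sg])
        scatter([("l", v) for v in fl], [("l", v) for v in sl])
    else:
        scatter(
            [("cell", g, l) for g, l in zip(fg, fl)],
            [("cell", g, l) for g, l in zip(sg, sl)],
        )
    return DesignMatrix(X=X, columns=columns)


@dataclass
class FitResult:
    """Maximum-likelihood fit of one observer model to one trial table."""

    scales: PerceptualScales
    spec: ModelSpec
    log_likelihood: float
    n_free_params: int
    converged: bool
    std_errors: np.ndarray | None = None
    columns: list[tuple] | None = None
    estimates: np.ndarray | None = None
    n_trials: int = 0
    gradient_norm: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "model": self.spec.model,
            "judged": self.spec.judged,
            "anchor_level": self.spec.anchor_level,
            "log_likelihood": self.log_likelihood,
            "n_free_params": self.n_free_params,
            "n_trials": self.n_trials,
            "converged": self.converged,
            "scales": self.scales.to_dict(),
            "parameters": [
                {
                    "name": "_".join(str(p) for p in label),
                    "estimate": float(est),
                    "std_error": None if self.std_errors is None else float(se),
                }
                for label, est, se in zip(
                    self.columns or [],
                    self.estimates if self.estimates is not None else [],
                    self.std_errors
                    if self.std_errors is not None
                    else np.full(self.n_free_params, np.nan),
                )
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def params_frame(self) -> pd.DataFrame:
        rows = self.to_dict()["parameters"]
        return pd.DataFrame(rows)


def _nll_and_grad(beta: np.ndarray, X: np.ndarray, sign: np.ndarray):
    """Negative Bernoulli probit log-likelihood and its gradient.

    ``sign`` is +1 where the first stimulus was chosen, -1 otherwise, so
    each term is log Phi(sign * x_i . beta), computed via ``log_ndtr`` for
    stability in the tails.
    """
    z = sign * (X @ beta)
    logphi = log_ndtr(z)
    ratio = np.exp(norm.logpdf(z) - logphi)  # phi(z)/Phi(z), the inverse Mills ratio
    nll = -logphi.sum()
    grad = -(X.T @ (sign * ratio))
    return nll, grad


def _nll_and_grad_offset(
    beta: np.ndarray, X: np.ndarray, offset: np.ndarray, sign: np.ndarray
):
    """As :func:`_nll_and_grad` with a fixed linear-predictor offset
    (used when separated parameters are pinned at the clamp boundary)."""
    z = sign * (X @ beta + offset)
    logphi = log_ndtr(z)
    ratio = np.exp(norm.logpdf(z) - logphi)
    return -logphi.sum(), -(X.T @ (sign * ratio))


def _separation_directions(X: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Flag parameters whose MLE diverges under complete separation.

    A free parameter's estimate runs to +inf when its level sits on the
    chosen stimulus in every trial where it appears (and to -inf in the
    mirror case).  Returns +/-1 per diverging column, 0 otherwise.
    """
    directions = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        nz = col != 0
        if not nz.any():
            continue
        prod = col[nz] * sign[nz]
        if np.all(prod > 0):
            directions[j] = 1.0
        elif np.all(prod < 0):
            directions[j] = -1.0
    return directions


def log_likelihood_direct(
    trials: pd.DataFrame, scales: PerceptualScales, spec: ModelSpec
) -> float:
    """Trial-by-trial log-likelihood straight from the decision model.

    Evaluates sum y log Phi(delta/sigma) + (1 - y) log Phi(-delta/sigma)
    without going through the design-matrix encoding; used to cross-check
    the regression formulation.
    """
    delta = decision_values(scales, trials, spec)
    y = trials["response"].to_numpy(dtype=int)
    sign = 2.0 * y - 1.0
    return float(log_ndtr(sign * delta / scales.sigma).sum())


def _scales_from_beta(
    beta: np.ndarray, columns: list[tuple], spec: ModelSpec, n_gloss: int, n_lightness: int
) -> PerceptualScales:
    psi_g = np.zeros(n_gloss)
    psi_l = np.zeros(n_lightness)
    interaction = np.zeros((n_gloss, n_lightness)) if spec.model == "full" else None
    for label, value in zip(columns, beta):
        if label[0] == "g":
            psi_g[label[1] - 1] = value
        elif label[0] == "l":
            psi_l[label[1] - 1] = value
        else:
            interaction[label[1] - 1, label[2] - 1] = value
    return PerceptualScales(psi_g, psi_l, interaction=interaction, sigma=1.0)


def fit(
    trials: pd.DataFrame,
    spec: ModelSpec,
    n_gloss: int = 5,
    n_lightness: int = 5,
    compute_std_errors: bool = True,
) -> FitResult:
    """Fit one observer model to a trial table by maximum likelihood.

    Responses must be binary (1 = first stimulus chosen).  Estimates are
    anchored (anchor level exactly zero) and expressed in units of the
    decision noise, which is fixed at 1.
    """
    y = trials["response"].to_numpy(dtype=int)
    if not np.isin(y, (0, 1)).all():
        raise DataError("responses must be binary 0/1")
    dm = build_design_matrix(trials, spec, n_gloss, n_lightness)
    sign = 2.0 * y - 1.0

    sep_dir = _separation_directions(dm.X, sign)
    free = sep_dir == 0
    offset = dm.X[:, ~free] @ (ESTIMATE_CLAMP * sep_dir[~free])
    if not free.all():
        warnings.warn(
            "complete separation: a level is always (or never) on the chosen "
            f"stimulus; {int((~free).sum())} estimate(s) clamped at "
            f"+/-{ESTIMATE_CLAMP}",
            SeparationWarning,
            stacklevel=2,
        )

    def objective(beta_free):
        nll, grad = _nll_and_grad_offset(beta_free, dm.X[:, free], offset, sign)
        return nll, grad

    beta = ESTIMATE_CLAMP * sep_dir
    if free.any():
        res = minimize(
            objective,
            np.zeros(int(free.sum())),
            jac=True,
            method="BFGS",
            options={"gtol": _GTOL, "maxiter": 1000},
        )
        beta[free] = np.clip(res.x, -ESTIMATE_CLAMP, ESTIMATE_CLAMP)
        grad_norm = float(np.linalg.norm(res.jac, np.inf)) if res.jac.size else 0.0
        converged = bool(res.success or grad_norm < 1e-4 or not free.all())
        if not converged:
            raise OptimizationError(
                f"probit fit did not converge: {res.message} (|grad|={grad_norm:.3g})"
            )
    else:
        grad_norm, converged = 0.0, True

    nll, _ = _nll_and_grad(beta, dm.X, sign)
    std_errors = None
    if compute_std_errors:
        z = sign * (dm.X @ beta)
        ratio = np.exp(norm.logpdf(z) - log_ndtr(z))
        weight = ratio * (z + ratio)  # per-trial observed information
        info = dm.X.T @ (dm.X * weight[:, None])
        cov = np.linalg.pinv(info)
        std_errors = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    scales = _scales_from_beta(beta, dm.columns, spec, n_gloss, n_lightness)
    return FitResult(
        scales=scales,
        spec=spec,
        log_likelihood=float(-nll),
        n_free_params=dm.n_free_params,
        converged=converged,
        std_errors=std_errors,
        columns=dm.columns,
        estimates=beta,
        n_trials=len(trials),
        gradient_norm=grad_norm,
    )


def _result_scales(result) -> tuple[PerceptualScales, ModelSpec | None]:
    if isinstance(result, FitResult):
        return result.scales, result.spec
    if isinstance(result, PerceptualScales):
        return result, None
    raise TypeError(f"expected FitResult or PerceptualScales, got {type(result)!r}")


def normalize_scales(result) -> PerceptualScales:
    """Divide all scale estimates by the largest absolute estimate.

    The largest-magnitude value becomes +/-1 and ratios between parameters
    are preserved; idempotent on already-normalized scales.
    """
    scales, _ = _result_scales(result)
    candidates = [np.abs(scales.psi_gloss).max(), np.abs(scales.psi_lightness).max()]
    if scales.interaction is not None:
        candidates.append(np.abs(scales.interaction).max())
    peak = max(candidates)
    if peak == 0:
        raise NormalizationError("all scale estimates are zero; normalization undefined")
    return PerceptualScales(
        psi_gloss=scales.psi_gloss / peak,
        psi_lightness=scales.psi_lightness / peak,
        interaction=None if scales.interaction is None else scales.interaction / peak,
        sigma=scales.sigma,
    )


def _marginal_profiles(scales: PerceptualScales) -> tuple[np.ndarray, np.ndarray]:
    """Main-effect profiles; for a per-cell fit, row/column means of the
    cell matrix are folded into the main effects."""
    psi_g = scales.psi_gloss.copy()
    psi_l = scales.psi_lightness.copy()
    if scales.interaction is not None:
        psi_g = psi_g + scales.interaction.mean(axis=1)
        psi_l = psi_l + scales.interaction.mean(axis=0)
    return psi_g, psi_l


def contamination_index(result) -> float:
    """Signed intrusion of the irrelevant dimension on the judged one.

    Defined as the signed end-to-end range of the irrelevant dimension's
    fitted scale divided by the absolute end-to-end range of the judged
    dimension's scale.  Negative values mean the irrelevant dimension
    suppresses the judged attribute.  Requires an additive or full fit.
    """
    scales, spec = _result_scales(result)
    if spec is not None and spec.model == "independent":
        raise InvalidParameterError(
            "contamination index requires an additive or full model fit"
        )
    judged = spec.judged if spec is not None else "gloss"
    psi_g, psi_l = _marginal_profiles(scales)
    primary, secondary = (psi_g, psi_l) if judged == "gloss" else (psi_l, psi_g)
    primary_range = abs(primary[-1] - primary[0])
    if primary_range == 0:
        raise NormalizationError("judged dimension has zero range; index undefined")
    return float((secondary[-1] - secondary[0]) / primary_range)


def contamination_summary(results, reducer: str = "per_observer_mean") -> float:
    """Aggregate the contamination index over several observers' fits.

    ``per_observer_mean`` (default) averages each observer's own range
    ratio; ``pooled_ratio`` first averages the normalized scale profiles
    across observers and takes the ratio of the averaged ranges.
    """
    results = list(results)
    if reducer == "per_observer_mean":
        return float(np.mean([contamination_index(r) for r in results]))
    if reducer == "pooled_ratio":
        judged = results[0].spec.judged
        norm_scales = [normalize_scales(r) for r in results]
        psi_g = np.mean([_marginal_profiles(s)[0] for s in norm_scales], axis=0)
        psi_l = np.mean([_marginal_profiles(s)[1] for s in norm_scales], axis=0)
        primary, secondary = (psi_g, psi_l) if judged == "gloss" else (psi_l, psi_g)
        return float((secondary[-1] - secondary[0]) / abs(primary[-1] - primary[0]))
    raise InvalidParameterError(f"unknown reducer {reducer!r}")
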