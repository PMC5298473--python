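"""Maximum-likelihood difference scaling (MLDS) for stimulus calibration.

Before running a conjoint experiment the physical stimulus magnitudes
(shader roughness for gloss, reflectance for albedo) are chosen so that
consecutive levels are perceptually equidistant.  MLDS estimates the
physical-to-perceptual transformation from quadruple judgments: on each
trial the observer sees two non-overlapping pairs (a, b) and (c, d) drawn
from an ordered set of calibration stimuli (a < b <= c < d) and reports
which pair looks more different.  Under a Gaussian difference model,

    P(pair (a, b) chosen) = Phi(((psi_b - psi_a) - (psi_d - psi_c)) / sigma),

and the scale is identified by double anchoring psi_1 = 0, psi_n = 1 with
sigma estimated — a different convention from the conjoint fits, where
sigma is fixed at 1 instead.

:func:`select_equal_steps` inverts the fitted (monotone) scale to place a
requested number of physical magnitudes at perceptually equal steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, minimize
from scipy.special import log_ndtr
from scipy.stats import norm

from .errors import (
    DataError,
    InvalidParameterError,
    NonMonotoneScaleError,
)

DIFFERENCE_COLUMNS = ["a", "b", "c", "d", "response"]


@dataclass
class CalibrationScale:
    """A fitted perceptual scale over the calibration stimuli.

    ``psi`` holds the perceptual values (anchored: psi[0] = 0,
    psi[-1] = 1), ``sigma`` the difference-judgment noise, ``physical``
    the physical magnitudes behind the stimuli.
    """

    psi: np.ndarray
    sigma: float
    physical: np.ndarray

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.physical = np.asarray(self.physical, dtype=float)
        if self.psi.size != self.physical.size:
            raise InvalidParameterError("psi and physical must have equal length")
        diffs = np.diff(self.physical)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise InvalidParameterError("physical magnitudes must be strictly monotone")

    @property
    def n_stimuli(self) -> int:
        return self.psi.size

    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.psi) > 0))

    def to_dict(self) -> dict:
        return {
            "psi": self.psi.tolist(),
            "sigma": self.sigma,
            "physical": self.physical.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationScale":
        return cls(np.asarray(d["psi"]), float(d["sigma"]), np.asarray(d["physical"]))


def enumerate_quadruples(n_stimuli: int) -> list[tuple[int, int, int, int]]:
    """All non-overlapping quadruples a < b < c < d of 1-based indices."""
    return list(combinations(range(1, n_stimuli + 1), 4))


def simulate_difference_trials(
    psi: np.ndarray,
    n_trials: int,
    sigma: float = 0.15,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate quadruple difference judgments from a known scale.

    Quadruples are sampled uniformly with replacement from all
    non-overlapping a < b < c < d; the response is 1 when the noisy
    difference-of-differences favors pair (a, b).
    """
    psi = np.asarray(psi, dtype=float)
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    quads = np.asarray(enumerate_quadruples(psi.size))
    rng = np.random.default_rng(seed)
    picks = quads[rng.integers(0, len(quads), size=n_trials)]
    a, b, c, d = picks.T
    signal = (psi[b - 1] - psi[a - 1]) - (psi[d - 1] - psi[c - 1])
    response = (signal + rng.normal(0.0, sigma, size=n_trials) > 0).astype(int)
    return pd.DataFrame(
        {"a": a, "b": b, "c": c, "d": d, "response": response}
    )


def _validate_difference_trials(trials: pd.DataFrame, n_stimuli: int):
    arr = trials[["a", "b", "c", "d"]].to_numpy(dtype=int)
    if arr.min() < 1 or arr.max() > n_stimuli:
        raise DataError(f"stimulus indices outside 1..{n_stimuli}")
    a, b, c, d = arr.T
    if not np.all((a < b) & (b <= c) & (c < d)):
        raise DataError("quadruples must satisfy a < b <= c < d")
    y = trials["response"].to_numpy(dtype=int)
    if not np.isin(y, (0, 1)).all():
        raise DataError("responses must be binary 0/1")
    return a, b, c, d, y


def fit_mlds(
    trials: pd.DataFrame,
    n_stimuli: int,
    physical: np.ndarray | None = None,
) -> CalibrationScale:
    """Fit a perceptual scale to difference judgments by maximum likelihood.

    Maximizes the Bernoulli likelihood of the quadruple responses under
    the Gaussian difference model, anchored at psi_1 = 0 and psi_n = 1
    with sigma free.  ``physical`` defaults to an even grid on [0, 1].
    """
    if n_stimuli < 4:
        raise InvalidParameterError("difference scaling needs at least 4 stimuli")
    a, b, c, d, y = _validate_difference_trials(trials, n_stimuli)
    sign = 2.0 * y - 1.0
    ia, ib, ic, id_ = a - 1, b - 1, c - 1, d - 1
    n_interior = n_stimuli - 2

    def unpack(theta):
        psi = np.empty(n_stimuli)
        psi[0] = 0.0
        psi[1:-1] = theta[:n_interior]
        psi[-1] = 1.0
        return psi, np.exp(theta[-1])

    def nll_and_grad(theta):
        psi, sigma = unpack(theta)
        eta = ((psi[ib] - psi[ia]) - (psi[id_] - psi[ic])) / sigma
        z = sign * eta
        logphi = log_ndtr(z)
        ratio = np.exp(norm.logpdf(z) - logphi)
        g_eta = sign * ratio  # d loglik / d eta, per trial
        grad_psi = np.zeros(n_stimuli)
        np.add.at(grad_psi, ib, g_eta / sigma)
        np.add.at(grad_psi, ia, -g_eta / sigma)
        np.add.at(grad_psi, ic, g_eta / sigma)
        np.add.at(grad_psi, id_, -g_eta / sigma)
        grad_logsigma = -np.dot(g_eta, eta)
        grad = np.concatenate([grad_psi[1:-1], [grad_logsigma]])
        return -logphi.sum(), -grad

    theta0 = np.concatenate([np.linspace(0, 1, n_stimuli)[1:-1], [np.log(0.2)]])
    res = minimize(
        nll_and_grad,
        theta0,
        jac=True,
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 2000},
    )
    psi, sigma = unpack(res.x)
    if physical is None:
        physical = np.linspace(0.0, 1.0, n_stimuli)
    return CalibrationScale(psi=psi, sigma=float(sigma), physical=np.asarray(physical))


def select_equal_steps(
    scale: CalibrationScale, n_levels: int, interpolation: str = "spline"
) -> np.ndarray:
    """Physical magnitudes whose perceptual values are equally spaced.

    The fitted scale is interpolated over the calibration points — by a
    cubic spline by default (exact for smooth polynomial scales), or
    piecewise linearly with ``interpolation="linear"`` — and inverted at
    perceptual targets equally spaced between the anchored endpoints.
    """
    if n_levels < 2:
        raise InvalidParameterError("need at least 2 levels")
    if not scale.is_monotone():
        raise NonMonotoneScaleError(
            "fitted scale is not monotone; inspect the calibration data before "
            "selecting equal perceptual steps"
        )
    psi, physical = scale.psi, scale.physical
    if physical[0] > physical[-1]:  # work on an increasing physical axis
        psi, physical = psi[::-1], physical[::-1]
    targets = np.linspace(psi[0], psi[-1], n_levels)
    if interpolation == "linear":
        return np.interp(targets, psi, physical)
    if interpolation != "spline":
        raise InvalidParameterError(f"unknown interpolation {interpolation!r}")
    spline = CubicSpline(physical, psi)
    out = np.empty(n_levels)
    out[0], out[-1] = physical[0], physical[-1]
    for i, t in enumerate(targets[1:-1], start=1):
        out[i] = brentq(lambda x: spline(x) - t, physical[0], physical[-1], xtol=1e-12)
    return out
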