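"""Signal-detection decision models for paired gloss/lightness comparisons.

Three nested observer models describe how an internal estimate of the
judged attribute is formed for each stimulus on a (gloss, lightness)
lattice:

independent
    The estimate depends only on the judged dimension's own scale value.
additive
    The irrelevant dimension contaminates the estimate additively:
    psi(g, l) = psi_g[g] + psi_l[l].
full
    The additive estimate plus a per-cell interaction term, allowing
    level-dependent contamination.

On each trial the two internal estimates are differenced and corrupted by
a single zero-mean Gaussian judgment error with standard deviation sigma,
so the probability of choosing the first stimulus is Phi(delta / sigma)
where delta is the noise-free estimate difference and Phi the standard
normal CDF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .design import StimulusIndex
from .errors import InvalidParameterError, ModelMismatchError

ModelKind = Literal["independent", "additive", "full"]
Task = Literal["lightness", "gloss"]

MODEL_KINDS = ("independent", "additive", "full")


@dataclass(frozen=True)
class ModelSpec:
    """Which observer model applies, which attribute is judged, and the
    anchoring convention (the level whose scale value is fixed at zero)."""

    model: ModelKind
    judged: Task
    anchor_level: int = 3

    def __post_init__(self) -> None:
        if self.model not in MODEL_KINDS:
            raise InvalidParameterError(f"unknown model {self.model!r}")
        if self.judged not in ("lightness", "gloss"):
            raise InvalidParameterError(f"unknown task {self.judged!r}")
        if self.anchor_level < 1:
            raise InvalidParameterError("anchor_level must be >= 1")


@dataclass
class PerceptualScales:
    """Latent scale values for both dimensions plus the decision noise.

    ``psi_gloss`` and ``psi_lightness`` hold one dimensionless scale value
    per level; ``interaction`` is an optional (n_gloss, n_lightness) matrix
    of per-cell terms used by the full model; ``sigma`` is the standard
    deviation of the single Gaussian judgment error on the decision
    difference.
    """

    psi_gloss: np.ndarray
    psi_lightness: np.ndarray
    interaction: np.ndarray | None = None
    sigma: float = 1.0

    def __post_init__(self) -> None:
        self.psi_gloss = np.asarray(self.psi_gloss, dtype=float)
        self.psi_lightness = np.asarray(self.psi_lightness, dtype=float)
        if self.psi_gloss.ndim != 1 or self.psi_lightness.ndim != 1:
            raise InvalidParameterError("scale values must be one-dimensional")
        if self.sigma <= 0 or not np.isfinite(self.sigma):
            raise InvalidParameterError(f"sigma must be positive, got {self.sigma}")
        if self.interaction is not None:
            self.interaction = np.asarray(self.interaction, dtype=float)
            expected = (self.psi_gloss.size, self.psi_lightness.size)
            if self.interaction.shape != expected:
                raise InvalidParameterError(
                    f"interaction matrix must have shape {expected}, "
                    f"got {self.interaction.shape}"
                )

    @property
    def n_gloss(self) -> int:
        return self.psi_gloss.size

    @property
    def n_lightness(self) -> int:
        return self.psi_lightness.size

    def to_dict(self) -> dict:
        return {
            "psi_gloss": self.psi_gloss.tolist(),
            "psi_lightness": self.psi_lightness.tolist(),
            "interaction": None if self.interaction is None else self.interaction.tolist(),
            "sigma": self.sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PerceptualScales":
        return cls(
            psi_gloss=np.asarray(d["psi_gloss"], dtype=float),
            psi_lightness=np.asarray(d["psi_lightness"], dtype=float),
            interaction=None if d.get("interaction") is None else np.asarray(d["interaction"]),
            sigma=float(d.get("sigma", 1.0)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PerceptualScales":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _check_interaction(scales: PerceptualScales, spec: ModelSpec) -> None:
    if spec.model == "full" and scales.interaction is None:
        raise ModelMismatchError("full model requires interaction terms, none present")


def internal_estimate(
    scales: PerceptualScales, s: StimulusIndex, spec: ModelSpec
) -> float:
    """Noise-free internal estimate of the judged attribute for stimulus ``s``."""
    _check_interaction(scales, spec)
    g, l = s
    if spec.model == "independent":
        if spec.judged == "gloss":
            return float(scales.psi_gloss[g - 1])
        return float(scales.psi_lightness[l - 1])
    value = scales.psi_gloss[g - 1] + scales.psi_lightness[l - 1]
    if spec.model == "full":
        value += scales.interaction[g - 1, l - 1]
    return float(value)


def decision_value(
    scales: PerceptualScales,
    first: StimulusIndex,
    second: StimulusIndex,
    spec: ModelSpec,
) -> float:
    """Signed noise-free decision difference delta(first, second).

    Antisymmetric by construction: delta(a, b) = -delta(b, a), and zero
    when both stimuli coincide.
    """
    return internal_estimate(scales, first, spec) - internal_estimate(scales, second, spec)


def decision_values(
    scales: PerceptualScales, trials: pd.DataFrame, spec: ModelSpec
) -> np.ndarray:
    """Vectorized ``decision_value`` over a long-format trial table."""
    _check_interaction(scales, spec)
    fg = trials["first_g"].to_numpy(dtype=int) - 1
    fl = trials["first_l"].to_numpy(dtype=int) - 1
    sg = trials["second_g"].to_numpy(dtype=int) - 1
    sl = trials["second_l"].to_numpy(dtype=int) - 1
    if spec.model == "independent":
        if spec.judged == "gloss":
            return scales.psi_gloss[fg] - scales.psi_gloss[sg]
        return scales.psi_lightness[fl] - scales.psi_lightness[sl]
    delta = (
        scales.psi_gloss[fg]
        + scales.psi_lightness[fl]
        - scales.psi_gloss[sg]
        - scales.psi_lightness[sl]
    )
    if spec.model == "full":
        delta = delta + scales.interaction[fg, fl] - scales.interaction[sg, sl]
    return delta


def choice_probability(delta, sigma: float = 1.0):
    """P(first stimulus chosen) = Phi(delta / sigma).

    Strictly increasing in ``delta`` and complementary under sign flip:
    Phi(d) + Phi(-d) = 1.  Accepts scalars or arrays.
    """
    if sigma <= 0 or not np.isfinite(sigma):
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    return ndtr(np.asarray(delta, dtype=float) / sigma)
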