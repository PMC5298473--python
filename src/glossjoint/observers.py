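"""Synthetic observers: generative models that answer paired comparisons.

No human data ship with this package, so simulated observers stand in for
them.  A :class:`GenerativeObserver` bundles a set of perceptual scales, a
decision-model specification, and a seed; :func:`simulate_responses` draws
one Bernoulli response per scheduled trial by sampling the Gaussian
judgment error directly (choose the first stimulus iff the noisy decision
difference is positive; an exactly-zero draw, a probability-zero event,
resolves to the second stimulus).

:func:`make_observer` builds the canonical observer kinds used throughout
the test battery and the worked analyses:

``independent_gloss`` / ``independent_lightness``
    Judgments driven purely by the judged dimension; the irrelevant
    dimension's scale is identically zero.
``additive_contaminated``
    An additive observer whose irrelevant-dimension scale is a signed
    fraction ``w`` of the judged scale: the canonical cue-contamination
    observer (w = -0.32 emulates lightness suppressing gloss, w = -0.12
    the reverse contamination).
``contrast_center_lightness``
    A simultaneous-contrast observer for center-surround displays: the
    perceived lightness of a constant central patch decreases
    monotonically with background albedo.
``chained_contrast_gloss``
    Composes simultaneous contrast with gloss contamination: a darker
    background makes the center look lighter, and a lighter center looks
    less glossy, so perceived center gloss increases with background
    albedo.

The default judged-dimension scale is linear over levels because stimulus
levels are assumed perceptually equalized (see the MLDS calibration
module); the response-strength multiplier sets discriminability in sigma
units across the full scale range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TrialSchedule
from .errors import GlossjointError, InvalidParameterError
from .models import ModelSpec, PerceptualScales, decision_values

#: End-to-end range of the default generative judged-dimension scale, in
#: units of the decision noise sigma.  Controls discriminability.
DEFAULT_STRENGTH = 4.0

OBSERVER_KINDS = (
    "independent_lightness",
    "independent_gloss",
    "additive_contaminated",
    "contrast_center_lightness",
    "chained_contrast_gloss",
)


@dataclass
class GenerativeObserver:
    """A fully specified response-generating observer."""

    scales: PerceptualScales
    spec: ModelSpec
    seed: int | None = None


def simulate_responses(
    observer: GenerativeObserver, schedule: TrialSchedule
) -> pd.DataFrame:
    """Simulate one binary response per trial of ``schedule``.

    Returns the schedule's long-format table with an added ``response``
    column (1 = first stimulus chosen).  Reproducible under the observer's
    seed; P(first chosen) = Phi(delta / sigma) per trial.
    """
    scales = observer.scales
    n_levels_needed = max(
        (max(f.g, s.g) for f, s, _ in schedule.trials),
        default=0,
    )
    if n_levels_needed > scales.n_gloss:
        raise GlossjointError(
            f"schedule references gloss level {n_levels_needed} but the "
            f"observer has {scales.n_gloss} levels"
        )
    n_light_needed = max((max(f.l, s.l) for f, s, _ in schedule.trials), default=0)
    if n_light_needed > scales.n_lightness:
        raise GlossjointError(
            f"schedule references lightness level {n_light_needed} but the "
            f"observer has {scales.n_lightness} levels"
        )
    frame = schedule.to_frame()
    delta = decision_values(scales, frame, observer.spec)
    rng = np.random.default_rng(observer.seed)
    noisy = delta + rng.normal(0.0, scales.sigma, size=delta.size)
    frame["response"] = (noisy > 0).astype(int)
    return frame


def _linear(n_levels: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, n_levels)


def make_observer(
    kind: str,
    w: float = 0.0,
    task: str | None = None,
    n_levels: int = 5,
    strength: float = DEFAULT_STRENGTH,
    contrast_strength: float | None = None,
    sigma: float = 1.0,
    anchor_level: int = 3,
    seed: int | None = None,
) -> GenerativeObserver:
    """Build one of the canonical generative observers (see module docs).

    Parameters
    ----------
    kind
        One of :data:`OBSERVER_KINDS`.
    w
        Signed contamination weight: the irrelevant dimension's scale is
        ``w`` times the (linear) judged scale.  Negative values suppress
        the judged attribute.
    task
        Judged attribute; defaults to the natural task for the kind.
    strength
        End-to-end range of the judged scale in sigma units.
    contrast_strength
        Range of the simultaneous-contrast lightness shift (defaults to
        ``strength``); used by the contrast and chained kinds.
    """
    if kind not in OBSERVER_KINDS:
        raise InvalidParameterError(
            f"unknown observer kind {kind!r}; expected one of {OBSERVER_KINDS}"
        )
    if contrast_strength is None:
        contrast_strength = strength
    lin = _linear(n_levels)
    zeros = np.zeros(n_levels)

    if kind == "independent_gloss":
        task = task or "gloss"
        scales = PerceptualScales(strength * lin, zeros, sigma=sigma)
        spec = ModelSpec("independent", "gloss", anchor_level)
    elif kind == "independent_lightness":
        task = task or "lightness"
        scales = PerceptualScales(zeros, strength * lin, sigma=sigma)
        spec = ModelSpec("independent", "lightness", anchor_level)
    elif kind == "additive_contaminated":
        task = task or "gloss"
        primary = strength * lin
        secondary = w * strength * lin
        if task == "gloss":
            scales = PerceptualScales(primary, secondary, sigma=sigma)
        else:
            scales = PerceptualScales(secondary, primary, sigma=sigma)
        spec = ModelSpec("additive", task, anchor_level)
    elif kind == "contrast_center_lightness":
        # Perceived lightness of a constant center, as a function of the
        # background's albedo level: darker surround -> lighter center.
        task = "lightness"
        scales = PerceptualScales(zeros, -contrast_strength * lin, sigma=sigma)
        spec = ModelSpec("independent", "lightness", anchor_level)
    elif kind == "chained_contrast_gloss":
        # Contrast shifts center lightness (decreasing in background
        # albedo); contamination w (< 0) maps lightness onto gloss, so the
        # composed gloss scale over background albedo is w * (-contrast).
        task = "gloss"
        if w == 0.0:
            w = -0.32
        gloss_component = np.zeros(n_levels)
        albedo_component = w * (-contrast_strength * lin)
        scales = PerceptualScales(gloss_component, albedo_component, sigma=sigma)
        spec = ModelSpec("additive", "gloss", anchor_level)

    return GenerativeObserver(scales=scales, spec=spec, seed=seed)
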