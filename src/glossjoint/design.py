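"""Stimulus lattices, comparison pairs, and randomized trial schedules.

The experimental design is a two-dimensional factorial lattice of surfaces
varying in gloss (microfacet roughness) and lightness (albedo), optionally
replicated over several surface shapes.  Observers judge pairs of stimuli,
so the schedule enumerates every unordered pair of lattice cells (without
self-comparisons by default), repeats each pair a fixed number of times,
and randomizes both trial order and within-trial presentation order.

Shapes act as replicates only: the perceptual models contain no shape term,
so comparison pairs are enumerated on the gloss x lightness grid alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidDesignError

TRIAL_COLUMNS = [
    "trial",
    "task",
    "first_g",
    "first_l",
    "second_g",
    "second_l",
    "repetition",
]

TASKS = ("lightness", "gloss")


class StimulusIndex(NamedTuple):
    """A lattice cell: 1-based gloss level ``g`` and lightness level ``l``."""

    g: int
    l: int


@dataclass(frozen=True)
class StimulusLattice:
    """A factorial stimulus grid of gloss and lightness levels.

    Parameters
    ----------
    n_gloss, n_lightness
        Number of levels on each perceptual dimension (1-based indices).
    n_shapes
        Number of surface-shape replicates.  Shapes do not enter the
        comparison grid; they only multiply the rendered surface count.
    physical_gloss, physical_albedo
        Optional physical magnitudes behind the levels (shader roughness
        alpha, reflectance fraction).  Must be strictly monotone and match
        the level counts.
    """

    n_gloss: int
    n_lightness: int
    n_shapes: int = 1
    physical_gloss: tuple[float, ...] | None = None
    physical_albedo: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("n_gloss", "n_lightness", "n_shapes"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise InvalidDesignError(f"{name} must be a positive integer, got {value!r}")
        for name, n in (
            ("physical_gloss", self.n_gloss),
            ("physical_albedo", self.n_lightness),
        ):
            mags = getattr(self, name)
            if mags is None:
                continue
            mags = tuple(float(m) for m in mags)
            object.__setattr__(self, name, mags)
            if len(mags) != n:
                raise InvalidDesignError(
                    f"{name} has {len(mags)} entries but the lattice has {n} levels"
                )
            diffs = np.diff(mags)
            if not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise InvalidDesignError(f"{name} must be strictly monotone")

    @property
    def n_stimuli(self) -> int:
        """Number of cells on the comparison grid (gloss x lightness)."""
        return self.n_gloss * self.n_lightness

    @property
    def n_surfaces(self) -> int:
        """Total rendered surfaces, including shape replicates."""
        return self.n_gloss * self.n_lightness * self.n_shapes

    def indices(self) -> list[StimulusIndex]:
        """All lattice cells in row-major (gloss-outer) order."""
        return [
            StimulusIndex(g, l)
            for g in range(1, self.n_gloss + 1)
            for l in range(1, self.n_lightness + 1)
        ]

    def contains(self, s: StimulusIndex) -> bool:
        return 1 <= s.g <= self.n_gloss and 1 <= s.l <= self.n_lightness


def build_lattice(
    n_gloss: int,
    n_lightness: int,
    n_shapes: int = 1,
    physical_gloss: Sequence[float] | None = None,
    physical_albedo: Sequence[float] | None = None,
) -> StimulusLattice:
    """Construct a validated factorial stimulus lattice."""
    return StimulusLattice(
        n_gloss=n_gloss,
        n_lightness=n_lightness,
        n_shapes=n_shapes,
        physical_gloss=tuple(physical_gloss) if physical_gloss is not None else None,
        physical_albedo=tuple(physical_albedo) if physical_albedo is not None else None,
    )


def enumerate_pairs(
    lattice: StimulusLattice, include_self: bool = False
) -> list[tuple[StimulusIndex, StimulusIndex]]:
    """Every unordered pair of lattice cells, each listed exactly once.

    With ``include_self=False`` (the default, matching a design without
    self-comparisons) the count is C(n, 2) for n = n_gloss * n_lightness.
    """
    cells = lattice.indices()
    if include_self:
        return list(combinations_with_replacement(cells, 2))
    return list(combinations(cells, 2))


@dataclass
class TrialSchedule:
    """An ordered list of paired-comparison trials for one observer.

    ``trials`` holds (first, second, repetition) triples; ``task`` is the
    judged attribute; ``seed`` records the randomization seed.
    """

    trials: list[tuple[StimulusIndex, StimulusIndex, int]]
    task: str
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise InvalidDesignError(f"task must be one of {TASKS}, got {self.task!r}")

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Long-format trial table (one row per trial)."""
        rows = [
            (t + 1, self.task, first.g, first.l, second.g, second.l, rep)
            for t, (first, second, rep) in enumerate(self.trials)
        ]
        return pd.DataFrame(rows, columns=TRIAL_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int | None = None) -> "TrialSchedule":
        tasks = frame["task"].unique()
        if len(tasks) != 1:
            raise InvalidDesignError(f"expected a single task, found {list(tasks)}")
        trials = [
            (
                StimulusIndex(int(r.first_g), int(r.first_l)),
                StimulusIndex(int(r.second_g), int(r.second_l)),
                int(r.repetition),
            )
            for r in frame.itertuples()
        ]
        return cls(trials=trials, task=str(tasks[0]), seed=seed)


def build_schedule(
    pairs: Sequence[tuple[StimulusIndex, StimulusIndex]],
    repetitions: int,
    seed: int | None = None,
    task: str = "gloss",
) -> TrialSchedule:
    """Randomized trial schedule: every pair repeated ``repetitions`` times.

    Trial order is shuffled and, independently per trial, which member of
    the pair is presented first.  Both randomizations derive from ``seed``,
    so equal seeds give bit-identical schedules.
    """
    if not pairs:
        raise InvalidDesignError("pair list is empty")
    if repetitions < 1:
        raise InvalidDesignError(f"repetitions must be >= 1, got {repetitions}")
    rng = np.random.default_rng(seed)
    entries = [(first, second, rep) for rep in range(1, repetitions + 1) for first, second in pairs]
    order = rng.permutation(len(entries))
    flip = rng.random(len(entries)) < 0.5
    trials = []
    for pos, idx in enumerate(order):
        first, second, rep = entries[idx]
        if flip[pos]:
            first, second = second, first
        trials.append((first, second, rep))
    return TrialSchedule(trials=trials, task=task, seed=seed)
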