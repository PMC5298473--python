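"""Conjoint proportion matrices, scale plots, and long-format exports.

A conjoint proportion matrix tabulates, for every ordered pair of lattice
stimuli, the fraction of trials on which the column stimulus was judged
greater (lighter or glossier) than the row stimulus.  Rows and columns
are arranged in nested blocks with a fixed convention for both tasks:
the outer index runs over gloss levels and each outer block is
subdivided by lightness levels.  A gloss judge uncontaminated by
lightness therefore produces constant inner blocks, while any dependence
on lightness — contamination in the gloss task, or the judged dimension
itself in the lightness task — shows up as gradients within them.
Self-comparison cells are undefined (the design excludes them) and
rendered as missing, not 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InvalidParameterError
from .fitting import FitResult, normalize_scales
from .models import choice_probability, decision_values
from .observers import GenerativeObserver


def _block_index(n_gloss: int, n_lightness: int) -> pd.MultiIndex:
    """Nested block ordering: gloss outer, lightness inner (both tasks)."""
    tuples = [
        (g, l) for g in range(1, n_gloss + 1) for l in range(1, n_lightness + 1)
    ]
    return pd.MultiIndex.from_tuples(tuples, names=("g", "l"))


@dataclass
class ConjointMatrix:
    """Choice proportions for every ordered stimulus pair.

    ``proportions[row, col]`` is the fraction of trials on which the
    column stimulus was judged greater than the row stimulus; ``counts``
    holds the number of contributing trials (None for analytic
    predictions).  Complement symmetry holds wherever both cells are
    observed: p(a, b) + p(b, a) = 1.
    """

    proportions: pd.DataFrame
    counts: pd.DataFrame | None
    task: str

    @property
    def n_stimuli(self) -> int:
        return self.proportions.shape[0]

    def to_long(self) -> pd.DataFrame:
        """Long format with one row per ordered pair: the row stimulus's
        levels, the column stimulus's levels, trial count, proportion."""
        idx = self.proportions.index
        outer, inner = idx.names
        rows = []
        for ri, row_key in enumerate(idx):
            for ci, col_key in enumerate(idx):
                n = None if self.counts is None else int(self.counts.iat[ri, ci])
                rows.append(
                    {
                        f"row_{outer}": row_key[0],
                        f"row_{inner}": row_key[1],
                        f"col_{outer}": col_key[0],
                        f"col_{inner}": col_key[1],
                        "n_trials": n,
                        "proportion": self.proportions.iat[ri, ci],
                    }
                )
        return pd.DataFrame(rows)


def _positions(frame: pd.DataFrame, n_lightness: int):
    """Map each trial's stimuli to their row/col position in block order."""
    fg = frame["first_g"].to_numpy(dtype=int) - 1
    fl = frame["first_l"].to_numpy(dtype=int) - 1
    sg = frame["second_g"].to_numpy(dtype=int) - 1
    sl = frame["second_l"].to_numpy(dtype=int) - 1
    return fg * n_lightness + fl, sg * n_lightness + sl


def conjoint_matrix(
    trials: pd.DataFrame, n_gloss: int = 5, n_lightness: int = 5
) -> ConjointMatrix:
    """Aggregate a trial table into a conjoint proportion matrix.

    Repetitions and presentation order are pooled per unordered pair; the
    table must contain a single task.
    """
    tasks = trials["task"].unique()
    if len(tasks) != 1:
        raise DataError(f"trial table mixes tasks {list(tasks)}")
    task = str(tasks[0])
    n = n_gloss * n_lightness
    first_pos, second_pos = _positions(trials, n_lightness)
    y = trials["response"].to_numpy(dtype=int)

    greater = np.zeros((n, n))
    counts = np.zeros((n, n))
    # response 1 = first judged greater: credit cell (row=second, col=first)
    np.add.at(greater, (second_pos, first_pos), y)
    np.add.at(greater, (first_pos, second_pos), 1 - y)
    np.add.at(counts, (first_pos, second_pos), 1)
    np.add.at(counts, (second_pos, first_pos), 1)

    with np.errstate(invalid="ignore"):
        props = np.where(counts > 0, greater / np.maximum(counts, 1), np.nan)
    index = _block_index(n_gloss, n_lightness)
    return ConjointMatrix(
        proportions=pd.DataFrame(props, index=index, columns=index),
        counts=pd.DataFrame(counts.astype(int), index=index, columns=index),
        task=task,
    )


def predict_matrix(observer: GenerativeObserver) -> ConjointMatrix:
    """Analytic expected proportions Phi(delta / sigma) for every ordered
    pair (no sampling); simulation aggregates converge to this matrix."""
    scales = observer.scales
    task = observer.spec.judged
    n_gloss, n_lightness = scales.n_gloss, scales.n_lightness
    index = _block_index(n_gloss, n_lightness)
    cells = list(index)
    frame = pd.DataFrame(
        [
            {"first_g": cg, "first_l": cl, "second_g": rg, "second_l": rl}
            for rg, rl in cells
            for cg, cl in cells
        ]
    )
    # entry (row, col) = P(col judged greater) = Phi(delta(col, row) / sigma)
    delta = decision_values(scales, frame, observer.spec)
    props = choice_probability(delta, scales.sigma).reshape(len(cells), len(cells))
    np.fill_diagonal(props, np.nan)
    return ConjointMatrix(
        proportions=pd.DataFrame(props, index=index, columns=index),
        counts=None,
        task=task,
    )


def plot_conjoint_matrix(matrix: ConjointMatrix, path, title: str | None = None) -> None:
    """Render the matrix as a heat map with the nested block grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = matrix.n_stimuli
    outer = len(matrix.proportions.index.levels[0])
    inner = n // outer
    fig, ax = plt.subplots(figsize=(7, 6.5))
    im = ax.imshow(
        matrix.proportions.to_numpy(), vmin=0, vmax=1, cmap="gray", origin="upper"
    )
    for k in range(1, outer):
        ax.axhline(k * inner - 0.5, color="tab:red", lw=1.2)
        ax.axvline(k * inner - 0.5, color="tab:red", lw=1.2)
    outer_name, inner_name = matrix.proportions.index.names
    ax.set_xlabel(f"column stimulus ({outer_name} outer, {inner_name} inner)")
    ax.set_ylabel(f"row stimulus ({outer_name} outer, {inner_name} inner)")
    ticks = [i * inner + (inner - 1) / 2 for i in range(outer)]
    ax.set_xticks(ticks, [str(i + 1) for i in range(outer)])
    ax.set_yticks(ticks, [str(i + 1) for i in range(outer)])
    ax.set_title(title or f"Conjoint proportions ({matrix.task} task)")
    fig.colorbar(im, ax=ax, label="P(column judged greater)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scales(fits, path, normalized: bool = True, title: str | None = None) -> None:
    """Plot fitted gloss and lightness scale profiles, optionally averaged
    over several observers' fits with standard-error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(fits, FitResult):
        fits = [fits]
    fits = list(fits)
    if not fits:
        raise InvalidParameterError("no fits to plot")
    scale_sets = [normalize_scales(f) if normalized else f.scales for f in fits]
    psi_g = np.array([s.psi_gloss for s in scale_sets])
    psi_l = np.array([s.psi_lightness for s in scale_sets])
    levels_g = np.arange(1, psi_g.shape[1] + 1)
    levels_l = np.arange(1, psi_l.shape[1] + 1)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for values, levels, label, color in (
        (psi_g, levels_g, "gloss", "tab:blue"),
        (psi_l, levels_l, "lightness", "tab:red"),
    ):
        mean = values.mean(axis=0)
        sem = values.std(axis=0, ddof=1) / np.sqrt(len(fits)) if len(fits) > 1 else None
        ax.errorbar(levels, mean, yerr=sem, marker="o", color=color, label=label)
    ax.axhline(0, color="0.7", lw=0.8)
    ax.set_xlabel("stimulus level")
    ax.set_ylabel("normalized scale value" if normalized else "scale value (sigma units)")
    ax.legend()
    ax.set_title(title or f"{fits[0].spec.model} model estimates ({fits[0].spec.judged} task)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
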