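"""Conjoint proportion matrices and their block structure."""

import numpy as np
import pandas as pd
import pytest

from glossjoint import (
    conjoint_matrix,
    make_observer,
    plot_conjoint_matrix,
    plot_scales,
    predict_matrix,
    simulate_responses,
)
from glossjoint.errors import DataError
from glossjoint.studies import simulate_observer_trials


@pytest.fixture(scope="module")
def independent_matrix():
    trials, observer = simulate_observer_trials("independent_gloss", 0.0, seed=21)
    return conjoint_matrix(trials), observer


def test_matrix_shape_and_block_ordering(independent_matrix):
    matrix, _ = independent_matrix
    assert matrix.proportions.shape == (25, 25)
    # gloss task: outer blocks index gloss, inner index lightness
    assert matrix.proportions.index.names == ("g", "l")
    assert list(matrix.proportions.index[:5]) == [(1, l) for l in range(1, 6)]


def test_complement_symmetry(independent_matrix):
    matrix, _ = independent_matrix
    P = matrix.proportions.to_numpy()
    observed = ~np.isnan(P)
    assert np.allclose((P + P.T)[observed & observed.T], 1.0)


def test_self_comparisons_are_missing(independent_matrix):
    matrix, _ = independent_matrix
    assert np.isnan(np.diag(matrix.proportions.to_numpy())).all()
    assert (np.diag(matrix.counts.to_numpy()) == 0).all()


def test_counts_cover_design(independent_matrix):
    matrix, _ = independent_matrix
    counts = matrix.counts.to_numpy()
    off = counts[~np.eye(25, dtype=bool)]
    assert off.sum() == 2 * 900  # each trial credits both ordered cells
    assert set(np.unique(off)) == {3}


def test_independent_observer_inner_blocks_constant():
    """Analytic matrix of an uncontaminated observer: within every 5x5
    inner block the expected proportion is constant."""
    pm = predict_matrix(make_observer("independent_gloss"))
    P = pm.proportions.to_numpy()
    for bi in range(5):
        for bj in range(5):
            if bi == bj:
                continue
            block = P[5 * bi : 5 * bi + 5, 5 * bj : 5 * bj + 5]
            assert np.nanstd(block) == pytest.approx(0.0, abs=1e-12)


def test_contaminated_observer_shows_inner_gradient():
    pm = predict_matrix(make_observer("additive_contaminated", w=-0.32))
    P = pm.proportions.to_numpy()
    block = P[0:5, 5:10]  # gloss 1 rows vs gloss 2 columns
    # columns: lightness of the column stimulus; w < 0 means lighter
    # column stimuli are judged glossy less often
    assert np.all(np.diff(block, axis=1) < 0)


def test_contrast_observer_gradient_within_blocks():
    pm = predict_matrix(make_observer("contrast_center_lightness"))
    P = pm.proportions.to_numpy()
    block = P[0:5, 5:10]
    # darker background (lower inner albedo level of the column stimulus)
    # makes the column's center lighter: proportion falls along the row
    assert np.all(np.diff(block, axis=1) < 0)


def test_predict_matrix_diagonal_and_chance_cells():
    pm = predict_matrix(make_observer("independent_gloss"))
    P = pm.proportions.to_numpy()
    assert np.isnan(np.diag(P)).all()
    # equal judged levels, different irrelevant levels -> exactly chance
    assert P[0, 1] == pytest.approx(0.5)


def test_simulated_matrix_converges_to_analytic():
    """At 1e5 repetitions per pair (single pair, binomial bound) the
    aggregated proportion matches the analytic prediction."""
    from glossjoint import StimulusIndex, build_schedule

    observer = make_observer("additive_contaminated", w=-0.32, seed=13)
    a, b = StimulusIndex(2, 3), StimulusIndex(3, 1)
    schedule = build_schedule([(a, b)], 100_000, seed=13, task="gloss")
    frame = simulate_responses(observer, schedule)
    matrix = conjoint_matrix(frame)
    pm = predict_matrix(observer)
    key_a, key_b = (a.g, a.l), (b.g, b.l)
    expected = pm.proportions.loc[[key_a], [key_b]].iat[0, 0]
    got = matrix.proportions.loc[[key_a], [key_b]].iat[0, 0]
    assert abs(got - expected) < 4 * np.sqrt(expected * (1 - expected) / 100_000)


def test_matrix_invariant_to_trial_and_presentation_order():
    trials, _ = simulate_observer_trials("additive_contaminated", -0.2, seed=17)
    shuffled = trials.sample(frac=1.0, random_state=0).reset_index(drop=True)
    flipped = trials.copy()
    flipped[["first_g", "first_l", "second_g", "second_l"]] = trials[
        ["second_g", "second_l", "first_g", "first_l"]
    ].to_numpy()
    flipped["response"] = 1 - trials["response"]
    for variant in (shuffled, flipped):
        pd.testing.assert_frame_equal(
            conjoint_matrix(variant).proportions, conjoint_matrix(trials).proportions
        )


def test_mixed_tasks_rejected():
    trials, _ = simulate_observer_trials("additive_contaminated", -0.2, seed=18)
    mixed = trials.copy()
    mixed.loc[0, "task"] = "lightness"
    with pytest.raises(DataError):
        conjoint_matrix(mixed)


def test_long_format_export(independent_matrix):
    matrix, _ = independent_matrix
    long = matrix.to_long()
    assert len(long) == 25 * 25
    assert {"row_g", "row_l", "col_g", "col_l", "n_trials", "proportion"} <= set(long.columns)
    assert long["n_trials"].sum() == 2 * 900


def test_plots_write_files(tmp_path, independent_matrix):
    from glossjoint import ModelSpec, fit

    matrix, _ = independent_matrix
    mpath = tmp_path / "matrix.png"
    plot_conjoint_matrix(matrix, mpath)
    assert mpath.stat().st_size > 0
    trials, _ = simulate_observer_trials("additive_contaminated", -0.32, seed=19)
    result = fit(trials, ModelSpec("additive", "gloss"))
    spath = tmp_path / "scales.png"
    plot_scales([result, result], spath)
    assert spath.stat().st_size > 0
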