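"""Maximum-likelihood fitting: design matrices, likelihoods, recovery."""

import numpy as np
import pandas as pd
import pytest

from glossjoint import (
    ModelSpec,
    PerceptualScales,
    build_design_matrix,
    contamination_index,
    contamination_summary,
    count_free_params,
    count_params_unanchored,
    fit,
    log_likelihood_direct,
    normalize_scales,
)
from glossjoint.errors import (
    DataError,
    InvalidParameterError,
    NormalizationError,
    SeparationWarning,
)
from glossjoint.fitting import _nll_and_grad
from glossjoint.studies import simulate_observer_trials


def _trial_row(first, second, response, task="gloss"):
    return {
        "trial": 1, "task": task,
        "first_g": first[0], "first_l": first[1],
        "second_g": second[0], "second_l": second[1],
        "repetition": 1, "response": response,
    }


@pytest.mark.parametrize(
    "model, judged, expected",
    [
        ("additive", "gloss", 8),
        ("full", "gloss", 24),
        ("independent", "gloss", 4),
        ("independent", "lightness", 4),
    ],
)
def test_free_param_counts(model, judged, expected):
    assert count_free_params(ModelSpec(model, judged), 5, 5) == expected


def test_unanchored_counts_and_anchoring_arithmetic():
    """Anchoring removes one value per anchored quantity plus sigma."""
    add = ModelSpec("additive", "gloss")
    assert count_params_unanchored(add) == 11
    assert count_params_unanchored(add) - 2 - 1 == count_free_params(add)
    ind = ModelSpec("independent", "gloss")
    assert count_params_unanchored(ind) == 6
    full = ModelSpec("full", "gloss")
    assert count_params_unanchored(full) - 1 - 1 == count_free_params(full) == 24


def test_design_matrix_shapes_and_anchor_row():
    spec = ModelSpec("additive", "gloss")
    trials = pd.DataFrame([_trial_row((3, 3), (3, 3), 1)])
    dm = build_design_matrix(trials, spec)
    assert dm.X.shape == (1, 8)
    assert np.all(dm.X == 0)  # anchored cell vs itself


def test_design_matrix_single_trial_encoding():
    spec = ModelSpec("additive", "gloss")
    trials = pd.DataFrame([_trial_row((1, 2), (2, 1), 1)])
    dm = build_design_matrix(trials, spec)
    row = dict(zip(dm.columns, dm.X[0]))
    assert row[("g", 1)] == 1 and row[("g", 2)] == -1
    assert row[("l", 2)] == 1 and row[("l", 1)] == -1
    assert np.count_nonzero(dm.X[0]) == 4


def test_design_matrix_rejects_out_of_range_levels():
    trials = pd.DataFrame([_trial_row((6, 1), (1, 1), 0)])
    with pytest.raises(DataError):
        build_design_matrix(trials, ModelSpec("additive", "gloss"))


@pytest.mark.parametrize("model", ["independent", "additive", "full"])
def test_design_matrix_likelihood_equals_direct_evaluation(model):
    """Regression and trial-by-trial likelihoods agree to 1e-10 on small
    random datasets with random parameter values."""
    rng = np.random.default_rng(123)
    spec = ModelSpec(model, "gloss")
    for _ in range(5):
        n = int(rng.integers(5, 51))
        trials = pd.DataFrame(
            [
                _trial_row(
                    tuple(rng.integers(1, 6, 2)), tuple(rng.integers(1, 6, 2)),
                    int(rng.integers(0, 2)),
                )
                for _ in range(n)
            ]
        )
        dm = build_design_matrix(trials, spec)
        beta = rng.normal(scale=0.8, size=dm.n_free_params)
        sign = 2.0 * trials["response"].to_numpy() - 1.0
        nll, _ = _nll_and_grad(beta, dm.X, sign)
        from glossjoint.fitting import _scales_from_beta

        scales = _scales_from_beta(beta, dm.columns, spec, 5, 5)
        assert -nll == pytest.approx(
            log_likelihood_direct(trials, scales, spec), abs=1e-10
        )


def test_fit_matches_statsmodels_probit(contaminated_trials):
    """Independent route: statsmodels probit on the same design matrix."""
    import statsmodels.api as sm

    trials, _ = contaminated_trials
    spec = ModelSpec("additive", "gloss")
    result = fit(trials, spec)
    dm = build_design_matrix(trials, spec)
    sm_fit = sm.Probit(trials["response"].to_numpy(), dm.X).fit(disp=0)
    assert np.allclose(result.estimates, sm_fit.params, atol=1e-4)
    assert result.log_likelihood == pytest.approx(sm_fit.llf, abs=1e-6)
    assert np.allclose(result.std_errors, sm_fit.bse, atol=1e-3)


def test_fit_reproducible_and_anchored(contaminated_trials):
    trials, _ = contaminated_trials
    spec = ModelSpec("additive", "gloss")
    a, b = fit(trials, spec), fit(trials, spec)
    assert a.log_likelihood == pytest.approx(b.log_likelihood, abs=1e-9)
    assert np.allclose(a.estimates, b.estimates, atol=1e-8)
    assert a.scales.psi_gloss[2] == 0.0 and a.scales.psi_lightness[2] == 0.0
    assert a.log_likelihood <= 0
    assert a.n_free_params == 8


def test_nested_log_likelihood_ordering(contaminated_trials):
    trials, _ = contaminated_trials
    ll = {
        model: fit(trials, ModelSpec(model, "gloss"), compute_std_errors=False).log_likelihood
        for model in ("independent", "additive", "full")
    }
    assert ll["full"] >= ll["additive"] >= ll["independent"]


def test_anchoring_invariance_under_generative_shift():
    """Adding a constant to one dimension's generative scale changes no
    decision difference, hence no data and no anchored estimate."""
    from glossjoint import build_lattice, build_schedule, enumerate_pairs
    from glossjoint.observers import GenerativeObserver, simulate_responses

    spec = ModelSpec("additive", "gloss")
    base = PerceptualScales(np.linspace(0, 4, 5), -0.32 * np.linspace(0, 4, 5))
    shifted = PerceptualScales(base.psi_gloss + 5.0, base.psi_lightness - 2.0)
    schedule = build_schedule(enumerate_pairs(build_lattice(5, 5)), 3, seed=6)
    r1 = simulate_responses(GenerativeObserver(base, spec, seed=6), schedule)
    r2 = simulate_responses(GenerativeObserver(shifted, spec, seed=6), schedule)
    pd.testing.assert_frame_equal(r1, r2)
    f1 = fit(r1, spec, compute_std_errors=False)
    f2 = fit(r2, spec, compute_std_errors=False)
    assert np.allclose(f1.estimates, f2.estimates, atol=1e-8)


def test_fit_rejects_nonbinary_responses(contaminated_trials):
    trials, _ = contaminated_trials
    bad = trials.copy()
    bad.loc[0, "response"] = 2
    with pytest.raises(DataError):
        fit(bad, ModelSpec("additive", "gloss"))


def test_separation_warns_and_clamps():
    """A level that always wins has a divergent ML estimate."""
    rows = []
    for l in range(1, 6):
        for _ in range(10):
            rows.append(_trial_row((5, l), (1, l), 1))
            rows.append(_trial_row((1, l), (5, l), 0))
    trials = pd.DataFrame(rows)
    with pytest.warns(SeparationWarning):
        result = fit(trials, ModelSpec("independent", "gloss"))
    assert np.abs(result.estimates).max() == pytest.approx(10.0)
    assert result.converged


def test_normalize_scales_definition_and_idempotence():
    scales = PerceptualScales(
        [0.0, 1.0, 2.0, 3.0, 4.0], [0.0, -0.3, -0.6, -0.9, -1.28]
    )
    normalized = normalize_scales(scales)
    assert np.allclose(normalized.psi_gloss, np.array([0, 1, 2, 3, 4]) / 4.0)
    assert np.allclose(normalized.psi_lightness, np.array([0, -0.3, -0.6, -0.9, -1.28]) / 4.0)
    again = normalize_scales(normalized)
    assert np.allclose(again.psi_gloss, normalized.psi_gloss)
    assert np.all(np.sign(again.psi_lightness) == np.sign(scales.psi_lightness))
    with pytest.raises(NormalizationError):
        normalize_scales(PerceptualScales(np.zeros(5), np.zeros(5)))


def test_contamination_index_sign_and_magnitude():
    scales = PerceptualScales(np.linspace(0, 4, 5), -0.32 * np.linspace(0, 4, 5))
    assert contamination_index(scales) == pytest.approx(-0.32)


def test_contamination_index_requires_contamination_model(contaminated_trials):
    trials, _ = contaminated_trials
    result = fit(trials, ModelSpec("independent", "gloss"), compute_std_errors=False)
    with pytest.raises(InvalidParameterError):
        contamination_index(result)


def test_contamination_recovery_smoke():
    """Small-scale recovery: 10 observers, loose bound (the full-size
    study lives in the acceptance suite)."""
    indices = []
    for seed in range(10):
        trials, _ = simulate_observer_trials("additive_contaminated", -0.32, seed=seed)
        result = fit(trials, ModelSpec("additive", "gloss"), compute_std_errors=False)
        indices.append(contamination_index(result))
    assert np.mean(indices) == pytest.approx(-0.32, abs=0.05)


def test_independent_observer_secondary_estimates_near_zero():
    """Secondary-dimension estimates from an independent observer sit
    within 2 standard errors of zero for most parameters."""
    hits = total = 0
    for seed in range(8):
        trials, _ = simulate_observer_trials("independent_gloss", 0.0, seed=seed)
        result = fit(trials, ModelSpec("additive", "gloss"))
        for label, est, se in zip(result.columns, result.estimates, result.std_errors):
            if label[0] == "l":
                total += 1
                hits += abs(est) < 2 * se
    assert hits / total >= 0.90


def test_contamination_summary_reducers():
    fits = []
    for seed in range(6):
        trials, _ = simulate_observer_trials("additive_contaminated", -0.2, seed=seed)
        fits.append(fit(trials, ModelSpec("additive", "gloss"), compute_std_errors=False))
    per_obs = contamination_summary(fits)
    pooled = contamination_summary(fits, reducer="pooled_ratio")
    assert per_obs == pytest.approx(-0.2, abs=0.06)
    assert pooled == pytest.approx(per_obs, abs=0.05)
    with pytest.raises(InvalidParameterError):
        contamination_summary(fits, reducer="median")
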