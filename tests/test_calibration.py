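"""Target evaluation and the inverse problem."""

import pytest

from ubt_impact.calibration import (
    TARGET_ORDER,
    CalibrationTarget,
    calibrate,
    evaluate_targets,
    identifiability_scan,
)
from ubt_impact.params import ValidationError
from ubt_impact.synthetic import make_problem


def test_target_vector_has_stable_names(default_config):
    vals = evaluate_targets(default_config.hidden, default_config)
    assert tuple(vals) == TARGET_ORDER


def test_deathless_world_zeroes_mortality_targets(default_config):
    hidden = default_config.hidden.replace(
        cfr_severe_no_surgery=0.0,
        cfr_severe_surgery=0.0,
        cfr_nonsevere_resolved=0.0,
        nonatonic_death_load=0.0,
    )
    vals = evaluate_targets(hidden, default_config)
    for name in (
        "lives_saved_base",
        "pct_mortality_reduction",
        "lives_saved_nonsevere_only",
        "optimistic_delta_lives",
        "pct_increase_eff95_nonsevere",
    ):
        assert vals[name] == pytest.approx(0.0, abs=1e-9)
    # morbidity targets are unaffected by case fatality being zero
    assert vals["severe_cases_averted_nonsevere_only"] > 0


def test_recorded_targets_self_consistent():
    problem = make_problem(seed=11)
    config = problem.config()
    fresh = evaluate_targets(problem.true_hidden, config)
    for name, value in problem.recorded_targets.items():
        assert fresh[name] == pytest.approx(value, abs=1e-9)


def test_calibrate_requires_targets_and_feasible_bounds(default_config):
    with pytest.raises(ValidationError, match="at least one target"):
        calibrate([], free=["progression_prob"], bounds=None, seed=0, config=default_config)
    t = CalibrationTarget("lives_saved_base", 6547.0)
    with pytest.raises(ValidationError, match="infeasible bounds"):
        calibrate(
            [t],
            free=["progression_prob"],
            bounds={"progression_prob": (0.5, 0.1)},
            seed=0,
            config=default_config,
        )


def test_calibrate_empty_free_returns_defaults(default_config, printed_targets):
    res = calibrate(printed_targets, free=[], bounds=None, seed=0, config=default_config)
    assert res.fitted == default_config.hidden
    model = evaluate_targets(default_config.hidden, default_config)
    for t in printed_targets:
        assert res.residuals[t.name] == pytest.approx(model[t.name] - t.observed, abs=1e-9)


def test_calibrate_deterministic_given_seed(default_config):
    problem = make_problem(seed=3)
    targets = [
        CalibrationTarget(name, observed, tolerance=1.0)
        for name, observed in problem.recorded_targets.items()
        if observed != 0
    ]
    free = ["presevere_fraction", "progression_prob", "cfr_severe_no_surgery"]
    kwargs = dict(bounds=None, seed=42, config=default_config, n_starts=4,
                  include_reference_start=False)
    a = calibrate(targets, free, **kwargs)
    b = calibrate(targets, free, **kwargs)
    assert a.fitted == b.fitted
    assert a.objective == b.objective
    assert a.residuals == b.residuals


def test_objective_recomputable_from_residuals(default_config, printed_targets):
    res = calibrate(
        printed_targets,
        free=["progression_prob", "presevere_fraction"],
        bounds=None,
        seed=1,
        config=default_config,
        n_starts=2,
    )
    recomputed = sum(
        t.weight * (res.residuals[t.name] / t.observed) ** 2 for t in printed_targets
    )
    assert res.objective == pytest.approx(recomputed, abs=1e-9)


def test_synthetic_parameter_recovery(default_config):
    """Calibrating against a synthetic problem's recorded targets drives the
    objective to (numerically) zero."""
    from ubt_impact.synthetic import default_ranges

    free = [
        "uterotonic_efficacy",
        "presevere_fraction",
        "progression_prob",
        "rebleed_prob",
        "cfr_severe_no_surgery",
        "nonatonic_death_load",
    ]
    problem = make_problem(seed=5, ranges={p: default_ranges()[p] for p in free})
    targets = [
        CalibrationTarget(name, observed, tolerance=1.0)
        for name, observed in problem.recorded_targets.items()
        if abs(observed) > 1e-6
    ]
    res = calibrate(
        targets,
        free,
        bounds=None,
        seed=7,
        config=problem.config().replace(hidden=default_config.hidden),
        n_starts=6,
        include_reference_start=False,
    )
    assert res.objective < 1e-6


def test_identifiability_scan_flags_inert_parameter(fitted_hidden, default_config):
    """Home surgical access cannot influence counterfactual deltas (the
    balloon never reaches home births), so its profile is flat."""
    config = default_config.replace(hidden=fitted_hidden)
    delta_targets = [
        CalibrationTarget("lives_saved_base", 6547.0),
        CalibrationTarget("lives_saved_nonsevere_only", 1148.0),
        CalibrationTarget("severe_cases_averted_nonsevere_only", 5287.0),
    ]
    free = ["surgery_access.home", "progression_prob", "rebleed_prob"]
    res = calibrate(
        delta_targets, free, bounds=None, seed=2, config=config,
        n_starts=2, include_reference_start=False, start=fitted_hidden,
    )
    profile = identifiability_scan(
        res,
        "surgery_access.home",
        [0.0, 0.05, 0.10, 0.15],
        delta_targets,
        config,
        seed=2,
        n_starts=1,
    )
    assert profile.flat


def test_identifiability_scan_rejects_out_of_bounds_grid(fitted_hidden, default_config):
    config = default_config.replace(hidden=fitted_hidden)
    targets = [CalibrationTarget("lives_saved_base", 6547.0)]
    res = calibrate(
        targets, ["progression_prob"], bounds=None, seed=0, config=config,
        n_starts=1, include_reference_start=False, start=fitted_hidden,
    )
    with pytest.raises(ValidationError, match="outside bounds"):
        identifiability_scan(res, "progression_prob", [0.9], targets, config)
    with pytest.raises(ValidationError, match="not among"):
        identifiability_scan(res, "rebleed_prob", [0.05], targets, config)
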