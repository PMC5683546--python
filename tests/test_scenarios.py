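"""Scenario comparison, scenario sets, and one-way sensitivity."""

import dataclasses

import numpy as np
import pytest

from ubt_impact import compare, one_way_sensitivity, run_config, run_scenario_set
from ubt_impact.params import ValidationError, load_packaged_config
from ubt_impact.scenarios import run_scenario


def _with_fitted(name, fitted_hidden):
    return load_packaged_config(name).replace(hidden=fitted_hidden)


def test_compare_with_itself_is_all_zero(ref_config):
    res = run_config(ref_config)
    impact = compare(res, res)
    assert all(v == 0.0 for v in impact.to_dict().values())


def test_compare_is_antisymmetric(ref_config):
    baseline = run_config(ref_config, baseline=True)
    scenario = run_config(ref_config)
    fwd = compare(baseline, scenario)
    # swapping arguments negates every delta except the percent, which is
    # rescaled to the swapped denominator
    rev = compare(scenario, baseline)
    assert rev.lives_saved == pytest.approx(-fwd.lives_saved, rel=1e-12)
    assert rev.surgeries_averted == pytest.approx(-fwd.surgeries_averted, rel=1e-12)
    assert rev.severe_cases_averted == pytest.approx(-fwd.severe_cases_averted, rel=1e-12)
    assert rev.anemia_cases_averted == pytest.approx(-fwd.anemia_cases_averted, rel=1e-12)


def test_compare_rejects_mismatched_regions(ref_config):
    other = ref_config.replace(
        region=dataclasses.replace(ref_config.region, live_births=1_000_000)
    )
    with pytest.raises(ValidationError, match="RegionInputs"):
        compare(run_config(ref_config, baseline=True), run_config(other))


def test_scenario_set_matches_single_compare(ref_config):
    table = run_scenario_set([ref_config])
    single = run_scenario(ref_config)
    row = table.loc[ref_config.scenario.name]
    for field, value in single.to_dict().items():
        assert row[field] == pytest.approx(value, rel=1e-12)


def test_scenario_set_orders_lives_saved_by_severe_efficacy(fitted_hidden):
    configs = [
        _with_fitted(name, fitted_hidden)
        for name in ("pessimistic.yaml", "base.yaml", "optimistic.yaml")
    ]
    table = run_scenario_set(configs)
    lives = table["lives_saved"].to_numpy()
    assert lives[0] < lives[1] < lives[2]
    assert list(table.index) == ["pessimistic", "base", "optimistic"]


def test_nonsevere_only_is_more_modest_than_base(fitted_hidden):
    configs = [
        _with_fitted("base.yaml", fitted_hidden),
        _with_fitted("nonsevere_only.yaml", fitted_hidden),
    ]
    table = run_scenario_set(configs)
    assert table.loc["nonsevere_only", "lives_saved"] < table.loc["base", "lives_saved"]


def test_scenario_set_empty_and_duplicates(ref_config):
    assert run_scenario_set([]).empty
    with pytest.raises(ValidationError, match="duplicate"):
        run_scenario_set([ref_config, ref_config])


def test_sensitivity_affine_in_severe_efficacy(ref_config):
    rows = one_way_sensitivity(ref_config, "ubt.efficacy_severe", [0.60, 0.70, 0.80])
    x = np.array([r.tested_value for r in rows])
    y = np.array([r.lives_saved for r in rows])
    slope, intercept = np.polyfit(x, y, 1)
    assert np.abs(y - (slope * x + intercept)).max() < 1e-9 * max(1.0, y.max())


def test_sensitivity_base_value_has_zero_delta(ref_config):
    rows = one_way_sensitivity(ref_config, "ubt.efficacy_severe", [0.70])
    assert rows[0].delta_vs_base == pytest.approx(0.0, abs=1e-9)


def test_sensitivity_empty_values_and_bad_path(ref_config):
    assert one_way_sensitivity(ref_config, "ubt.efficacy_severe", []) == []
    with pytest.raises(KeyError, match="ubt.efficacy_extreme"):
        one_way_sensitivity(ref_config, "ubt.efficacy_extreme", [0.5])


@pytest.mark.parametrize(
    "path",
    [
        "ubt.penetration.clinic",
        "ubt.penetration.hospital",
        "ubt.utilization.clinic",
        "ubt.efficacy_nonsevere",
        "ubt.efficacy_severe",
    ],
)
def test_monotone_in_coverage_and_efficacy(ref_config, path):
    """More availability, use, or efficacy never costs lives and never
    reduces balloon resolutions (5-point grids)."""
    grid = np.linspace(0.05, 0.85, 5)
    rows = one_way_sensitivity(ref_config, path, list(grid))
    lives = [r.lives_saved for r in rows]
    assert all(b >= a - 1e-9 for a, b in zip(lives, lives[1:]))
    tree = ref_config.to_dict()
    resolved = []
    from ubt_impact.params import ModelConfig, set_path

    for v in grid:
        cfg = ModelConfig.from_dict(set_path(tree, path, float(v)))
        res = run_config(cfg)
        resolved.append(
            res.total("resolved_by_ubt_nonsevere") + res.total("resolved_by_ubt_severe")
        )
    assert all(b >= a - 1e-9 for a, b in zip(resolved, resolved[1:]))
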