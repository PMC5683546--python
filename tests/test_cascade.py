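"""Cohort allocation and cascade flow accounting."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ubt_impact import (
    Constants,
    allocate_cohort,
    anemia_from_severe,
    run_cascade,
)
from ubt_impact.params import (
    REGION_SSA_2018,
    UBT_REFERENCE,
    ValidationError,
)
from ubt_impact.synthetic import reference_config, sample_params


# Hand products of the published inputs (live births x share x PPH rate x
# atonic fraction), frozen independently of the implementation.
HOME_BIRTHS = 34_806_654 * 0.50
HOME_PPH = 34_806_654 * 0.50 * 0.12
HOME_ATONIC = 34_806_654 * 0.50 * 0.12 * 0.90
HOSPITAL_PPH = 34_806_654 * 0.15 * 0.08


def test_allocation_reproduces_hand_products():
    alloc = allocate_cohort(REGION_SSA_2018)
    assert alloc["home"]["births"] == pytest.approx(HOME_BIRTHS, abs=1e-6)
    assert alloc["home"]["pph_cases"] == pytest.approx(HOME_PPH, abs=1e-6)
    assert alloc["home"]["atonic_cases"] == pytest.approx(HOME_ATONIC, abs=1e-6)
    assert alloc["hospital"]["pph_cases"] == pytest.approx(HOSPITAL_PPH, abs=1e-6)
    # cross-check: summed PPH equals the share-weighted rate product
    total_pph = sum(alloc[s]["pph_cases"] for s in alloc)
    expected = sum(
        34_806_654 * share * rate
        for share, rate in [(0.50, 0.12), (0.35, 0.10), (0.15, 0.08)]
    )
    assert total_pph == pytest.approx(expected, rel=1e-12)


def test_zero_cohort_allocates_zeros():
    region = dataclasses.replace(REGION_SSA_2018, live_births=0)
    alloc = allocate_cohort(region)
    assert all(v == 0.0 for by_setting in alloc.values() for v in by_setting.values())


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_flow_conservation_for_random_parameters(seed):
    """Branch probabilities sum to 1 and atonic inflow equals terminal outflow."""
    hidden = sample_params(seed)
    cfg = reference_config(hidden=hidden)
    for filt in ("all", "nonsevere_only"):
        res = run_cascade(cfg.region, cfg.ubt, hidden, cfg.constants, filt)
        assert (res.conservation_errors() < 1e-9).all()
        assert res.total("deaths") <= res.total("pph_cases")


def test_inert_intervention_equals_baseline(fitted_hidden):
    cfg = reference_config(hidden=fitted_hidden)
    baseline = run_cascade(cfg.region, None, fitted_hidden, cfg.constants)
    for inert in (
        UBT_REFERENCE.replace(penetration={s: 0.0 for s in ("home", "clinic", "hospital")}),
        UBT_REFERENCE.replace(utilization={s: 0.0 for s in ("home", "clinic", "hospital")}),
        UBT_REFERENCE.replace(efficacy_nonsevere=0.0, efficacy_severe=0.0),
    ):
        res = run_cascade(cfg.region, inert, fitted_hidden, cfg.constants)
        diff = (res.per_setting - baseline.per_setting).abs().to_numpy().max()
        assert diff < 1e-9


def test_perfect_first_line_rescue_stops_progression(fitted_hidden):
    """Universal, fully effective nonsevere tamponade (with no rebleeding)
    leaves nothing to progress past the threshold in facility settings."""
    hidden = fitted_hidden.replace(presevere_fraction=0.0, rebleed_prob=0.0)
    ubt = UBT_REFERENCE.replace(
        penetration={"home": 0.0, "clinic": 1.0, "hospital": 1.0},
        utilization={"home": 0.0, "clinic": 1.0, "hospital": 1.0},
        efficacy_nonsevere=1.0,
    )
    cfg = reference_config(hidden=hidden)
    res = run_cascade(cfg.region, ubt, hidden, cfg.constants)
    assert res.per_setting.loc["clinic", "progressed_to_severe"] == pytest.approx(0.0, abs=1e-9)
    assert res.per_setting.loc["hospital", "progressed_to_severe"] == pytest.approx(0.0, abs=1e-9)


def test_unknown_population_filter_raises(fitted_hidden):
    cfg = reference_config(hidden=fitted_hidden)
    with pytest.raises(ValidationError, match="population_filter"):
        run_cascade(cfg.region, cfg.ubt, fitted_hidden, cfg.constants, "everyone")


@pytest.mark.parametrize(
    "severe,expected",
    [(5287.0, 634.44), (0.0, 0.0), (100.0, 12.0)],
)
def test_anemia_fraction_of_severe(severe, expected):
    assert anemia_from_severe(severe, Constants()) == pytest.approx(expected, abs=1e-9)


def test_anemia_rejects_negative_input():
    with pytest.raises(ValidationError, match="severe_count"):
        anemia_from_severe(-1.0, Constants())


def test_tidy_frame_layout(fitted_hidden):
    cfg = reference_config(hidden=fitted_hidden)
    res = run_cascade(cfg.region, cfg.ubt, fitted_hidden, cfg.constants)
    tidy = res.to_tidy_frame()
    assert list(tidy.columns) == ["setting", "severity", "field", "value"]
    assert set(tidy["setting"]) == {"home", "clinic", "hospital", "total"}
    totals = tidy[tidy.setting == "total"].set_index("field")["value"]
    assert totals["deaths"] == pytest.approx(res.total("deaths"), rel=1e-12)
    assert np.isfinite(tidy["value"]).all()
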