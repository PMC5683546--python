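"""Scenario comparison, scenario sets, and one-way sensitivity analysis.

Impact is always a counterfactual delta between two cascade runs over the
same cohort: a no-UBT baseline and an intervention scenario.  Anemia averted
follows the published arithmetic — the severe-anemia fraction applied to
severe hemorrhage cases averted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cascade import CascadeResult, run_config
from .params import (
    HiddenParams,
    ModelConfig,
    ValidationError,
    get_path,
    set_path,
)

IMPACT_FIELDS = (
    "lives_saved",
    "pct_mortality_reduction",
    "surgeries_averted",
    "severe_cases_averted",
    "anemia_cases_averted",
)


@dataclass(frozen=True)
class ImpactSummary:
    """Counterfactual deltas between a baseline and an intervention run."""

    lives_saved: float
    pct_mortality_reduction: float
    surgeries_averted: float
    severe_cases_averted: float
    anemia_cases_averted: float

    def to_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in IMPACT_FIELDS}


@dataclass(frozen=True)
class SensitivityRow:
    """One tested value in a one-way sensitivity sweep."""

    parameter: str
    tested_value: float
    lives_saved: float
    delta_vs_base: float


def compare(baseline: CascadeResult, scenario: CascadeResult,
            anemia_fraction: float = 0.12) -> ImpactSummary:
    """Impact of `scenario` relative to `baseline` (negative deltas permitted)."""
    if (
        abs(baseline.region.live_births - scenario.region.live_births) > 1e-6
        or baseline.region.setting_shares != scenario.region.setting_shares
        or baseline.region.pph_rate != scenario.region.pph_rate
    ):
        raise ValidationError(
            "compare() requires both results to come from the same RegionInputs"
        )
    base_deaths = baseline.total("deaths")
    lives = base_deaths - scenario.total("deaths")
    pct = 100.0 * lives / base_deaths if base_deaths > 0 else 0.0
    severe_averted = baseline.total("severe_cases") - scenario.total("severe_cases")
    return ImpactSummary(
        lives_saved=lives,
        pct_mortality_reduction=pct,
        surgeries_averted=baseline.total("surgeries") - scenario.total("surgeries"),
        severe_cases_averted=severe_averted,
        anemia_cases_averted=severe_averted * anemia_fraction,
    )


def run_scenario(config: ModelConfig, hidden: HiddenParams | None = None) -> ImpactSummary:
    """Run one scenario configuration against its own no-UBT baseline."""
    baseline = run_config(config, baseline=True, hidden=hidden)
    scenario = run_config(config, baseline=False, hidden=hidden)
    return compare(baseline, scenario, config.constants.anemia_fraction)


def run_scenario_set(
    configs: Sequence[ModelConfig], hidden: HiddenParams | None = None
) -> pd.DataFrame:
    """Impact summaries for a list of scenarios, all against the shared baseline.

    Every configuration must share the cohort (region) of the first one; the
    baseline is computed once from it.  Row order follows input order.
    """
    if len(configs) == 0:
        return pd.DataFrame(columns=list(IMPACT_FIELDS)).rename_axis("scenario")
    names = [c.scenario.name for c in configs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValidationError(f"duplicate scenario names: {sorted(dupes)}")
    baseline = run_config(configs[0], baseline=True, hidden=hidden)
    rows = {}
    for config in configs:
        scen = run_config(config, baseline=False, hidden=hidden)
        rows[config.scenario.name] = compare(
            baseline, scen, config.constants.anemia_fraction
        ).to_dict()
    table = pd.DataFrame.from_dict(rows, orient="index").loc[names, list(IMPACT_FIELDS)]
    table.index.name = "scenario"
    return table


def one_way_sensitivity(
    base_config: ModelConfig,
    parameter_path: str,
    values: Sequence[float],
) -> list[SensitivityRow]:
    """Sweep one dotted config path, holding everything else at base.

    ``parameter_path`` addresses the YAML schema, e.g. ``ubt.efficacy_severe``
    or ``hidden.progression_prob``.  Each tested value is run against the
    swept configuration's own baseline (so sweeps over cohort or hidden
    parameters remain internally consistent counterfactuals).
    """
    base_tree = base_config.to_dict()
    current = get_path(base_tree, parameter_path)  # raises KeyError naming path
    if not isinstance(current, (int, float)) or isinstance(current, bool):
        raise ValidationError(
            f"parameter path {parameter_path!r} does not address a numeric field "
            f"(found {type(current).__name__})"
        )
    base_lives = run_scenario(base_config).lives_saved
    rows: list[SensitivityRow] = []
    for v in values:
        tree = set_path(base_tree, parameter_path, float(v))
        config = ModelConfig.from_dict(tree)
        lives = run_scenario(config).lives_saved
        rows.append(
            SensitivityRow(
                parameter=parameter_path,
                tested_value=float(v),
                lives_saved=lives,
                delta_vs_base=lives - base_lives,
            )
        )
    return rows


def sensitivity_frame(rows: Sequence[SensitivityRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [r.__dict__ for r in rows],
        columns=["parameter", "tested_value", "lives_saved", "delta_vs_base"],
    )
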