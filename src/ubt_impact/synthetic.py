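"""Synthetic problems and the individual-level microsimulation oracle.

Two roles:

* generate complete hidden-parameter sets with recorded ground-truth target
  vectors, so calibration can be tested as a parameter-recovery problem with
  a known answer;
* simulate the cascade one delivery at a time through the *same* branch
  table the cohort arithmetic uses, providing a brute-force stochastic check
  on the expected-value model (law of large numbers: cohort counts must sit
  within a few standard errors of the microsimulation at large n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cascade import FLOW_FIELDS, Branch, branch_table
from .params import (
    DEFAULT_HIDDEN,
    SETTINGS,
    UBT_REFERENCE,
    UTEROTONIC_COVERAGE,
    REGION_SSA_2018,
    Constants,
    HiddenParams,
    InterventionSpec,
    ModelConfig,
    RegionInputs,
    ScenarioSpec,
    ValidationError,
)
from .calibration import evaluate_targets

_MAX_REJECTION_TRIES = 1000


def default_ranges() -> dict[str, tuple[float, float]]:
    """Plausible sampling windows: the default values ±50 %, clipped to [0, 1].

    ``nonatonic_death_load`` is a count, clipped only below at zero.
    """
    base = DEFAULT_HIDDEN.to_dict()
    flat = {
        "uterotonic_efficacy": base["uterotonic_efficacy"],
        "presevere_fraction": base["presevere_fraction"],
        "progression_prob": base["progression_prob"],
        "rebleed_prob": base["rebleed_prob"],
        "surgery_access.home": base["surgery_access"]["home"],
        "surgery_access.clinic": base["surgery_access"]["clinic"],
        "surgery_access.hospital": base["surgery_access"]["hospital"],
        "cfr_severe_no_surgery": base["cfr_severe_no_surgery"],
        "cfr_severe_surgery": base["cfr_severe_surgery"],
        "cfr_nonsevere_resolved": base["cfr_nonsevere_resolved"],
        "nonatonic_death_load": base["nonatonic_death_load"],
    }
    ranges = {}
    for path, v in flat.items():
        lo, hi = 0.5 * v, 1.5 * v
        if path != "nonatonic_death_load":
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        ranges[path] = (lo, hi)
    return ranges


def sample_params(
    seed: int, ranges: Mapping[str, tuple[float, float]] | None = None
) -> HiddenParams:
    """Draw one hidden-parameter set uniformly within `ranges`.

    Deterministic given the seed.  The orderings ``cfr_severe_surgery <=
    cfr_severe_no_surgery`` and ``rebleed_prob <= progression_prob`` are
    enforced by rejection (the whole vector is redrawn).
    """
    if ranges is None:
        ranges = default_ranges()
    if len(ranges) == 0:
        raise ValidationError("sample_params() requires a non-empty range map")
    for path, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValidationError(f"range for {path!r} has lo > hi: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    base = DEFAULT_HIDDEN.to_dict()
    paths = sorted(ranges)
    for _ in range(_MAX_REJECTION_TRIES):
        tree = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
        for path in paths:
            lo, hi = ranges[path]
            value = float(lo + rng.uniform() * (hi - lo))
            node = tree
            keys = path.split(".")
            for key in keys[:-1]:
                node = node[key]
            node[keys[-1]] = value
        if (
            tree["cfr_severe_surgery"] <= tree["cfr_severe_no_surgery"]
            and tree["rebleed_prob"] <= tree["progression_prob"]
        ):
            return HiddenParams.from_dict(tree)
    raise RuntimeError(
        "could not draw ordered parameters within "
        f"{_MAX_REJECTION_TRIES} tries; check the ranges"
    )


def reference_config(
    hidden: HiddenParams | None = None, scenario: ScenarioSpec | None = None
) -> ModelConfig:
    """A ModelConfig carrying the published cohort and UBT inputs."""
    return ModelConfig(
        region=REGION_SSA_2018,
        uterotonic_coverage=dict(UTEROTONIC_COVERAGE),
        ubt=UBT_REFERENCE,
        hidden=hidden if hidden is not None else DEFAULT_HIDDEN,
        constants=Constants(),
        scenario=scenario if scenario is not None else ScenarioSpec(),
    )


@dataclass(frozen=True)
class SyntheticProblem:
    """A calibration problem with known ground truth."""

    true_hidden: HiddenParams
    region: RegionInputs
    ubt: InterventionSpec
    recorded_targets: dict[str, float]
    seed: int

    def config(self) -> ModelConfig:
        return reference_config(hidden=self.true_hidden)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "region": self.region.to_dict(),
            "ubt": self.ubt.to_dict(),
            "hidden": self.true_hidden.to_dict(),
            "recorded_targets": dict(self.recorded_targets),
        }


def make_problem(
    seed: int, ranges: Mapping[str, tuple[float, float]] | None = None
) -> SyntheticProblem:
    """Sample hidden parameters and record the target vector they imply."""
    hidden = sample_params(seed, ranges)
    config = reference_config(hidden=hidden)
    recorded = evaluate_targets(hidden, config)
    return SyntheticProblem(
        true_hidden=hidden,
        region=config.region,
        ubt=config.ubt,
        recorded_targets=recorded,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Microsimulation oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MicrosimResult:
    """Stochastic cascade counts scaled to the cohort, with standard errors."""

    per_setting: pd.DataFrame
    se_per_setting: pd.DataFrame
    branches: list[Branch]
    n_individuals: int
    seed: int

    @property
    def totals(self) -> pd.Series:
        return self.per_setting.sum(axis=0)

    @property
    def se_totals(self) -> pd.Series:
        # independent individuals: variances add across settings
        return np.sqrt((self.se_per_setting**2).sum(axis=0))


def microsim_oracle(
    region: RegionInputs,
    ubt: InterventionSpec | None,
    hidden: HiddenParams,
    constants: Constants,
    n_individuals: int,
    seed: int,
    population_filter: str = "all",
    uterotonic_coverage: Mapping[str, float] | None = None,
) -> MicrosimResult:
    """Simulate `n_individuals` deliveries through the cascade event tree.

    Each delivery draws a setting, then a terminal branch of the per-setting
    event tree (a categorical draw over branch probabilities, which is
    distribution-identical to the underlying sequence of binary decisions),
    then survival.  Counts are scaled by ``live_births / n_individuals``;
    standard errors use the binomial formula on the per-individual
    indicators.  Deterministic given the seed.
    """
    if n_individuals < 0:
        raise ValidationError(f"n_individuals must be >= 0, got {n_individuals}")
    branches = branch_table(
        region, ubt, hidden, constants, population_filter, uterotonic_coverage
    )

    counts_rows: dict[str, dict[str, float]] = {}
    se_rows: dict[str, dict[str, float]] = {}
    n = int(n_individuals)
    scale = region.live_births / n if n > 0 else 0.0
    rng = np.random.default_rng(seed)

    shares = np.array([region.setting_shares[s] for s in SETTINGS])
    n_by_setting = (
        rng.multinomial(n, shares) if n > 0 else np.zeros(len(SETTINGS), dtype=int)
    )

    for s, n_s in zip(SETTINGS, n_by_setting):
        setting_branches = [b for b in branches if b.setting == s]
        probs = np.array([b.prob for b in setting_branches])
        probs = probs / probs.sum()
        raw = {f: 0.0 for f in FLOW_FIELDS}
        raw["births"] = float(n_s)
        if n_s > 0:
            leaf_counts = rng.multinomial(int(n_s), probs)
        else:
            leaf_counts = np.zeros(len(setting_branches), dtype=int)
        for b, k in zip(setting_branches, leaf_counts):
            if k == 0:
                continue
            deaths = float(rng.binomial(int(k), b.death_prob)) if b.death_prob > 0 else 0.0
            if b.pph:
                raw["pph_cases"] += k
            if b.pph and not b.atonic:
                raw["nonatonic_cases"] += k
            if b.atonic:
                raw["atonic_cases"] += k
            if b.resolved_by == "uterotonic":
                raw["resolved_by_uterotonic"] += k
            elif b.resolved_by == "ubt_nonsevere":
                raw["resolved_by_ubt_nonsevere"] += k
            elif b.resolved_by == "ubt_severe":
                raw["resolved_by_ubt_severe"] += k
            if b.severe and not b.progressed:
                raw["presevere_cases"] += k
            if b.progressed:
                raw["progressed_to_severe"] += k
            if b.severe:
                raw["severe_cases"] += k
                raw["severe_deaths"] += deaths
            if b.persistent_nonsevere:
                raw["persistent_nonsevere"] += k
            if b.unresolved_severe:
                raw["unresolved_severe"] += k
            if b.surgery:
                raw["surgeries"] += k
            raw["deaths"] += deaths
        raw["severe_survivors"] = raw["severe_cases"] - raw["severe_deaths"]
        raw["anemia_cases"] = raw["severe_survivors"] * constants.anemia_fraction

        scaled = {f: raw[f] * scale for f in FLOW_FIELDS}
        ses = {}
        for f in FLOW_FIELDS:
            if n == 0:
                ses[f] = 0.0
                continue
            # anemia is a deterministic fraction of severe survivors
            eff = raw["severe_survivors"] if f == "anemia_cases" else raw[f]
            p_hat = min(max(eff / n, 0.0), 1.0)
            se = scale * np.sqrt(n * p_hat * (1.0 - p_hat))
            ses[f] = se * constants.anemia_fraction if f == "anemia_cases" else se
        counts_rows[s] = scaled
        se_rows[s] = ses

    per_setting = pd.DataFrame.from_dict(counts_rows, orient="index").loc[
        list(SETTINGS), list(FLOW_FIELDS)
    ]
    per_setting.index.name = "setting"
    se_frame = pd.DataFrame.from_dict(se_rows, orient="index").loc[
        list(SETTINGS), list(FLOW_FIELDS)
    ]
    se_frame.index.name = "setting"
    return MicrosimResult(
        per_setting=per_setting,
        se_per_setting=se_frame,
        branches=branches,
        n_individuals=n,
        seed=seed,
    )
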