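"""Deterministic cohort arithmetic for the PPH treatment cascade.

The cascade is a fixed-order decision tree applied to every delivery:

1. delivery setting (home / clinic / hospital) and PPH onset;
2. cause attribution (atonic uterus vs. other causes);
3. first-line uterotonic drugs (per-setting coverage × efficacy);
4. severity at second line: a fraction of uterotonic failures are already
   past the 1000 mL threshold ("pre-severe"), the rest are nonsevere;
5. uterine balloon tamponade (UBT), gated by penetration × utilization and
   by the scenario's population filter;
6. severity dynamics: uncontrolled nonsevere bleeding progresses past the
   threshold with ``progression_prob``; bleeding initially controlled by the
   balloon may still cross it with ``rebleed_prob``, in which case the
   in-place device is used at severe-stratum efficacy (where severe-stratum
   use is permitted);
7. last-resort surgery for every unresolved case, at per-setting access;
8. case fatality: unresolved severe cases face the no-surgery or surgical
   case-fatality rate; every other pathway faces the small background rate.

The whole tree is materialised once as a table of terminal branches
(:func:`branch_table`).  The cohort model propagates expected case mass down
that table; the individual-level oracle in :mod:`ubt_impact.synthetic` draws
each delivery through the *same* table, so the two cannot drift apart
structurally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .params import (
    SETTINGS,
    UTEROTONIC_COVERAGE,
    Constants,
    HiddenParams,
    InterventionSpec,
    ModelConfig,
    RegionInputs,
    ValidationError,
    _check_setting_map,
)

#: Flow-accounting columns, in deterministic output order.
FLOW_FIELDS = (
    "births",
    "pph_cases",
    "nonatonic_cases",
    "atonic_cases",
    "resolved_by_uterotonic",
    "resolved_by_ubt_nonsevere",
    "resolved_by_ubt_severe",
    "presevere_cases",
    "progressed_to_severe",
    "severe_cases",
    "persistent_nonsevere",
    "unresolved_severe",
    "surgeries",
    "deaths",
    "severe_deaths",
    "severe_survivors",
    "anemia_cases",
)

#: Severity stratum each flow field reports on (for the tidy CSV layout).
FIELD_SEVERITY = {
    "births": "all",
    "pph_cases": "all",
    "nonatonic_cases": "all",
    "atonic_cases": "all",
    "resolved_by_uterotonic": "all",
    "resolved_by_ubt_nonsevere": "nonsevere",
    "resolved_by_ubt_severe": "severe",
    "presevere_cases": "severe",
    "progressed_to_severe": "severe",
    "severe_cases": "severe",
    "persistent_nonsevere": "nonsevere",
    "unresolved_severe": "severe",
    "surgeries": "all",
    "deaths": "all",
    "severe_deaths": "severe",
    "severe_survivors": "severe",
    "anemia_cases": "severe",
}


@dataclass(frozen=True)
class Branch:
    """One terminal path through the event tree, conditional on a delivery."""

    setting: str
    label: str
    prob: float  # probability of this path given a delivery in `setting`
    pph: bool
    atonic: bool
    severe: bool  # crossed the 1000 mL threshold at any point
    progressed: bool  # crossed the threshold after second line began
    resolved_by: str  # "", "uterotonic", "ubt_nonsevere", "ubt_severe"
    unresolved_severe: bool
    persistent_nonsevere: bool
    surgery: bool
    death_prob: float


def _nonatonic_death_rate(region: RegionInputs, hidden: HiddenParams) -> float:
    """Convert the additive non-atonic death load to a per-case rate."""
    nonatonic_cases = sum(
        region.live_births
        * region.setting_shares[s]
        * region.pph_rate[s]
        * (1.0 - region.atonic_fraction)
        for s in SETTINGS
    )
    if nonatonic_cases <= 0.0:
        if hidden.nonatonic_death_load > 0.0:
            raise ValidationError(
                "nonatonic_death_load > 0 but the cohort has no non-atonic PPH cases"
            )
        return 0.0
    rate = hidden.nonatonic_death_load / nonatonic_cases
    if rate > 1.0:
        raise ValidationError(
            f"nonatonic_death_load {hidden.nonatonic_death_load} exceeds the "
            f"{nonatonic_cases:.1f} non-atonic PPH cases in the cohort"
        )
    return rate


def branch_table(
    region: RegionInputs,
    ubt: InterventionSpec | None,
    hidden: HiddenParams,
    constants: Constants,
    population_filter: str = "all",
    uterotonic_coverage: Mapping[str, float] | None = None,
) -> list[Branch]:
    """Enumerate every terminal branch of the cascade, per setting.

    ``ubt=None`` is the no-intervention baseline.  Under the
    ``nonsevere_only`` filter the device is withheld from the severe stratum:
    severe-stratum efficacy is forced to zero while the nonsevere pathway is
    unchanged.  Branch probabilities within a setting sum to 1.
    """
    if population_filter not in ("all", "nonsevere_only"):
        raise ValidationError(
            f"population_filter must be 'all' or 'nonsevere_only', "
            f"got {population_filter!r}"
        )
    if uterotonic_coverage is None:
        uterotonic_coverage = UTEROTONIC_COVERAGE
    cov_ut = _check_setting_map("uterotonic_coverage", uterotonic_coverage)

    e_ns = ubt.efficacy_nonsevere if ubt is not None else 0.0
    e_sv = ubt.efficacy_severe if ubt is not None else 0.0
    if population_filter == "nonsevere_only":
        e_sv = 0.0

    pi = hidden.presevere_fraction
    p = hidden.progression_prob
    q = hidden.rebleed_prob
    eu = hidden.uterotonic_efficacy
    cfr_ns = hidden.cfr_nonsevere_resolved
    cfr_op = hidden.cfr_severe_surgery
    cfr_noop = hidden.cfr_severe_no_surgery
    nonatonic_rate = _nonatonic_death_rate(region, hidden)

    branches: list[Branch] = []

    for s in SETTINGS:
        r = region.pph_rate[s]
        a = region.atonic_fraction
        cu = cov_ut[s]
        c = ubt.coverage(s) if ubt is not None else 0.0
        sa = hidden.surgery_access[s]

        def emit(label: str, prob: float, **kw) -> None:
            fields = dict(
                pph=True,
                atonic=True,
                severe=False,
                progressed=False,
                resolved_by="",
                unresolved_severe=False,
                persistent_nonsevere=False,
                surgery=False,
                death_prob=cfr_ns,
            )
            fields.update(kw)
            branches.append(Branch(setting=s, label=label, prob=prob, **fields))

        def emit_unresolved_severe(label: str, prob: float, progressed: bool) -> None:
            emit(
                f"{label}/surgery",
                prob * sa,
                severe=True,
                progressed=progressed,
                unresolved_severe=True,
                surgery=True,
                death_prob=cfr_op,
            )
            emit(
                f"{label}/no_surgery",
                prob * (1.0 - sa),
                severe=True,
                progressed=progressed,
                unresolved_severe=True,
                death_prob=cfr_noop,
            )

        def emit_persistent_nonsevere(label: str, prob: float) -> None:
            # Persistent (uncontrolled but sub-threshold) bleeding is also
            # referred for last-resort care; fatality stays at the background
            # nonsevere rate.
            emit(f"{label}/surgery", prob * sa, persistent_nonsevere=True, surgery=True)
            emit(f"{label}/no_surgery", prob * (1.0 - sa), persistent_nonsevere=True)

        emit("no_pph", 1.0 - r, pph=False, atonic=False, death_prob=0.0)
        emit("pph/nonatonic", r * (1.0 - a), atonic=False, death_prob=nonatonic_rate)

        atone = r * a  # probability of atonic PPH given a delivery

        # -- first line: uterotonic drugs ---------------------------------
        emit("atonic/uterotonic_resolved", atone * cu * eu, resolved_by="uterotonic")
        fail = atone * (1.0 - cu * eu)

        # -- severity split at second line --------------------------------
        presevere = fail * pi
        nonsevere = fail * (1.0 - pi)

        # pre-severe stratum: balloon at severe-stratum efficacy
        emit(
            "presevere/ubt_resolved",
            presevere * c * e_sv,
            severe=True,
            resolved_by="ubt_severe",
        )
        emit_unresolved_severe(
            "presevere/unresolved", presevere * (1.0 - c * e_sv), progressed=False
        )

        # nonsevere stratum, balloon available and used
        cov = nonsevere * c
        emit(
            "nonsevere/ubt_controlled/stable",
            cov * e_ns * (1.0 - q),
            resolved_by="ubt_nonsevere",
        )
        emit(
            "nonsevere/ubt_controlled/rebleed/ubt_resolved",
            cov * e_ns * q * e_sv,
            severe=True,
            progressed=True,
            resolved_by="ubt_severe",
        )
        emit_unresolved_severe(
            "nonsevere/ubt_controlled/rebleed/unresolved",
            cov * e_ns * q * (1.0 - e_sv),
            progressed=True,
        )
        emit_unresolved_severe(
            "nonsevere/ubt_failed/progressed", cov * (1.0 - e_ns) * p, progressed=True
        )
        emit_persistent_nonsevere(
            "nonsevere/ubt_failed/persistent", cov * (1.0 - e_ns) * (1.0 - p)
        )

        # nonsevere stratum, no balloon available
        unc = nonsevere * (1.0 - c)
        emit_unresolved_severe("nonsevere/no_ubt/progressed", unc * p, progressed=True)
        emit_persistent_nonsevere("nonsevere/no_ubt/persistent", unc * (1.0 - p))

    return branches


def branches_to_frame(branches: list[Branch]) -> pd.DataFrame:
    """Branch table as a DataFrame (one row per terminal branch)."""
    return pd.DataFrame([b.__dict__ for b in branches])


# ---------------------------------------------------------------------------
# Cohort allocation and cascade results
# ---------------------------------------------------------------------------

def allocate_cohort(region: RegionInputs) -> dict[str, dict[str, float]]:
    """Split the annual birth cohort into settings and PPH/atonic case counts.

    Counts are real-valued: the cohort model tracks expected case mass, not
    integer people.
    """
    out: dict[str, dict[str, float]] = {}
    for s in SETTINGS:
        births = region.live_births * region.setting_shares[s]
        pph = births * region.pph_rate[s]
        out[s] = {
            "births": births,
            "pph_cases": pph,
            "atonic_cases": pph * region.atonic_fraction,
        }
    return out


def _aggregate(branches: list[Branch], births_by_setting: Mapping[str, float],
               anemia_fraction: float) -> pd.DataFrame:
    rows = {}
    for s in SETTINGS:
        births = births_by_setting[s]
        acc = {f: 0.0 for f in FLOW_FIELDS}
        acc["births"] = births
        for b in branches:
            if b.setting != s:
                continue
            mass = births * b.prob
            deaths = mass * b.death_prob
            if b.pph:
                acc["pph_cases"] += mass
            if b.pph and not b.atonic:
                acc["nonatonic_cases"] += mass
            if b.atonic:
                acc["atonic_cases"] += mass
            if b.resolved_by == "uterotonic":
                acc["resolved_by_uterotonic"] += mass
            elif b.resolved_by == "ubt_nonsevere":
                acc["resolved_by_ubt_nonsevere"] += mass
            elif b.resolved_by == "ubt_severe":
                acc["resolved_by_ubt_severe"] += mass
            if b.severe and not b.progressed:
                acc["presevere_cases"] += mass
            if b.progressed:
                acc["progressed_to_severe"] += mass
            if b.severe:
                acc["severe_cases"] += mass
                acc["severe_deaths"] += deaths
            if b.persistent_nonsevere:
                acc["persistent_nonsevere"] += mass
            if b.unresolved_severe:
                acc["unresolved_severe"] += mass
            if b.surgery:
                acc["surgeries"] += mass
            acc["deaths"] += deaths
        acc["severe_survivors"] = acc["severe_cases"] - acc["severe_deaths"]
        acc["anemia_cases"] = acc["severe_survivors"] * anemia_fraction
        rows[s] = acc
    frame = pd.DataFrame.from_dict(rows, orient="index").loc[list(SETTINGS), list(FLOW_FIELDS)]
    frame.index.name = "setting"
    return frame


@dataclass(frozen=True)
class CascadeResult:
    """Flow accounting for one cascade run (per setting, plus totals)."""

    per_setting: pd.DataFrame
    branches: list[Branch]
    region: RegionInputs
    population_filter: str
    scenario_name: str = ""

    @property
    def totals(self) -> pd.Series:
        return self.per_setting.sum(axis=0)

    def total(self, field: str) -> float:
        return float(self.per_setting[field].sum())

    def to_tidy_frame(self) -> pd.DataFrame:
        """Long-form table: one row per (setting, severity, flow field)."""
        records = []
        for setting, row in self.per_setting.iterrows():
            for f in FLOW_FIELDS:
                records.append(
                    {
                        "setting": setting,
                        "severity": FIELD_SEVERITY[f],
                        "field": f,
                        "value": row[f],
                    }
                )
        totals = self.totals
        for f in FLOW_FIELDS:
            records.append(
                {
                    "setting": "total",
                    "severity": FIELD_SEVERITY[f],
                    "field": f,
                    "value": totals[f],
                }
            )
        return pd.DataFrame.from_records(
            records, columns=["setting", "severity", "field", "value"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_tidy_frame().to_csv(path, index=False)

    def conservation_errors(self) -> pd.Series:
        """Largest flow-conservation violations per setting.

        Checks, per setting: branch probabilities sum to 1; atonic inflow
        equals the sum of the terminal states (resolved by each route,
        unresolved severe, persistent nonsevere); and the spec-level identity
        cases = resolved + deaths + surviving-unresolved, which follows from
        the terminal-state split because every terminal mass divides into
        deaths and survivors.
        """
        errs = {}
        for s in SETTINGS:
            psum = sum(b.prob for b in self.branches if b.setting == s)
            row = self.per_setting.loc[s]
            terminal = (
                row["resolved_by_uterotonic"]
                + row["resolved_by_ubt_nonsevere"]
                + row["resolved_by_ubt_severe"]
                + row["unresolved_severe"]
                + row["persistent_nonsevere"]
            )
            scale = max(row["atonic_cases"], 1.0)
            errs[s] = max(
                abs(psum - 1.0), abs(terminal - row["atonic_cases"]) / scale
            )
        return pd.Series(errs)


def run_cascade(
    region: RegionInputs,
    ubt: InterventionSpec | None,
    hidden: HiddenParams,
    constants: Constants,
    population_filter: str = "all",
    uterotonic_coverage: Mapping[str, float] | None = None,
    scenario_name: str = "",
) -> CascadeResult:
    """Propagate the birth cohort through the cascade (expected-value arithmetic)."""
    branches = branch_table(
        region, ubt, hidden, constants, population_filter, uterotonic_coverage
    )
    births = {s: region.live_births * region.setting_shares[s] for s in SETTINGS}
    frame = _aggregate(branches, births, constants.anemia_fraction)
    return CascadeResult(
        per_setting=frame,
        branches=branches,
        region=region,
        population_filter=population_filter,
        scenario_name=scenario_name,
    )


def run_config(config: ModelConfig, baseline: bool = False,
               hidden: HiddenParams | None = None) -> CascadeResult:
    """Run a full scenario configuration (or its no-UBT baseline)."""
    return run_cascade(
        config.region,
        None if baseline else config.effective_ubt(),
        hidden if hidden is not None else config.hidden,
        config.constants,
        "all" if baseline else config.scenario.population_filter,
        config.uterotonic_coverage,
        scenario_name="baseline" if baseline else config.scenario.name,
    )


def anemia_from_severe(severe_count: float, constants: Constants) -> float:
    """Severe-anemia cases among `severe_count` severe-hemorrhage sufferers.

    Returns the unrounded product; rounding is a reporting concern.
    """
    if severe_count < 0:
        raise ValidationError(f"severe_count must be >= 0, got {severe_count}")
    return severe_count * constants.anemia_fraction
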