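"""Formatting and CSV output helpers.

All tabular output is plain CSV (comma separator, dot decimal, header row)
so reruns diff bit-exactly.  Headline counts are rounded to the nearest
integer only at this layer; scenario deltas are additionally reported to the
nearest hundred, matching the precision of the published figures.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .params import ModelConfig
from .scenarios import ImpactSummary


def round_count(x: float) -> int:
    """Nearest integer, half away from zero (reporting convention for counts)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def round_hundred(x: float) -> int:
    return round_count(x / 100.0) * 100


def config_digest(config: ModelConfig) -> str:
    """Stable digest of a configuration (for log lines and provenance)."""
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:12]


def impact_to_frame(name: str, impact: ImpactSummary) -> pd.DataFrame:
    row = {"scenario": name}
    row.update(impact.to_dict())
    rounded = {
        f"{k}_rounded": round_count(v) for k, v in impact.to_dict().items() if k != "pct_mortality_reduction"
    }
    row.update(rounded)
    row["pct_mortality_reduction_rounded"] = round_count(impact.pct_mortality_reduction)
    return pd.DataFrame([row])


def scenario_table_text(table: pd.DataFrame) -> str:
    """Plain-text block mirroring the four-scenario summary figure."""
    lines = ["Estimated impact of the uterine balloon tamponade, by scenario", ""]
    header = f"{'scenario':<20}{'lives saved':>14}{'% mortality':>13}{'surgeries':>12}{'severe':>10}{'anemia':>9}"
    lines.append(header)
    lines.append("-" * len(header))
    for name, row in table.iterrows():
        lines.append(
            f"{name:<20}"
            f"{round_count(row['lives_saved']):>14d}"
            f"{row['pct_mortality_reduction']:>12.1f}%"
            f"{round_count(row['surgeries_averted']):>12d}"
            f"{round_count(row['severe_cases_averted']):>10d}"
            f"{round_count(row['anemia_cases_averted']):>9d}"
        )
    return "\n".join(lines) + "\n"


def write_csv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=index)


def residuals_frame(residuals: Mapping[str, float], model_values: Mapping[str, float],
                    observed: Mapping[str, float]) -> pd.DataFrame:
    rows = []
    for name in residuals:
        rows.append(
            {
                "target": name,
                "observed": observed[name],
                "model": model_values[name],
                "residual": residuals[name],
            }
        )
    return pd.DataFrame(rows, columns=["target", "observed", "model", "residual"])
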