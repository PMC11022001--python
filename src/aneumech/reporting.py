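"""Study tables and printed-value reproduction checks.

Embeds the published study tables (luminal volumes, identified wall
constants, stress-state summaries for subjects S1 and S2 under stimulus
flows D1/D2/D3) as input fixtures, recomputes every derived column from
its sources, and emits the provisional stress/pressure criterion ratio.

Rounding conventions used throughout: volume changes to 2 decimals (mm^3),
volume-change percentages to 1 decimal, stiffness decreases to the nearest
integer percent, relative errors e to 2 decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "CONDITIONS",
    "LUMINAL_VOLUMES",
    "PRINTED_DELTA_V",
    "IDENTIFIED_CONSTANTS",
    "PRINTED_RELATIVE_ERRORS",
    "STRESS_STATE",
    "PRINTED_SUMMARY",
    "CheckItem",
    "reproduce_printed_values",
    "criterion_ratio",
    "build_study_table",
    "write_study_table",
    "read_study_table",
]

CONDITIONS = ("C2-D1", "C2-D2", "C2-D3")  # stimulated states at 150/170/190 ml/min

#: published luminal volumes (mm^3) per subject and acquisition state
LUMINAL_VOLUMES = {
    "S1": {"C1": 12.98, "C2-D1": 13.10, "C2-D2": 13.86, "C2-D3": 13.57},
    "S2": {"C1": 9.81, "C2-D1": 10.64, "C2-D2": 10.38, "C2-D3": 10.84},
}

#: published volume changes dV_exp (mm^3) per stimulated state
PRINTED_DELTA_V = {
    "S1": {"C2-D1": 0.12, "C2-D2": 0.88, "C2-D3": 0.59},
    "S2": {"C2-D1": 0.83, "C2-D2": 0.57, "C2-D3": 1.03},
}

#: published identified wall constants per flow rate
IDENTIFIED_CONSTANTS = {
    "S1": {"C2-D1": (316.92, 16.21), "C2-D2": (311.26, 16.13), "C2-D3": (232.07, 16.37)},
    "S2": {"C2-D1": (260.35, 16.87), "C2-D2": (283.98, 16.13), "C2-D3": (209.44, 16.82)},
}

#: published relative errors e (%) between dV_num/mat and dV_exp
PRINTED_RELATIVE_ERRORS = {
    "S1": {"C2-D1": 4.33, "C2-D2": 3.41, "C2-D3": 3.86},
    "S2": {"C2-D1": 8.84, "C2-D2": 8.98, "C2-D3": 7.78},
}

#: published stress-state summary at the systole peak: mean wall pressure
#: (kPa), its C1->C2 variation (%), mean first principal Cauchy stress
#: (kPa) and its variation (%)
STRESS_STATE = {
    "S1": {
        "C2-D1": {"P": 14.2, "dP_pct": 3.17, "sigma1": 88.2, "dsigma1_pct": 2.55},
        "C2-D2": {"P": 14.3, "dP_pct": 4.12, "sigma1": 88.9, "dsigma1_pct": 3.35},
        "C2-D3": {"P": 14.5, "dP_pct": 5.0, "sigma1": 92.5, "dsigma1_pct": 4.45},
    },
    "S2": {
        "C2-D1": {"P": 14.8, "dP_pct": 7.09, "sigma1": 64.0, "dsigma1_pct": 6.08},
        "C2-D2": {"P": 15.1, "dP_pct": 9.38, "sigma1": 64.4, "dsigma1_pct": 8.07},
        "C2-D3": {"P": 15.4, "dP_pct": 11.35, "sigma1": 69.1, "dsigma1_pct": 10.59},
    },
}

#: published headline numbers recomputed by reproduce_printed_values
PRINTED_SUMMARY = {
    "dv_min_mm3": 0.12,  # S1, C2-D1
    "dv_max_mm3": 1.03,  # S2, C2-D3
    "dv_min_pct": 0.92,
    "dv_max_pct": 10.5,
    "a_decrease_d2_d3_s1_pct": 25.0,
    "a_decrease_d2_d3_s2_pct": 26.0,
}


@dataclass(frozen=True)
class CheckItem:
    name: str
    computed: float
    printed: float
    passed: bool


def _delta_v(subject: str, condition: str) -> float:
    vols = LUMINAL_VOLUMES[subject]
    return vols[condition] - vols["C1"]


def _delta_v_pct(subject: str, condition: str) -> float:
    vols = LUMINAL_VOLUMES[subject]
    return (vols[condition] - vols["C1"]) / vols["C1"] * 100.0


def _a_decrease_pct(subject: str) -> float:
    a_d2 = IDENTIFIED_CONSTANTS[subject]["C2-D2"][0]
    a_d3 = IDENTIFIED_CONSTANTS[subject]["C2-D3"][0]
    return (a_d2 - a_d3) / a_d2 * 100.0


def reproduce_printed_values() -> list[CheckItem]:
    """Recompute the published derived quantities from their source columns.

    Volume changes per condition (2 d.p.), the headline minimum/maximum
    change and its percentage (1 d.p.), and the stiffness decrease from D2
    to D3 (nearest integer percent), each compared to the printed value.
    """
    checks: list[CheckItem] = []

    def add(name, computed, printed, ndigits):
        checks.append(CheckItem(name, computed, printed, round(computed, ndigits) == round(printed, ndigits)))

    for subject in ("S1", "S2"):
        for cond in CONDITIONS:
            add(f"dv_exp_{subject}_{cond}_mm3", _delta_v(subject, cond), PRINTED_DELTA_V[subject][cond], 2)
    add("dv_min_mm3", _delta_v("S1", "C2-D1"), PRINTED_SUMMARY["dv_min_mm3"], 2)
    add("dv_max_mm3", _delta_v("S2", "C2-D3"), PRINTED_SUMMARY["dv_max_mm3"], 2)
    add("dv_min_pct", _delta_v_pct("S1", "C2-D1"), PRINTED_SUMMARY["dv_min_pct"], 1)
    add("dv_max_pct", _delta_v_pct("S2", "C2-D3"), PRINTED_SUMMARY["dv_max_pct"], 1)
    add("a_decrease_d2_d3_s1_pct", _a_decrease_pct("S1"), PRINTED_SUMMARY["a_decrease_d2_d3_s1_pct"], 0)
    add("a_decrease_d2_d3_s2_pct", _a_decrease_pct("S2"), PRINTED_SUMMARY["a_decrease_d2_d3_s2_pct"], 0)
    return checks


def criterion_ratio(sigma1_mean: float, pressure_mean: float) -> float:
    """Provisional rupture-criterion ratio <sigma1>/<P> for one condition.

    The eventual criterion is expected to combine all stress components;
    this is the simplest instance and is flagged as provisional in output.
    """
    if pressure_mean == 0:
        raise ValidationError("criterion ratio undefined for zero mean pressure")
    return sigma1_mean / pressure_mean


def build_study_table(
    subject: str,
    volumes: dict[str, float],
    constants: dict[str, tuple[float, float]] | None = None,
    errors: dict[str, float] | None = None,
    stress: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Assemble a per-subject study table with derived columns recomputed.

    ``volumes`` maps acquisition state (C1, C2-D1, ...) to luminal volume
    in mm^3; optional identified constants, relative errors and
    stress-state summaries fill the remaining columns.
    """
    if "C1" not in volumes or volumes["C1"] <= 0:
        raise ValidationError("study table needs a positive C1 volume")
    rows = []
    v1 = volumes["C1"]
    for cond in [c for c in CONDITIONS if c in volumes]:
        v2 = volumes[cond]
        row = {
            "subject": subject,
            "condition": cond,
            "v_c1_mm3": v1,
            "v_c2_mm3": v2,
            "delta_v_mm3": v2 - v1,
            "delta_v_pct": (v2 - v1) / v1 * 100.0,
        }
        if constants and cond in constants:
            row["a_kpa"], row["b"] = constants[cond]
        if errors and cond in errors:
            row["e_pct"] = errors[cond]
        if stress and cond in stress:
            s = stress[cond]
            row.update(
                {
                    "mean_p_kpa": s["P"],
                    "delta_p_pct": s["dP_pct"],
                    "mean_sigma1_kpa": s["sigma1"],
                    "delta_sigma1_pct": s["dsigma1_pct"],
                    "criterion_ratio_provisional": criterion_ratio(s["sigma1"], s["P"]),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_study_table(table: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(table.to_dict(orient="records"), indent=1))
    else:
        table.to_csv(path, index=False)


def read_study_table(path) -> pd.DataFrame:
    """Read a study table and verify derived-column self-consistency."""
    path = Path(path)
    if path.suffix == ".json":
        table = pd.DataFrame(json.loads(path.read_text()))
    else:
        table = pd.read_csv(path)
    dv = table["v_c2_mm3"] - table["v_c1_mm3"]
    pct = dv / table["v_c1_mm3"] * 100.0
    if not ((table["delta_v_mm3"] - dv).abs().max() < 1e-9 and (table["delta_v_pct"] - pct).abs().max() < 1e-9):
        raise ValidationError("study table derived columns inconsistent with source columns")
    return table
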