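"""Table rendering and distribution export.

Renders the study's two summary tables — means and dispersion/ranges of
model results per sample definition — and exports long-format pretest
distributions (with skewness annotations) for raincloud/density plotting
in external tools.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .eligibility import EligibilityCriterion, sample_skewness
from .estimation import FULL_SAMPLE
from .montecarlo import StudySummary


def _round(x: float, places: int) -> float:
    # round-half-to-even, the convention behind the printed tables
    return float(np.round(x, places))


def render_summary_tables(
    summary: StudySummary, precision: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Format a study summary as (means table, dispersion/ranges table).

    Columns are ordered full sample first, then the criteria in their
    configured order.  Estimates and R² round half-to-even at
    ``precision`` decimals; percent bias rounds to whole percent.  Returns
    string-valued DataFrames ready for CSV or console output.
    """
    required = {
        "estimate_mean", "se_mean", "pct_bias_mean", "r2_mean",
        "estimate_min", "estimate_max", "estimate_sd",
        "pct_bias_min", "pct_bias_max", "pct_bias_sd",
        "r2_min", "r2_max", "r2_sd",
    }
    missing = required - set(summary.table.columns)
    if missing:
        raise KeyError(f"summary missing columns: {sorted(missing)}")

    p = precision
    means = {}
    disp = {}
    for name in summary.sample_names:
        row = summary.table.loc[name]
        is_full = name == FULL_SAMPLE
        means[name] = {
            "Intervention (SE)": f"{_round(row.estimate_mean, p):.{p}f} "
                                 f"({_round(row.se_mean, p):.{p}f})",
            "% Bias": "-" if is_full else f"{_round(row.pct_bias_mean, 0):.0f}%",
            "r-squared": f"{_round(row.r2_mean, p):.{p}f}",
        }
        disp[name] = {
            "Intervention (SD)": f"{_round(row.estimate_min, p):.{p}f}–"
                                 f"{_round(row.estimate_max, p):.{p}f} "
                                 f"({_round(row.estimate_sd, p):.{p}f})",
            "% Bias (SD)": "-" if is_full else
                           f"{_round(row.pct_bias_min, 0):.0f}% – "
                           f"{_round(row.pct_bias_max, 0):.0f}% "
                           f"({_round(row.pct_bias_sd, 0):.0f}%)",
            "r-squared": f"{_round(row.r2_min, p):.{p}f}–"
                         f"{_round(row.r2_max, p):.{p}f} "
                         f"({_round(row.r2_sd, p):.{p}f})",
        }
    order = summary.sample_names
    means_df = pd.DataFrame(means)[order]
    disp_df = pd.DataFrame(disp)[order]
    return means_df, disp_df


def export_distributions(
    table: pd.DataFrame, criteria: Sequence[EligibilityCriterion]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Long-format (sample_name, student_id, pretest) records plus skewness.

    The full sample contributes every student; each criterion contributes
    its flagged students only.  The companion dict maps sample name to the
    moment-based skewness of its pretest scores.  Rendering never mutates
    the input table.
    """
    records = [
        pd.DataFrame(
            {
                "sample_name": FULL_SAMPLE,
                "student_id": table["student_id"],
                "pretest": table["pretest"],
            }
        )
    ]
    skew = {FULL_SAMPLE: sample_skewness(table["pretest"])}
    for crit in criteria:
        if crit.flag_column not in table.columns:
            raise KeyError(
                f"criterion {crit.name!r} has no flag column in the table; "
                f"apply_criteria first"
            )
        sub = table[table[crit.flag_column]]
        records.append(
            pd.DataFrame(
                {
                    "sample_name": crit.name,
                    "student_id": sub["student_id"],
                    "pretest": sub["pretest"],
                }
            )
        )
        skew[crit.name] = sample_skewness(sub["pretest"])
    return pd.concat(records, ignore_index=True), skew
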