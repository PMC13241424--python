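"""Eligibility criteria: selection rules applied to screening (pretest) scores.

Three criteria recur in the Tier 2 reading-intervention literature and are
the study's defaults:

* **Method 1** — students at or below the 40th percentile of pretest
  (emulates failing a population-based screener; ~2000 of 5000 eligible);
* **Method 2** — students at or below the 25th percentile (~1250 eligible);
* **Method 3** — the lowest-scoring 4 students per classroom (exactly
  1000 eligible with 250 classrooms).

Selection depends only on pretest (and classroom membership for Method 3),
never on condition or posttest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PERCENTILE = "percentile_at_or_below"
LOWEST_K = "lowest_k_per_classroom"


@dataclass(frozen=True)
class EligibilityCriterion:
    """A named selection rule.

    ``method`` is either ``percentile_at_or_below`` (set ``percentile``,
    optionally ``basis``) or ``lowest_k_per_classroom`` (set ``k``).
    ``basis`` chooses where the percentile cutoff comes from: the screened
    sample's empirical quantile (``sample``, the default and what the study
    does) or the standard-normal quantile (``population``, a
    population-based screener).
    """

    name: str
    method: str
    percentile: float | None = None
    k: int | None = None
    basis: str = "sample"

    def __post_init__(self) -> None:
        if self.method == PERCENTILE:
            if self.percentile is None or self.k is not None:
                raise ValueError(
                    f"criterion {self.name!r}: percentile method takes "
                    f"exactly the 'percentile' parameter"
                )
            if not 0 < self.percentile < 100:
                raise ValueError(
                    f"criterion {self.name!r}: percentile must be in (0, 100)"
                )
            if self.basis not in ("sample", "population"):
                raise ValueError(
                    f"criterion {self.name!r}: basis must be 'sample' or "
                    f"'population'"
                )
        elif self.method == LOWEST_K:
            if self.k is None or self.percentile is not None:
                raise ValueError(
                    f"criterion {self.name!r}: lowest-k method takes "
                    f"exactly the 'k' parameter"
                )
            if self.k < 1:
                raise ValueError(f"criterion {self.name!r}: k must be >= 1")
        else:
            raise ValueError(f"unknown eligibility method {self.method!r}")

    @property
    def flag_column(self) -> str:
        return f"eligible_{self.name}"


def default_criteria() -> list[EligibilityCriterion]:
    """The three literature-derived criteria with their study parameters."""
    return [
        EligibilityCriterion("method_1", PERCENTILE, percentile=40),
        EligibilityCriterion("method_2", PERCENTILE, percentile=25),
        EligibilityCriterion("method_3", LOWEST_K, k=4),
    ]


def select_by_percentile(
    table: pd.DataFrame, p: float, basis: str = "sample"
) -> np.ndarray:
    """Flag students with pretest at or below the p-th percentile cutoff.

    With ``basis='sample'`` the cutoff is the p-th sample quantile of
    pretest, computed by linear interpolation between order statistics
    (numpy's default); with continuous data this flags exactly
    ``floor(p/100 * n)`` students.  With ``basis='population'`` the cutoff
    is the standard-normal p-th quantile.  "At or below" is inclusive.
    """
    if len(table) == 0:
        raise ValueError("cannot select from an empty table")
    pretest = table["pretest"].to_numpy()
    if basis == "sample":
        cutoff = np.quantile(pretest, p / 100.0)
    elif basis == "population":
        cutoff = stats.norm.ppf(p / 100.0)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return pretest <= cutoff


def select_lowest_k_per_classroom(table: pd.DataFrame, k: int) -> np.ndarray:
    """Flag the k lowest-pretest students within every classroom.

    Ties (measure-zero with continuous scores) break by ascending
    student_id.  Total flagged is always ``k * n_classrooms``.  Raises if
    any classroom has fewer than k students.
    """
    sizes = table.groupby("classroom_id").size()
    small = sizes[sizes < k]
    if len(small):
        raise ValueError(
            f"classroom(s) {list(small.index)} have fewer than k={k} students"
        )
    ranked = table.sort_values(["pretest", "student_id"], kind="mergesort")
    chosen = ranked.groupby("classroom_id", sort=False).head(k).index
    flags = pd.Series(False, index=table.index)
    flags.loc[chosen] = True
    return flags.to_numpy()


def apply_criteria(
    table: pd.DataFrame, criteria: Sequence[EligibilityCriterion]
) -> pd.DataFrame:
    """Append one boolean ``eligible_<name>`` column per criterion.

    Original rows and columns are preserved; duplicate criterion names are
    an error.
    """
    names = [c.name for c in criteria]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate criterion names in {names}")
    out = table.copy()
    for crit in criteria:
        if crit.method == PERCENTILE:
            flags = select_by_percentile(out, crit.percentile, crit.basis)
        else:
            flags = select_lowest_k_per_classroom(out, crit.k)
        out[crit.flag_column] = flags
    return out


def sample_skewness(values, adjusted: bool = False) -> float:
    """Moment-based skewness g1 = m3 / m2^(3/2).

    Central moments use population (1/n) denominators; pass
    ``adjusted=True`` for the bias-adjusted variant G1 with the
    sqrt(n(n-1))/(n-2) correction.  Requires at least 3 values and nonzero
    variance.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("skewness needs at least 3 values")
    if np.var(arr) == 0:
        raise ValueError("skewness undefined for zero-variance data")
    return float(stats.skew(arr, bias=not adjusted))
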