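"""Counterfactual decomposition of incidence-count change into population
growth, population aging, and age-specific rate change.

Two counterfactual expected counts attribute the change between a reference
year and a current year:

* scenario 1 (*growth only*): reference age-specific rates and reference age
  structure applied to the current total population,
  ``e_growth = (sum_a pop_cur(a)) * sum_a structure_ref(a) * rates_ref(a) / 1e5``;
* scenario 2 (*growth + aging*): reference rates applied to the current
  population size *and* structure,
  ``e_growth_aging = sum_a pop_cur(a) * rates_ref(a) / 1e5``.

Contributions are percents of the reference count ``n_ref``::

    pct_growth  = 100 * (e_growth       - n_ref)          / n_ref
    pct_aging   = 100 * (e_growth_aging - e_growth)       / n_ref
    pct_rates   = 100 * (n_cur          - e_growth_aging) / n_ref
    pct_overall = 100 * (n_cur          - n_ref)          / n_ref

The three contributions telescope, so additivity
``pct_growth + pct_aging + pct_rates == pct_overall`` holds identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError, InsufficientDataError

_STRUCTURE_ATOL = 1e-9

RESULT_COLUMNS = ["group", "sex", "n_ref", "n_cur", "e_growth", "e_growth_aging",
                  "pct_growth", "pct_aging", "pct_rates", "pct_overall"]


@dataclass(frozen=True)
class PopulationCell:
    location: str
    year: int
    sex: str
    age_group: str
    population: float


@dataclass(frozen=True)
class DecompositionResult:
    n_ref: float
    n_cur: float
    e_growth: float
    e_growth_aging: float
    pct_growth: float
    pct_aging: float
    pct_rates: float
    pct_overall: float


def expected_counts(rates_ref: Mapping[str, float],
                    structure_ref: Mapping[str, float],
                    pop_cur: Mapping[str, float]) -> tuple[float, float]:
    """Counterfactual expected counts under the two demographic scenarios.

    ``rates_ref`` are reference-year age-specific rates per 100,000,
    ``structure_ref`` the reference age distribution (sums to 1), and
    ``pop_cur`` current-year population counts by age.  All three must share
    the same age keys.
    """
    ages = set(rates_ref)
    if set(structure_ref) != ages or set(pop_cur) != ages:
        raise AlignmentError(
            f"age keys differ: rates {sorted(rates_ref)}, "
            f"structure {sorted(structure_ref)}, population {sorted(pop_cur)}"
        )
    total_structure = sum(structure_ref.values())
    if abs(total_structure - 1.0) > _STRUCTURE_ATOL:
        raise DomainError(
            f"reference age structure sums to {total_structure!r}, not 1"
        )
    total_pop = sum(pop_cur.values())
    e_growth = total_pop * sum(
        structure_ref[a] * rates_ref[a] / 1e5 for a in sorted(ages)
    )
    e_growth_aging = sum(pop_cur[a] * rates_ref[a] / 1e5 for a in sorted(ages))
    return e_growth, e_growth_aging


def decompose(n_ref: float, n_cur: float, e_growth: float,
              e_growth_aging: float) -> DecompositionResult:
    """Attribute the reference→current change to the three factors."""
    if n_ref <= 0:
        raise DomainError(f"reference count must be positive, got {n_ref!r}")
    return DecompositionResult(
        n_ref=n_ref, n_cur=n_cur, e_growth=e_growth, e_growth_aging=e_growth_aging,
        pct_growth=100.0 * (e_growth - n_ref) / n_ref,
        pct_aging=100.0 * (e_growth_aging - e_growth) / n_ref,
        pct_rates=100.0 * (n_cur - e_growth_aging) / n_ref,
        pct_overall=100.0 * (n_cur - n_ref) / n_ref,
    )


def additivity_error(result: DecompositionResult) -> float:
    """Relative residual of ``pct_growth + pct_aging + pct_rates - pct_overall``.

    The identity telescopes exactly in real arithmetic; in floating point the
    residual is measured relative to the largest-magnitude term (floored at
    1), the scale on which the additions actually lose precision.
    """
    total = result.pct_growth + result.pct_aging + result.pct_rates
    scale = max(1.0, abs(result.pct_overall), abs(result.pct_growth),
                abs(result.pct_aging), abs(result.pct_rates))
    return abs(total - result.pct_overall) / scale


def pct_change(v_ref: float, v_cur: float) -> float:
    """Plain percent change, ``100 * (v_cur - v_ref) / v_ref``."""
    if v_ref <= 0:
        raise DomainError(f"reference value must be positive, got {v_ref!r}")
    return 100.0 * (v_cur - v_ref) / v_ref


def _age_map(df: pd.DataFrame, value_col: str) -> dict[str, float]:
    g = df.groupby("age_group", sort=True, observed=True)[value_col].sum()
    return {str(a): float(v) for a, v in g.items()}


def decompose_panel(cells: pd.DataFrame, pops: pd.DataFrame,
                    ref_year: int, cur_year: int,
                    group_by: tuple[str, ...] = (),
                    by_sex: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the decomposition per group directly from a burden panel.

    Age-specific reference rates are derived as ``count / population * 1e5``
    from the panel's own incidence counts and the population table — never
    read as pre-rounded rate rows — so numerator and denominator are
    internally consistent.

    Parameters
    ----------
    cells
        Canonical burden-cell frame (count metric incidence rows are used).
    pops
        Population table with columns location/year/sex/age_group/population.
    group_by
        Grouping columns beyond sex, e.g. ``("location",)``; empty for a
        single global group.
    by_sex
        Decompose each sex separately as well as both sexes combined.

    Returns
    -------
    (results, exclusions)
        ``results``: one row per (group, sex) with the counts, counterfactual
        expectations and the four percents.  ``exclusions``: groups skipped
        for missing age bins, with reasons.
    """
    inc = cells[(cells["measure"] == "incidence") & (cells["metric"] == "count")
                & (~cells["age_group"].isin(["All Ages", "Age-standardized"]))]
    if inc.empty:
        raise InsufficientDataError("no age-specific incidence counts in input")

    sexes = (["both"] + sorted(inc["sex"].unique())) if by_sex else ["both"]
    sexes = [s for s in dict.fromkeys(sexes) if s == "both" or s in set(inc["sex"])]

    group_by = list(group_by)
    groups = ([tuple(v) for v in inc[group_by].drop_duplicates()
               .sort_values(group_by).to_numpy()] if group_by else [()])

    results, exclusions = [], []
    for gkey in groups:
        gmask_inc = pd.Series(True, index=inc.index)
        gmask_pop = pd.Series(True, index=pops.index)
        for col, val in zip(group_by, gkey):
            gmask_inc &= inc[col] == val
            gmask_pop &= pops[col] == val
        label = "/".join(map(str, gkey)) if gkey else "global"
        for sex in sexes:
            smask_inc = gmask_inc if sex == "both" else gmask_inc & (inc["sex"] == sex)
            smask_pop = gmask_pop if sex == "both" else gmask_pop & (pops["sex"] == sex)
            cnt_ref = _age_map(inc[smask_inc & (inc["year"] == ref_year)], "value")
            cnt_cur = _age_map(inc[smask_inc & (inc["year"] == cur_year)], "value")
            pop_ref = _age_map(pops[smask_pop & (pops["year"] == ref_year)], "population")
            pop_cur = _age_map(pops[smask_pop & (pops["year"] == cur_year)], "population")

            ages = set(cnt_ref) | set(cnt_cur) | set(pop_ref) | set(pop_cur)
            missing = [
                f"{which} missing bins {sorted(ages - set(m))}"
                for which, m in (("ref counts", cnt_ref), ("cur counts", cnt_cur),
                                 ("ref population", pop_ref),
                                 ("cur population", pop_cur))
                if ages - set(m)
            ]
            if missing:
                exclusions.append({"group": label, "sex": sex,
                                   "reason": "; ".join(missing)})
                continue
            total_ref_pop = sum(pop_ref.values())
            if total_ref_pop == 0 or sum(cnt_ref.values()) == 0:
                exclusions.append({"group": label, "sex": sex,
                                   "reason": "zero reference population or count"})
                continue
            rates_ref = {a: cnt_ref[a] / pop_ref[a] * 1e5 if pop_ref[a] > 0 else 0.0
                         for a in ages}
            structure_ref = {a: pop_ref[a] / total_ref_pop for a in ages}
            # tiny float drift in the normalized structure is ours, not the data's
            drift = sum(structure_ref.values())
            structure_ref = {a: v / drift for a, v in structure_ref.items()}
            e_growth, e_growth_aging = expected_counts(rates_ref, structure_ref,
                                                       pop_cur)
            res = decompose(sum(cnt_ref.values()), sum(cnt_cur.values()),
                            e_growth, e_growth_aging)
            results.append({"group": label, "sex": sex, **res.__dict__})

    if not results and exclusions:
        raise InsufficientDataError(
            f"no group computable; exclusions: {exclusions}"
        )
    results_df = pd.DataFrame(results, columns=RESULT_COLUMNS)
    exclusions_df = pd.DataFrame(exclusions, columns=["group", "sex", "reason"])
    return results_df, exclusions_df


def format_report(results: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Report-layer rounding: percents to ``decimals``, counts with
    thousands separators.  Analysis tables keep full precision; rounding
    happens only here."""
    out = results.copy()
    for c in ["n_ref", "n_cur", "e_growth", "e_growth_aging"]:
        out[c] = out[c].map(lambda v: f"{v:,.0f}")
    for c in ["pct_growth", "pct_aging", "pct_rates", "pct_overall"]:
        out[c] = out[c].map(lambda v: f"{v:.{decimals}f}%")
    return out
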