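"""Synthetic GBD-like burden panels with a known latent care-quality scalar.

Each location carries a latent quality ``q`` in (0, 1) that drives the
epidemiology the ratio indices are meant to detect:

* case fatality falls with quality: ``MIR = m_max - (m_max - m_min) * q``,
* survival (mean prevalent duration) rises: ``prev/inc = d_min + (d_max - d_min) * q``,
* the YLL:YLD balance tilts toward disability as deaths are averted.

Incidence follows an age profile that rises with age and ascends sharply
after 75, with a female:male multiplier (default 2.5, matching the 2-3x
female excess typical of thyroid cancer).  YLDs are prevalence times a
disability weight, YLLs are deaths times remaining life expectancy, and
DALY = YLL + YLD holds *exactly* in every generated stratum, noisy or not:
multiplicative lognormal noise is applied to the three primary quantities
(incidence, the case-fatality link, the duration link) and the year-lived
measures are derived afterwards.  Population pyramids are discretized
beta-shaped densities; the current year encodes a total-growth factor and
an aging tilt so the trend decomposition has real signal.

The generator emits the same cell dialect :mod:`careindex.io` reads, so the
whole pipeline runs end-to-end on generated files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .io import AGE_BINS, CELL_COLUMNS, DEFAULT_DIALECT, MEASURES


def _default_age_incidence() -> dict[str, float]:
    """Baseline age-specific incidence per 100,000: gentle rise to 74,
    sharp geometric ascent from 75 on."""
    rates = {}
    for i, bin_ in enumerate(AGE_BINS):
        rates[bin_] = 0.5 + 0.4 * i if i < 15 else (0.5 + 0.4 * 14) * 1.6 ** (i - 14)
    return rates


def _default_life_expectancy() -> dict[str, float]:
    """Remaining life expectancy at the bin midpoint (floor of 3 years)."""
    return {b: max(88.0 - (5 * i + 2.5), 3.0) for i, b in enumerate(AGE_BINS)}


@dataclass(frozen=True)
class SyntheticConfig:
    n_locations: int = 20
    years: tuple[int, ...] = (1990, 2017)
    age_bins: tuple[str, ...] = AGE_BINS
    female_incidence_multiplier: float = 2.5
    baseline_age_incidence: Mapping[str, float] = field(
        default_factory=_default_age_incidence)
    case_fatality_bounds: tuple[float, float] = (0.02, 0.5)
    mean_duration_bounds: tuple[float, float] = (2.0, 12.0)
    disability_weight: float = 0.06
    reference_life_expectancy: Mapping[str, float] = field(
        default_factory=_default_life_expectancy)
    noise_sd: float = 0.1
    pop_growth_factor: float = 1.6
    aging_shift: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_locations < 1:
            raise ConfigError("n_locations must be >= 1")
        if not self.years:
            raise ConfigError("years must be non-empty")
        if not self.age_bins:
            raise ConfigError("age_bins must be non-empty")
        m_min, m_max = self.case_fatality_bounds
        d_min, d_max = self.mean_duration_bounds
        if not (0 < m_min <= m_max < 1):
            raise ConfigError(f"case_fatality_bounds invalid: {m_min, m_max}")
        if not (0 < d_min <= d_max):
            raise ConfigError(f"mean_duration_bounds invalid: {d_min, d_max}")
        if not 0 < self.disability_weight < 1:
            raise ConfigError("disability_weight must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.pop_growth_factor <= 0:
            raise ConfigError("pop_growth_factor must be positive")
        missing = [b for b in self.age_bins if b not in self.baseline_age_incidence]
        if missing:
            raise ConfigError(f"baseline_age_incidence missing bins {missing}")
        if any(self.baseline_age_incidence[b] < 0 for b in self.age_bins):
            raise ConfigError("incidence rates must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Latent quality per location plus the noiseless per-stratum measures."""

    quality: dict[str, float]
    config: SyntheticConfig
    noiseless: pd.DataFrame  # panel-shaped: key columns + six measure counts


def _pyramid(n_bins: int, shift: float) -> np.ndarray:
    """Discretized beta-shaped age density; positive shift moves mass older."""
    a = max(1.8 + 2.0 * shift, 0.2)
    b = max(3.2 - 2.0 * shift, 0.2)
    x = (np.arange(n_bins) + 0.5) / n_bins
    dens = stats.beta.pdf(x, a, b)
    return dens / dens.sum()


def generate_panel(config: SyntheticConfig = SyntheticConfig()
                   ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (burden cells, population table, truth) for a config.

    Deterministic given ``config.seed``: identical configs yield
    byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_loc = config.n_locations
    ages = list(config.age_bins)
    years = sorted(config.years)
    sexes = ["female", "male"]
    y_ref, y_cur = years[0], years[-1]
    span = max(y_cur - y_ref, 1)

    locations = [f"Location {i + 1:03d}" for i in range(n_loc)]
    quality = rng.uniform(0.05, 0.95, n_loc)
    base_pop = rng.uniform(2e5, 2e6, n_loc)
    # one lognormal factor per (loc, year, sex, age) for each primary quantity
    eps = (rng.lognormal(0.0, config.noise_sd,
                         size=(3, n_loc, len(years), 2, len(ages)))
           if config.noise_sd > 0
           else np.ones((3, n_loc, len(years), 2, len(ages))))

    m_min, m_max = config.case_fatality_bounds
    d_min, d_max = config.mean_duration_bounds
    dw = config.disability_weight
    base_rate = np.array([config.baseline_age_incidence[a] for a in ages])
    life_exp = np.array([config.reference_life_expectancy.get(a, 3.0) for a in ages])

    cell_rows, pop_rows, clean_rows = [], [], []
    for li, loc in enumerate(locations):
        q = quality[li]
        mir_q = m_max - (m_max - m_min) * q
        dur_q = d_min + (d_max - d_min) * q
        for yi, year in enumerate(years):
            frac = (year - y_ref) / span
            growth = config.pop_growth_factor ** frac
            dens = _pyramid(len(ages), config.aging_shift * frac)
            for si, sex in enumerate(sexes):
                pop = base_pop[li] * growth * dens / 2.0
                mult = config.female_incidence_multiplier if sex == "female" else 1.0
                inc0 = pop * base_rate * mult / 1e5
                for noisy, e in ((True, eps[:, li, yi, si, :]),
                                 (False, np.ones((3, len(ages))))):
                    inc = inc0 * e[0]
                    deaths = inc * mir_q * e[1]
                    prev = inc * dur_q * e[2]
                    ylds = prev * dw
                    ylls = deaths * life_exp
                    dalys = ylls + ylds
                    vals = {"incidence": inc, "prevalence": prev, "deaths": deaths,
                            "dalys": dalys, "ylls": ylls, "ylds": ylds}
                    if noisy:
                        for m in MEASURES:
                            for ai, age in enumerate(ages):
                                cell_rows.append((loc, year, sex, age, m, "count",
                                                  vals[m][ai], np.nan, np.nan))
                    else:
                        for ai, age in enumerate(ages):
                            clean_rows.append((loc, year, sex, age,
                                               *(vals[m][ai] for m in MEASURES)))
                for ai, age in enumerate(ages):
                    pop_rows.append((loc, year, sex, age, pop[ai]))

    cells = pd.DataFrame(cell_rows, columns=CELL_COLUMNS)
    pops = pd.DataFrame(pop_rows, columns=["location", "year", "sex", "age_group",
                                           "population"])
    noiseless = pd.DataFrame(
        clean_rows,
        columns=["location", "year", "sex", "age_group", *MEASURES])
    truth = SyntheticTruth(
        quality=dict(zip(locations, quality.tolist())),
        config=config, noiseless=noiseless)
    return cells, pops, truth


def cells_to_gbd_dialect(cells: pd.DataFrame) -> pd.DataFrame:
    """Rename canonical cell columns to the GBD results-tool export dialect."""
    label = {"count": "Number", "rate_per_100k": "Rate"}
    out = pd.DataFrame({
        DEFAULT_DIALECT["measure"]: cells["measure"].str.capitalize()
        .replace({"Dalys": "DALYs", "Ylls": "YLLs", "Ylds": "YLDs"}),
        DEFAULT_DIALECT["location"]: cells["location"],
        DEFAULT_DIALECT["sex"]: cells["sex"].str.capitalize(),
        DEFAULT_DIALECT["age_group"]: cells["age_group"],
        DEFAULT_DIALECT["year"]: cells["year"],
        DEFAULT_DIALECT["metric"]: cells["metric"].map(label),
        DEFAULT_DIALECT["value"]: cells["value"],
        DEFAULT_DIALECT["upper"]: cells["upper"],
        DEFAULT_DIALECT["lower"]: cells["lower"],
    })
    return out


def generate_decomposition_case(
    rates_ref: Mapping[str, float],
    pop_ref: Mapping[str, float],
    pop_cur: Mapping[str, float],
    rates_cur: Mapping[str, float] | None = None,
) -> dict:
    """Build a decomposition input with its analytically known answer.

    ``rates_*`` are per 100,000; ``pop_*`` are age→count maps sharing keys.
    The reference age structure is ``pop_ref`` normalized.  ``rates_cur``
    defaults to ``rates_ref`` (zero rate contribution).  Returns a dict with
    the population tables, the four counts, and the expected contribution
    percents computed by direct arithmetic — usable as the frozen answer in
    recovery tests of the decomposition pipeline.
    """
    ages = sorted(pop_ref)
    if sorted(pop_cur) != ages or sorted(rates_ref) != ages:
        raise ConfigError("rates_ref, pop_ref and pop_cur must share age keys")
    rates_cur = dict(rates_cur) if rates_cur is not None else dict(rates_ref)
    total_ref = sum(pop_ref.values())
    total_cur = sum(pop_cur.values())
    if total_ref <= 0 or total_cur <= 0:
        raise ConfigError("populations must have positive totals")

    n_ref = sum(pop_ref[a] * rates_ref[a] / 1e5 for a in ages)
    n_cur = sum(pop_cur[a] * rates_cur[a] / 1e5 for a in ages)
    structure = {a: pop_ref[a] / total_ref for a in ages}
    e_growth = total_cur * sum(structure[a] * rates_ref[a] / 1e5 for a in ages)
    e_growth_aging = sum(pop_cur[a] * rates_ref[a] / 1e5 for a in ages)
    return {
        "ages": ages,
        "rates_ref": dict(rates_ref),
        "rates_cur": rates_cur,
        "pop_ref": dict(pop_ref),
        "pop_cur": dict(pop_cur),
        "structure_ref": structure,
        "n_ref": n_ref,
        "n_cur": n_cur,
        "e_growth": e_growth,
        "e_growth_aging": e_growth_aging,
        "pct_growth": 100.0 * (e_growth - n_ref) / n_ref,
        "pct_aging": 100.0 * (e_growth_aging - e_growth) / n_ref,
        "pct_rates": 100.0 * (n_cur - e_growth_aging) / n_ref,
        "pct_overall": 100.0 * (n_cur - n_ref) / n_ref,
    }


def decomposition_case_tables(case: dict, location: str = "Case",
                              sex: str = "both", ref_year: int = 1990,
                              cur_year: int = 2017
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Materialise a :func:`generate_decomposition_case` dict as the
    (cells, pops) tables :func:`careindex.decomposition.decompose_panel`
    consumes."""
    cell_rows, pop_rows = [], []
    for year, pops, rates in ((ref_year, case["pop_ref"], case["rates_ref"]),
                              (cur_year, case["pop_cur"], case["rates_cur"])):
        for a in case["ages"]:
            cell_rows.append((location, year, sex, a, "incidence", "count",
                              pops[a] * rates[a] / 1e5, np.nan, np.nan))
            pop_rows.append((location, year, sex, a, pops[a]))
    cells = pd.DataFrame(cell_rows, columns=CELL_COLUMNS)
    pops_df = pd.DataFrame(pop_rows, columns=["location", "year", "sex",
                                              "age_group", "population"])
    return cells, pops_df
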