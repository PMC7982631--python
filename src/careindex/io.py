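"""Reading, validating and pivoting GBD-results-style burden tables.

The canonical in-memory representation of a collection of burden cells is a
:class:`pandas.DataFrame` with columns ``location, year, sex, age_group,
measure, metric, value, lower, upper`` (one row per cell).  A pivoted panel
holds one row per stratum (location, year, sex, age group) with the six
burden measures as count columns.

Counts — not rates — are the canonical input for all downstream ratio
indices: within a stratum, count ratios equal rate ratios, and counts avoid
the rounding applied to published per-100,000 rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import DomainError, IntegrityError, SchemaError, VocabularyError

MEASURES: tuple[str, ...] = ("incidence", "prevalence", "deaths", "dalys", "ylls", "ylds")
SEXES: tuple[str, ...] = ("female", "male", "both")
METRICS: tuple[str, ...] = ("count", "rate_per_100k")

#: GBD 5-year age bins, youngest first, plus the aggregate labels accepted on read.
AGE_BINS: tuple[str, ...] = tuple(
    f"{5 * i} to {5 * i + 4}" for i in range(19)
) + ("95 plus",)
AGGREGATE_AGE_LABELS: tuple[str, ...] = ("All Ages", "Age-standardized")
AGE_VOCABULARY: tuple[str, ...] = AGE_BINS + AGGREGATE_AGE_LABELS

#: Default column-name map matching the GBD results-tool CSV export.
DEFAULT_DIALECT: dict[str, str] = {
    "measure": "measure_name",
    "location": "location_name",
    "sex": "sex_name",
    "age_group": "age_name",
    "year": "year",
    "metric": "metric_name",
    "value": "val",
    "lower": "lower",
    "upper": "upper",
}

_MEASURE_ALIASES = {
    "incidence": "incidence",
    "prevalence": "prevalence",
    "deaths": "deaths",
    "dalys": "dalys",
    "dalys (disability-adjusted life years)": "dalys",
    "ylls": "ylls",
    "ylls (years of life lost)": "ylls",
    "ylds": "ylds",
    "ylds (years lived with disability)": "ylds",
}
_SEX_ALIASES = {"female": "female", "male": "male", "both": "both"}
_METRIC_ALIASES = {
    "count": "count",
    "number": "count",
    "rate": "rate_per_100k",
    "rate_per_100k": "rate_per_100k",
}

CELL_COLUMNS = ["location", "year", "sex", "age_group", "measure", "metric",
                "value", "lower", "upper"]
KEY_COLUMNS = ["location", "year", "sex", "age_group"]

#: Relative tolerance for the DALY = YLL + YLD consistency warning.  Published
#: tables round internally, so a small discrepancy is a warning, not an error.
DALY_IDENTITY_RTOL = 1e-3


@dataclass(frozen=True)
class StratumKey:
    """Identifies one (location, year, sex, age-group) cell of a panel."""

    location: str
    year: int
    sex: str
    age_group: str


@dataclass(frozen=True)
class BurdenCell:
    """One measure value for one stratum, with optional uncertainty bounds."""

    location: str
    year: int
    sex: str
    age_group: str
    measure: str
    metric: str
    value: float
    lower: float | None = None
    upper: float | None = None


@dataclass(frozen=True)
class MeasurePanel:
    """All six burden measures, as counts, for one stratum."""

    key: StratumKey
    incidence: float
    prevalence: float
    deaths: float
    dalys: float
    ylls: float
    ylds: float


def _normalise(raw: object, aliases: Mapping[str, str], kind: str, row: int) -> str:
    label = str(raw).strip()
    try:
        return aliases[label.lower()]
    except KeyError:
        raise VocabularyError(
            f"unknown {kind} label {label!r} at row {row}"
        ) from None


def read_gbd_csv(path, dialect: Mapping[str, str] | None = None,
                 age_vocabulary: Sequence[str] = AGE_VOCABULARY) -> pd.DataFrame:
    """Read a GBD-results-style CSV into the canonical cell DataFrame.

    Parameters
    ----------
    path
        CSV file (gzip-compressed input is accepted transparently).
    dialect
        Map from canonical column names (``measure``, ``location``, ...) to
        the column names used in the file.  Defaults to the GBD results-tool
        export.  ``lower``/``upper`` entries are optional.
    age_vocabulary
        Accepted age-group labels; anything else raises
        :class:`~careindex.errors.VocabularyError`.

    Returns
    -------
    pandas.DataFrame
        One row per cell, columns :data:`CELL_COLUMNS`.  Row order and row
        count are preserved from the file.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    raw = pd.read_csv(path)

    required = ["measure", "location", "sex", "age_group", "year", "metric", "value"]
    for canon in required:
        if dialect[canon] not in raw.columns:
            raise SchemaError(
                f"required column {dialect[canon]!r} (for {canon!r}) "
                f"not found in header {list(raw.columns)}"
            )

    out = pd.DataFrame(index=raw.index)
    out["location"] = raw[dialect["location"]].astype(str)
    out["year"] = raw[dialect["year"]].astype(int)

    age_set = set(age_vocabulary)
    cells_sex, cells_meas, cells_metric, cells_age = [], [], [], []
    for i, (sex, meas, metric, age) in enumerate(
        zip(raw[dialect["sex"]], raw[dialect["measure"]],
            raw[dialect["metric"]], raw[dialect["age_group"]])
    ):
        cells_sex.append(_normalise(sex, _SEX_ALIASES, "sex", i + 1))
        cells_meas.append(_normalise(meas, _MEASURE_ALIASES, "measure", i + 1))
        cells_metric.append(_normalise(metric, _METRIC_ALIASES, "metric", i + 1))
        age_label = str(age).strip()
        if age_label not in age_set:
            raise VocabularyError(f"unknown age_group label {age_label!r} at row {i + 1}")
        cells_age.append(age_label)
    out["sex"] = cells_sex
    out["age_group"] = cells_age
    out["measure"] = cells_meas
    out["metric"] = cells_metric

    out["value"] = pd.to_numeric(raw[dialect["value"]])
    for bound in ("lower", "upper"):
        col = dialect.get(bound)
        out[bound] = pd.to_numeric(raw[col]) if col in raw.columns else float("nan")

    if (out["value"] < 0).any():
        bad = int(out.index[out["value"] < 0][0]) + 1
        raise DomainError(f"negative value at row {bad}")
    has_bounds = out["lower"].notna() & out["upper"].notna()
    violated = has_bounds & ~(
        (out["lower"] <= out["value"]) & (out["value"] <= out["upper"])
    )
    if violated.any():
        bad = int(out.index[violated][0]) + 1
        raise DomainError(f"value outside its [lower, upper] bounds at row {bad}")
    return out[CELL_COLUMNS]


def pivot_panel(cells: pd.DataFrame, metric: str = "count",
                check_daly_identity: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot burden cells into per-stratum measure panels.

    Keeps cells at the requested ``metric``, drops ``Age-standardized`` rows
    (ratio indices are computed on counts per age group or on all-age
    aggregates), and returns one wide row per stratum with all six measures.
    Strata missing any measure are never silently dropped: they come back in
    the exclusion table with a reason.

    Returns
    -------
    (panels, exclusions)
        ``panels``: columns :data:`KEY_COLUMNS` + the six measures.
        ``exclusions``: columns :data:`KEY_COLUMNS` + ``reason``.
    """
    if metric not in METRICS:
        raise VocabularyError(f"unknown metric {metric!r}; expected one of {METRICS}")
    sub = cells[(cells["metric"] == metric)
                & (cells["age_group"] != "Age-standardized")]

    dup = sub.duplicated(subset=KEY_COLUMNS + ["measure"], keep=False)
    if dup.any():
        pairs = (sub.loc[dup, KEY_COLUMNS + ["measure"]]
                 .drop_duplicates().to_dict("records"))
        raise IntegrityError(f"duplicate (stratum, measure) cells: {pairs}")

    if sub.empty:
        empty_keys = pd.DataFrame(columns=KEY_COLUMNS)
        return (empty_keys.assign(**{m: [] for m in MEASURES}),
                empty_keys.assign(reason=[]))

    wide = sub.pivot_table(index=KEY_COLUMNS, columns="measure", values="value",
                           aggfunc="first", observed=True)
    wide = wide.reindex(columns=list(MEASURES))

    missing_mask = wide.isna()
    incomplete = missing_mask.any(axis=1)
    exclusions = wide.index.to_frame(index=False)[incomplete.to_numpy()].copy()
    if incomplete.any():
        reasons = missing_mask[incomplete.to_numpy()].apply(
            lambda row: "missing " + ", ".join(m for m in MEASURES if row[m]), axis=1
        )
        exclusions["reason"] = reasons.to_numpy()
    else:
        exclusions["reason"] = pd.Series(dtype=str)

    panels = wide[~incomplete.to_numpy()].reset_index()
    panels.columns.name = None

    if check_daly_identity and len(panels):
        resid = (panels["dalys"] - (panels["ylls"] + panels["ylds"])).abs()
        denom = panels["dalys"].where(panels["dalys"] > 0, 1.0)
        bad = resid / denom > DALY_IDENTITY_RTOL
        if bad.any():
            warnings.warn(
                f"DALY != YLL + YLD beyond {DALY_IDENTITY_RTOL:.1%} relative "
                f"tolerance in {int(bad.sum())} strata",
                stacklevel=2,
            )
    return panels, exclusions


def panels_to_records(panels: pd.DataFrame) -> list[MeasurePanel]:
    """Materialise panel rows as :class:`MeasurePanel` dataclasses."""
    return [
        MeasurePanel(
            key=StratumKey(r.location, int(r.year), r.sex, r.age_group),
            incidence=r.incidence, prevalence=r.prevalence, deaths=r.deaths,
            dalys=r.dalys, ylls=r.ylls, ylds=r.ylds,
        )
        for r in panels.itertuples(index=False)
    ]


def write_table(records: pd.DataFrame, path,
                provenance: Mapping[str, object] | None = None) -> None:
    """Write a tabular result as CSV at full precision.

    Floats are written with ``repr`` precision so a round-trip read returns
    identical values.  An optional provenance mapping is written as leading
    ``# key=value`` comment lines (skipped by :func:`read_table`).
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}={val}\n")
        records.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a table written by :func:`write_table`, skipping provenance lines."""
    return pd.read_csv(path, comment="#")
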