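"""The four secondary care-quality ratio indices, computed per stratum.

For one stratum with complete burden counts the indices are

* ``mir``       = deaths / incidence   (mortality-to-incidence ratio; higher
  means more of the newly diagnosed die — worse care),
* ``daly_prev`` = DALYs / prevalence   (burden per prevalent case),
* ``prev_inc``  = prevalence / incidence  (how long cases survive under
  management — higher is better),
* ``yll_yld``   = YLLs / YLDs          (deaths dominating disability —
  higher means patients die rather than live with the disease).

A zero denominator makes the affected ratio undefined; the stratum is
flagged invalid with the offending ratio(s) named, and excluded from model
fitting but never silently dropped.  Denominators are never epsilon-padded:
padding distorts small strata more than exclusion does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .io import KEY_COLUMNS, MeasurePanel, StratumKey

#: Fixed column order of the index matrix consumed by the QCI model.
INDEX_COLUMNS: tuple[str, ...] = ("mir", "daly_prev", "prev_inc", "yll_yld")

#: (numerator, denominator) measure for each ratio.
_RATIO_DEFS: dict[str, tuple[str, str]] = {
    "mir": ("deaths", "incidence"),
    "daly_prev": ("dalys", "prevalence"),
    "prev_inc": ("prevalence", "incidence"),
    "yll_yld": ("ylls", "ylds"),
}


@dataclass(frozen=True)
class IndexVector:
    """The four ratio indices for one stratum; invalid when any is undefined."""

    key: StratumKey
    mir: float
    daly_prev: float
    prev_inc: float
    yll_yld: float
    valid: bool = True
    reason: str = ""


def compute_indices(panel: MeasurePanel) -> IndexVector:
    """Compute the four ratio indices for a single measure panel.

    Zero denominators flag the vector invalid (reason names every undefined
    ratio); a zero numerator over a positive denominator is simply 0.
    """
    values: dict[str, float] = {}
    undefined: list[str] = []
    for name, (num, den) in _RATIO_DEFS.items():
        d = getattr(panel, den)
        if d == 0:
            undefined.append(name)
            values[name] = float("nan")
        else:
            values[name] = getattr(panel, num) / d
    return IndexVector(
        key=panel.key, valid=not undefined,
        reason="undefined ratio(s): " + ", ".join(undefined) if undefined else "",
        **values,
    )


def index_table(panels: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`compute_indices` over a panel DataFrame.

    Returns one row per stratum with key columns, the four ratios, a
    ``valid`` flag and a ``reason`` column.
    """
    out = panels[KEY_COLUMNS].copy()
    undefined = np.full(len(panels), "", dtype=object)
    for name, (num, den) in _RATIO_DEFS.items():
        d = panels[den].to_numpy(dtype=float)
        n = panels[num].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d == 0, np.nan, n / np.where(d == 0, 1.0, d))
        out[name] = ratio
        zero = d == 0
        undefined[zero] = np.where(
            undefined[zero] == "", name,
            undefined[zero].astype(object) + ", " + name,
        )
    out["valid"] = undefined == ""
    out["reason"] = np.where(
        undefined == "", "", "undefined ratio(s): " + undefined.astype(str)
    )
    return out


def index_matrix(vectors: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Assemble the observation matrix for QCI fitting.

    Parameters
    ----------
    vectors
        Output of :func:`index_table` (or any frame with the four ratio
        columns, key columns and a ``valid`` flag).

    Returns
    -------
    (matrix, keys)
        ``matrix``: float array of shape (n_valid, 4) in the fixed column
        order :data:`INDEX_COLUMNS`.  ``keys``: the key columns of the valid
        rows, positionally aligned with the matrix rows.
    """
    valid = vectors[vectors["valid"]] if "valid" in vectors.columns else vectors
    if len(valid) < 2:
        raise InsufficientDataError(
            f"need at least 2 valid index vectors to build a matrix, got {len(valid)}"
        )
    matrix = valid[list(INDEX_COLUMNS)].to_numpy(dtype=float)
    keys = valid[KEY_COLUMNS].reset_index(drop=True)
    return matrix, keys


def vectors_to_table(vectors: list[IndexVector]) -> pd.DataFrame:
    """Convert :class:`IndexVector` records to the tabular form."""
    return pd.DataFrame(
        {
            "location": [v.key.location for v in vectors],
            "year": [v.key.year for v in vectors],
            "sex": [v.key.sex for v in vectors],
            "age_group": [v.key.age_group for v in vectors],
            **{c: [getattr(v, c) for v in vectors] for c in INDEX_COLUMNS},
            "valid": [v.valid for v in vectors],
            "reason": [v.reason for v in vectors],
        }
    )
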