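"""Gender-disparity ratio (GDR) tables built on QCI scores.

GDR = QCI(female) / QCI(male) for a shared (location, year, age-group) key.
A ratio near one means the two sexes receive comparable care; above one,
care favours women.  The ratio is taken on the rescaled 0-100 QCI — raw
first-component scores are affine and their ratios are meaningless across
the zero point.  A male score of exactly 0 (a rescale-endpoint artifact)
yields an undefined ratio rather than infinity.

Because two locations can share a near-one GDR while their absolute scores
differ wildly, :func:`scatter_pairs` emits the paired scores themselves for
a both-sex scatter comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PairingError

PAIR_KEY = ["location", "year", "age_group"]


@dataclass(frozen=True)
class GDRRecord:
    location: str
    year: int
    age_group: str
    qci_female: float
    qci_male: float
    gdr: float | None  # None when qci_male == 0

    @property
    def defined(self) -> bool:
        return self.gdr is not None


def compute_gdr(female, male) -> GDRRecord:
    """GDR for one matched pair of per-sex QCI score records.

    ``female`` and ``male`` are mappings (or pandas rows) with ``location``,
    ``year``, ``age_group``, ``sex`` and ``qci`` entries sharing the same
    stratum key.
    """
    f, m = dict(female), dict(male)
    key_f = tuple(f[k] for k in PAIR_KEY)
    key_m = tuple(m[k] for k in PAIR_KEY)
    if key_f != key_m:
        raise PairingError(f"stratum keys differ: {key_f} vs {key_m}")
    if f.get("sex", "female") != "female" or m.get("sex", "male") != "male":
        raise PairingError(
            f"expected (female, male) records, got ({f.get('sex')}, {m.get('sex')})"
        )
    qf, qm = float(f["qci"]), float(m["qci"])
    return GDRRecord(
        location=f["location"], year=int(f["year"]), age_group=f["age_group"],
        qci_female=qf, qci_male=qm,
        gdr=qf / qm if qm > 0 else None,
    )


def gdr_table(scores: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GDR for every key present with both sexes.

    Parameters
    ----------
    scores
        QCI score table with columns ``location, year, sex, age_group, qci``
        (the per-stratum output of ``score_qci``, or any aggregate of it that
        retains a sex column).

    Returns
    -------
    (records, exclusions)
        ``records``: one row per complete pair with ``qci_female``,
        ``qci_male``, ``gdr`` (NaN where undefined) and ``defined``.
        ``exclusions``: keys having only one sex, with the sex that is
        missing.
    """
    sexed = scores[scores["sex"].isin(["female", "male"])]
    wide = sexed.pivot_table(index=PAIR_KEY, columns="sex", values="qci",
                             aggfunc="first", observed=True)
    wide = wide.reindex(columns=["female", "male"])

    complete = wide.notna().all(axis=1)
    records = wide[complete].reset_index()
    records.columns.name = None
    records = records.rename(columns={"female": "qci_female", "male": "qci_male"})
    with np.errstate(divide="ignore", invalid="ignore"):
        records["gdr"] = np.where(records["qci_male"] > 0,
                                  records["qci_female"] / records["qci_male"],
                                  np.nan)
    records["defined"] = records["qci_male"] > 0

    excl = wide[~complete].reset_index()
    excl.columns.name = None
    excl["reason"] = np.where(excl["female"].isna(), "missing female score",
                              "missing male score")
    exclusions = excl[PAIR_KEY + ["reason"]]
    return records, exclusions


def scatter_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Paired (female, male) score table for a both-sex scatter comparison.

    Rows are sorted deterministically by location (then year, age group);
    values pass through unaltered.
    """
    cols = ["location", "qci_female", "qci_male", "gdr"]
    sort_cols = [c for c in PAIR_KEY if c in records.columns]
    return records.sort_values(sort_cols, kind="stable")[cols].reset_index(drop=True)
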