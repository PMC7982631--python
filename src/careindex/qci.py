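"""Quality of Care Index: first-principal-component summary of the four
ratio indices, oriented so higher = better care, rescaled to 0-100.

The summarizer is PCA on the *correlation* matrix (z-scored indices), not
the covariance: the four ratios live on incommensurable scales (MIR is well
below 1, prevalence/incidence is around 8 for thyroid cancer), and a 0-100
score demands a scale-free combination.  The leading eigenvector gives the
loadings; its sign is first fixed deterministically (largest-magnitude
loading positive) and then an orientation flip is applied so that the score
is anti-correlated with MIR over the fitting set — higher score, better
care.  Scores are min-max rescaled to [0, 100] on the fitting set, with
out-of-fit scores clipped and flagged.

One pooled model is fitted over all finest-level strata across the full
study period; coarser scales (all-age, both-sex, per-location compilations)
are scored by summing the constituent measure *counts*, recomputing the
ratios, and scoring — never by averaging constituent scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import (CoverageError, DegenerateDataError,
                     InsufficientDataError, VocabularyError)
from .indices import INDEX_COLUMNS, index_matrix, index_table
from .io import KEY_COLUMNS, MEASURES

_NORM_ATOL = 1e-12  # unit-norm tolerance on the loading vector

#: Grouping columns retained by each aggregation level; the remaining key
#: dimensions are summed out (counts added) before ratios are recomputed.
AGGREGATION_LEVELS: dict[str, list[str]] = {
    "all_age": ["location", "year", "sex"],
    "both_sex": ["location", "year", "age_group"],
    "location_year": ["location", "year"],
    "location": ["location"],
}


class QualityOfCareIndex(TransformerMixin, BaseEstimator):
    """First-principal-component care-quality score on the 0-100 scale.

    Parameters
    ----------
    clip : bool, default=True
        Clip out-of-fit scores into [0, 100].  Scores from the fitting set
        always lie inside the rescale bounds by construction.

    Attributes
    ----------
    means_, sds_ : ndarray of shape (4,)
        Standardization parameters of the fitting set (sample sd, ddof=1).
    loadings_ : ndarray of shape (4,)
        Unit-norm leading eigenvector of the 4x4 correlation matrix, sign
        fixed so the largest-magnitude loading is positive.
    orientation_ : {-1, 1}
        Flip applied so the oriented score is anti-correlated with MIR.
    variance_explained_ : float
        Leading eigenvalue / 4.
    score_min_, score_max_ : float
        Oriented raw-score range over the fitting set (rescale bounds).
    fit_n_ : int
        Number of fitting observations.
    """

    def __init__(self, clip: bool = True):
        self.clip = clip

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None) -> "QualityOfCareIndex":
        """Fit standardization, loadings, orientation and rescale bounds.

        ``X`` is an (n, 4) array in the fixed column order
        ``(mir, daly_prev, prev_inc, yll_yld)`` with n >= 2 and every column
        of nonzero variance.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(INDEX_COLUMNS):
            raise ValueError(
                f"expected an (n, {len(INDEX_COLUMNS)}) matrix, got shape {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("index matrix contains non-finite values")
        n = X.shape[0]
        if n < 2:
            raise InsufficientDataError(f"need at least 2 observations, got {n}")

        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        # a numerically constant column: sd indistinguishable from rounding
        # noise on the column's own scale
        dead = np.flatnonzero(sds <= 1e-12 * np.maximum(np.abs(means), 1.0))
        if dead.size:
            names = ", ".join(INDEX_COLUMNS[i] for i in dead)
            raise DegenerateDataError(f"zero-variance index column(s): {names}")

        Z = (X - means) / sds
        corr = (Z.T @ Z) / (n - 1)
        eigvals, eigvecs = np.linalg.eigh(corr)
        leading = eigvecs[:, -1]
        # eigenvector sign is arbitrary: make the largest-|loading| positive
        anchor = int(np.argmax(np.abs(leading)))
        if leading[anchor] < 0:
            leading = -leading

        scores = Z @ leading
        mir = X[:, 0]
        corr_mir = float(np.corrcoef(scores, mir)[0, 1]) if np.ptp(scores) else 0.0
        orientation = -1 if corr_mir > 0 else 1
        oriented = orientation * scores

        if orientation * leading[0] > 0:
            raise DegenerateDataError(
                "oriented MIR loading is positive: the leading component does "
                "not contrast mortality against the other indices on these "
                "data, so a higher-is-better orientation is not defined"
            )

        self.means_ = means
        self.sds_ = sds
        self.loadings_ = leading
        self.orientation_ = orientation
        self.variance_explained_ = float(eigvals[-1] / len(INDEX_COLUMNS))
        self.score_min_ = float(oriented.min())
        self.score_max_ = float(oriented.max())
        self.fit_n_ = n
        if not self.score_min_ < self.score_max_:
            raise DegenerateDataError("all fitting observations score identically")
        assert abs(np.linalg.norm(self.loadings_) - 1.0) < _NORM_ATOL
        return self

    # ------------------------------------------------------------- scoring
    def raw_score(self, X) -> np.ndarray:
        """Oriented first-component score before rescaling."""
        check_is_fitted(self, "loadings_")
        X = np.asarray(X, dtype=float)
        Z = (X - self.means_) / self.sds_
        return self.orientation_ * (Z @ self.loadings_)

    def transform(self, X) -> np.ndarray:
        """Map index vectors to 0-100 QCI scores; returns shape (n, 1)."""
        return self.score(X)[0].reshape(-1, 1)

    def score(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(qci, clipped)`` for an (n, 4) index matrix.

        ``qci`` is ``100 * (raw - score_min_) / (score_max_ - score_min_)``
        clipped into [0, 100]; ``clipped`` flags scores whose raw value fell
        outside the fitting range.
        """
        raw = self.raw_score(X)
        span = self.score_max_ - self.score_min_
        qci = 100.0 * (raw - self.score_min_) / span
        clipped = (raw < self.score_min_) | (raw > self.score_max_)
        if self.clip:
            qci = np.clip(qci, 0.0, 100.0)
        return qci, clipped

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["qci"], dtype=object)

    # ------------------------------------------------------- serialization
    def to_text(self) -> str:
        """Serialise the fitted model as flat ``key=value`` lines.

        Floats are written with ``repr`` so the round trip is exact.
        """
        check_is_fitted(self, "loadings_")
        lines = []
        for name, vec in (("mean", self.means_), ("sd", self.sds_),
                          ("loading", self.loadings_)):
            for col, v in zip(INDEX_COLUMNS, vec):
                lines.append(f"{name}.{col}={float(v)!r}")
        lines += [
            f"orientation={self.orientation_}",
            f"variance_explained={self.variance_explained_!r}",
            f"score_min={self.score_min_!r}",
            f"score_max={self.score_max_!r}",
            f"fit_n={self.fit_n_}",
            f"clip={self.clip}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "QualityOfCareIndex":
        kv = dict(line.split("=", 1) for line in text.strip().splitlines())
        model = cls(clip=kv.get("clip", "True") == "True")
        model.means_ = np.array([float(kv[f"mean.{c}"]) for c in INDEX_COLUMNS])
        model.sds_ = np.array([float(kv[f"sd.{c}"]) for c in INDEX_COLUMNS])
        model.loadings_ = np.array([float(kv[f"loading.{c}"]) for c in INDEX_COLUMNS])
        model.orientation_ = int(kv["orientation"])
        model.variance_explained_ = float(kv["variance_explained"])
        model.score_min_ = float(kv["score_min"])
        model.score_max_ = float(kv["score_max"])
        model.fit_n_ = int(kv["fit_n"])
        return model


# ---------------------------------------------------------------- wrappers

def fit_qci(matrix: np.ndarray, clip: bool = True) -> QualityOfCareIndex:
    """Fit a :class:`QualityOfCareIndex` on an (n, 4) index matrix."""
    return QualityOfCareIndex(clip=clip).fit(matrix)


def score_qci(model: QualityOfCareIndex,
              vectors: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score an index table; invalid vectors are skipped with an audit record.

    Returns
    -------
    (scores, audit)
        ``scores``: key columns + ``raw_score``, ``qci``, ``clipped`` for
        every valid vector.  ``audit``: the skipped rows with their reasons.
    """
    valid_mask = vectors["valid"] if "valid" in vectors.columns \
        else pd.Series(True, index=vectors.index)
    valid = vectors[valid_mask]
    audit = vectors.loc[~valid_mask, KEY_COLUMNS + ["reason"]].reset_index(drop=True)

    X = valid[list(INDEX_COLUMNS)].to_numpy(dtype=float)
    scores = valid[KEY_COLUMNS].reset_index(drop=True)
    if len(valid):
        qci, clipped = model.score(X)
        scores["raw_score"] = model.raw_score(X)
        scores["qci"] = qci
        scores["clipped"] = clipped
    else:
        scores["raw_score"] = scores["qci"] = np.nan
        scores["clipped"] = pd.Series(dtype=bool)
    return scores, audit


def fit_qci_from_panels(panels: pd.DataFrame,
                        clip: bool = True) -> tuple[QualityOfCareIndex, pd.DataFrame]:
    """Compute indices from panels, fit the pooled model, return both."""
    vectors = index_table(panels)
    matrix, _ = index_matrix(vectors)
    return fit_qci(matrix, clip=clip), vectors


def aggregate_qci(model: QualityOfCareIndex, panels: pd.DataFrame,
                  level: str, check_coverage: bool = True) -> pd.DataFrame:
    """Score a coarser scale by summing constituent measure counts.

    The aggregate QCI of, say, a location-year is the score of the ratio
    vector recomputed on the summed counts of its strata — not the average
    of the constituent scores.

    Parameters
    ----------
    level
        One of :data:`AGGREGATION_LEVELS` (``all_age``, ``both_sex``,
        ``location_year``, ``location``).
    check_coverage
        Require every group to cover the full cross-product of the summed-out
        dimensions observed in the panel; missing strata raise
        :class:`~careindex.errors.CoverageError`.
    """
    if level not in AGGREGATION_LEVELS:
        raise VocabularyError(
            f"unknown aggregation level {level!r}; expected one of "
            f"{sorted(AGGREGATION_LEVELS)}"
        )
    group_cols = AGGREGATION_LEVELS[level]
    summed_out = [c for c in KEY_COLUMNS if c not in group_cols]

    if check_coverage and summed_out:
        expected = 1
        for c in summed_out:
            expected *= panels[c].nunique()
        counts = panels.groupby(group_cols, sort=True).size()
        short = counts[counts < expected]
        if len(short):
            missing = []
            full = {c: set(panels[c].unique()) for c in summed_out}
            for key, _ in short.items():
                key = key if isinstance(key, tuple) else (key,)
                grp = panels
                for c, v in zip(group_cols, key):
                    grp = grp[grp[c] == v]
                for c in summed_out:
                    absent = full[c] - set(grp[c].unique())
                    if absent:
                        missing.append(f"{dict(zip(group_cols, key))}: "
                                       f"missing {c} {sorted(absent)}")
            raise CoverageError("incomplete aggregate coverage: " + "; ".join(missing))

    summed = panels.groupby(group_cols, sort=True, as_index=False)[list(MEASURES)].sum()
    for c in summed_out:  # re-expose the summed-out dimensions as aggregates
        summed[c] = {"age_group": "All Ages", "sex": "both",
                     "year": "all_years", "location": "all_locations"}[c]
    vectors = index_table(summed[KEY_COLUMNS + list(MEASURES)])
    scores, _ = score_qci(model, vectors)
    return scores[group_cols + ["raw_score", "qci", "clipped"]]
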