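"""Sample normalization and missingness routing.

Two jobs happen before any inference: (1) equalize sample medians on the
log2 scale so between-sample loading differences cancel, and (2) split the
proteins into a quantitative path (enough observations in both disease
groups to regress on) and a detection-limit heuristic path (too sparse to
model, but possibly "uniquely expressed" in one group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import PreprocessError, ValidationError

__all__ = [
    "MedianNormalizer",
    "MissingnessRouter",
    "MissingnessRouting",
    "median_normalize",
    "route_by_missingness",
    "classify_detection_limit",
]


def _check_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(matrix, pd.DataFrame):
        raise ValidationError("intensity matrix must be a pandas DataFrame "
                              "(proteins x samples)")
    if matrix.index.has_duplicates:
        dup = sorted(matrix.index[matrix.index.duplicated()].unique())
        raise ValidationError(f"duplicate protein ids: {dup}")
    if matrix.columns.has_duplicates:
        dup = sorted(matrix.columns[matrix.columns.duplicated()].unique())
        raise ValidationError(f"duplicate sample ids: {dup}")
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValidationError("intensity matrix is empty")
    return matrix


def _check_design(design: pd.DataFrame, matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    required = {"sample", "group", "batch"}
    if not isinstance(design, pd.DataFrame) or not required <= set(design.columns):
        raise ValidationError(f"design must be a DataFrame with columns {sorted(required)}")
    bad = set(design["group"]) - {"DM", "NDM"}
    if bad:
        raise ValidationError(f"group labels must be DM or NDM, found {sorted(bad)}")
    if len(set(design["group"])) < 2:
        raise ValidationError("both DM and NDM groups must be represented")
    if design["sample"].duplicated().any():
        raise ValidationError("duplicate sample ids in design")
    if matrix is not None:
        missing = set(matrix.columns) - set(design["sample"])
        if missing:
            raise ValidationError(f"samples absent from design: {sorted(missing)}")
    return design


class MedianNormalizer(TransformerMixin, BaseEstimator):
    """Equalize per-sample medians by an additive log2 shift.

    Each sample's observed values are shifted so every sample median equals
    the median of the input's per-sample medians (equivalently a
    multiplicative rescaling of raw intensities).  Missing entries are
    ignored when computing medians and stay missing.  The transform is
    stateless -- the target is recomputed from the matrix being transformed,
    which makes it idempotent.
    """

    def fit(self, X, y=None):
        _check_matrix(X)
        return self

    def transform(self, X) -> pd.DataFrame:
        _check_matrix(X)
        medians = X.median(axis=0, skipna=True)
        empty = medians.index[medians.isna()]
        if len(empty):
            raise PreprocessError(
                f"sample(s) with no observed values: {list(empty)}")
        target = float(medians.median())
        return X.add(target - medians, axis=1)


def median_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Shift each sample so all sample medians agree (log2 scale)."""
    return MedianNormalizer().fit_transform(matrix)


@dataclass
class MissingnessRouting:
    """Partition of proteins into quantitative and heuristic paths."""

    quantitative_ids: list
    heuristic_ids: list
    observed_counts: pd.DataFrame  # index protein_id, columns n_obs_DM, n_obs_NDM


def _observed_counts(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    by_group = design.set_index("sample")["group"]
    counts = {}
    for g in ("DM", "NDM"):
        cols = [s for s in matrix.columns if by_group[s] == g]
        counts[f"n_obs_{g}"] = matrix[cols].notna().sum(axis=1)
    out = pd.DataFrame(counts)
    out.index.name = "protein_id"
    return out


def route_by_missingness(matrix: pd.DataFrame, design: pd.DataFrame,
                         min_per_group: int = 4) -> MissingnessRouting:
    """Quantitative iff observed at least ``min_per_group`` times in BOTH groups."""
    _check_matrix(matrix)
    _check_design(design, matrix)
    counts = _observed_counts(matrix, design)
    quant = (counts["n_obs_DM"] >= min_per_group) & (counts["n_obs_NDM"] >= min_per_group)
    return MissingnessRouting(
        quantitative_ids=list(counts.index[quant]),
        heuristic_ids=list(counts.index[~quant]),
        observed_counts=counts,
    )


def classify_detection_limit(matrix: pd.DataFrame, design: pd.DataFrame,
                             heuristic_ids=None, nmin_present: int | None = None,
                             nmax_absent: int | None = None) -> pd.DataFrame:
    """Call group-unique expression among sparsely quantified proteins.

    A protein is ``unique_DM`` when observed in at least ``nmin_present`` DM
    samples and at most ``nmax_absent`` NDM samples (and symmetrically for
    ``unique_NDM``); anything else is ``insufficient``.  When thresholds are
    not given they scale with group size as ceil(0.7 * n_group) present and
    floor(0.1 * n_group) absent -- 7 and 1 for groups of 10.
    """
    _check_matrix(matrix)
    _check_design(design, matrix)
    if heuristic_ids is None:
        heuristic_ids = list(matrix.index)
    unknown = set(heuristic_ids) - set(matrix.index)
    if unknown:
        raise ValidationError(f"heuristic ids not in matrix: {sorted(unknown)}")

    n_by_group = design.groupby("group")["sample"].count()
    counts = _observed_counts(matrix, design).loc[list(heuristic_ids)]

    def thresholds(group):
        n = int(n_by_group[group])
        lo = nmin_present if nmin_present is not None else math.ceil(0.7 * n)
        hi = nmax_absent if nmax_absent is not None else math.floor(0.1 * n)
        return lo, hi

    nmin_dm, _ = thresholds("DM")
    nmin_ndm, _ = thresholds("NDM")
    _, nmax_dm = thresholds("DM")
    _, nmax_ndm = thresholds("NDM")

    dm, ndm = counts["n_obs_DM"], counts["n_obs_NDM"]
    call = np.where((dm >= nmin_dm) & (ndm <= nmax_ndm), "unique_DM",
                    np.where((ndm >= nmin_ndm) & (dm <= nmax_dm),
                             "unique_NDM", "insufficient"))
    return pd.DataFrame({"protein_id": list(heuristic_ids), "call": call,
                         "n_obs_DM": dm.to_numpy(), "n_obs_NDM": ndm.to_numpy()})


class MissingnessRouter(BaseEstimator):
    """Route proteins by group-wise observation counts and call unique expression.

    Parameters
    ----------
    min_per_group : int, default 4
        Minimum observations in each group for the quantitative path.
    nmin_present, nmax_absent : int or None
        Detection-limit heuristic thresholds; ``None`` auto-scales with
        group size (7 present / 1 absent for groups of 10).

    Attributes (after :meth:`fit`)
    ------------------------------
    routing_ : MissingnessRouting
    unique_calls_ : pandas.DataFrame
        One row per heuristic-path protein with its call.
    """

    def __init__(self, min_per_group: int = 4, nmin_present: int | None = None,
                 nmax_absent: int | None = None):
        self.min_per_group = min_per_group
        self.nmin_present = nmin_present
        self.nmax_absent = nmax_absent

    def fit(self, X, design):
        self.routing_ = route_by_missingness(X, design, self.min_per_group)
        self.unique_calls_ = classify_detection_limit(
            X, design, self.routing_.heuristic_ids,
            self.nmin_present, self.nmax_absent)
        return self
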