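"""Turn grouped expression data into criteria tables.

Each performance measure is the absolute difference of a group statistic
(mean or median) between two sample conditions, negated so that large
expression changes map to small criterion values (minimization sense).  A
single two-group study contributes two measures (mean and median
difference); a meta-analysis contributes one median-difference measure per
contrast, up to five in one run.

Values are used exactly as stored — no normalization or log transform — so
the frontier is invariant to any monotone rescaling of a criterion but
reflects the raw units of the source matrix.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import ExpressionDataset
from .frontier import CriteriaTable

#: largest number of criteria supported in one analysis
MAX_CRITERIA = 5
#: a statistic needs at least this many non-missing values per group
MIN_GROUP_VALUES = 2

_STATS = {"mean": np.nanmean, "median": np.nanmedian}


@dataclasses.dataclass
class GroupContrast:
    """One performance measure: |stat(group_a) - stat(group_b)| per gene.

    ``group_a`` plays the role of the reference condition ("control") and
    ``group_b`` the altered one ("cancer"); the absolute difference makes
    the order immaterial.
    """

    name: str
    group_a: list
    group_b: list
    statistic: str = "median"

    def __post_init__(self):
        if self.statistic not in _STATS:
            raise ValueError(f"statistic must be one of {sorted(_STATS)}, "
                             f"got {self.statistic!r}")
        if not self.group_a or not self.group_b:
            raise ValueError(f"contrast {self.name!r}: both groups must be nonempty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.name!r}: groups must be disjoint")


def group_stat_difference(dataset: ExpressionDataset,
                          contrast: GroupContrast) -> pd.Series:
    """Per-gene absolute difference of the group statistic.

    The statistic (mean, or midpoint-convention median) is computed over
    non-missing values only.  Genes with fewer than two usable values in
    either group get NaN, flagging them for exclusion.
    """
    ia = dataset.sample_index(contrast.group_a)
    ib = dataset.sample_index(contrast.group_b)
    stat = _STATS[contrast.statistic]
    va, vb = dataset.values[:, ia], dataset.values[:, ib]
    ok = ((np.isfinite(va).sum(axis=1) >= MIN_GROUP_VALUES)
          & (np.isfinite(vb).sum(axis=1) >= MIN_GROUP_VALUES))
    diff = np.full(dataset.n_probes, np.nan)
    if ok.any():
        with np.errstate(invalid="ignore"):
            diff[ok] = np.abs(stat(va[ok], axis=1) - stat(vb[ok], axis=1))
    return pd.Series(diff, index=dataset.probe_ids, name=contrast.name)


def to_minimization(values) -> np.ndarray:
    """Negate nonnegative difference magnitudes so that the largest change
    becomes the smallest (best) criterion value.  Any strictly decreasing
    transform gives the same frontier; negation is the transparent choice."""
    values = np.asarray(values, dtype=np.float64)
    finite = values[np.isfinite(values)]
    if (finite < 0).any():
        raise ValueError("difference values must be nonnegative "
                         "(was the absolute value skipped?)")
    return -values


class ContrastCriteria(BaseEstimator, TransformerMixin):
    """Transformer from an :class:`ExpressionDataset` to a criteria matrix.

    One output column per contrast: the negated absolute group-statistic
    difference.  Genes lacking two usable values in any group of any
    contrast are dropped; their ids are recorded in ``excluded_ids_``.

    Attributes
    ----------
    criterion_names_ : list of str
    kept_mask_ : ndarray of bool, per input gene
    excluded_ids_ : list of probe ids dropped for insufficient data
    """

    def __init__(self, contrasts: Sequence[GroupContrast] = ()):
        self.contrasts = contrasts

    def fit(self, X: ExpressionDataset, y=None):
        contrasts = list(self.contrasts)
        if not 2 <= len(contrasts) <= MAX_CRITERIA:
            raise ValueError(
                f"between 2 and {MAX_CRITERIA} criteria are supported per "
                f"analysis, got {len(contrasts)}; split a larger meta-analysis "
                f"into runs of at most {MAX_CRITERIA} contrasts")
        names = [c.name for c in contrasts]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicated contrast names: {names}")
        diffs = pd.concat([group_stat_difference(X, c) for c in contrasts], axis=1)
        self.criterion_names_ = names
        self._columns = to_minimization(diffs.to_numpy())
        self.kept_mask_ = np.isfinite(self._columns).all(axis=1)
        ids = np.asarray(X.probe_ids, dtype=object)
        self.excluded_ids_ = list(ids[~self.kept_mask_])
        return self

    def transform(self, X: ExpressionDataset) -> np.ndarray:
        return self._columns[self.kept_mask_]


def build_criteria(dataset: ExpressionDataset,
                   contrasts: Sequence[GroupContrast]) -> tuple:
    """Build a named criteria table from 2-5 contrasts.

    Returns ``(CriteriaTable, excluded_ids)``: gene order is preserved from
    the dataset, and genes without enough usable values in some group are
    excluded and listed.
    """
    tr = ContrastCriteria(contrasts).fit(dataset)
    ids = np.asarray(dataset.probe_ids, dtype=object)[tr.kept_mask_]
    table = CriteriaTable(list(ids), tr.transform(dataset), tr.criterion_names_)
    return table, tr.excluded_ids_
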