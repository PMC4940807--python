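"""Pareto-efficient frontier computation via pairwise penalty matrices.

The central object is a criteria table: ``n`` alternatives (genes, probes)
scored on ``C`` criteria, every criterion in *minimization* sense.  An
alternative is Pareto-efficient (nondominated) when no other alternative is
at least as good on every criterion and strictly better on at least one.

The frontier is found by a full pairwise comparison scheme.  For each
criterion ``k`` a matrix ``delta^k`` is built whose entry ``(i, j)`` is

* ``-1``  if alternative ``i`` beats ``j`` on criterion ``k``,
* ``0``   on a tie,
* ``W``   (a large integer penalty, default 1000) if ``i`` loses to ``j``.

Summing the ``C`` delta matrices gives ``alpha``; entries of ``alpha`` that
are nonnegative multiples of ``W`` mark pairs where ``i`` is tied-or-worse on
every criterion.  Those entries are mapped to ``gamma`` values of ``(C/2)W``
(or ``CW`` when ``i`` loses on every criterion), everything else to 0.  The
row sums ``beta_i = sum_j gamma_ij`` then separate the frontier: alternative
``i`` is Pareto-efficient exactly when ``beta_i < C*W``.  Including the
self-comparison (``alpha_ii = 0``) every frontier member has
``beta_i = (C/2) W`` exactly.

``beta`` is accumulated row-chunk by row-chunk so memory stays ``O(chunk*n)``
even for tens of thousands of alternatives; a tournament mode that partitions
the table, pools local winners and re-runs on the pool is also provided and
yields the identical frontier for any partitioning.

All penalty arithmetic is exact: deltas and alphas are ``int64``, and gamma/
beta are carried internally in doubled integer units so that ``(C/2)W`` stays
an integer for odd ``C``.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

DEFAULT_PENALTY = 1000
#: criteria tables larger than this are processed in row chunks of at most
#: this many matrix elements (chunk_rows * n <= _CHUNK_ELEMS)
_CHUNK_ELEMS = 2**24


# ---------------------------------------------------------------------------
# containers


@dataclasses.dataclass
class CriteriaTable:
    """``n`` named alternatives scored on ``C`` criteria (minimization sense).

    Parameters
    ----------
    ids : sequence of str
        Unique alternative labels (gene or probe identifiers).
    values : ndarray of shape (n, C)
        ``values[i, k]`` is the score of alternative ``i`` on criterion ``k``;
        smaller is better on every criterion.  Must be finite.
    criterion_names : sequence of str
        One label per criterion.
    """

    ids: list
    values: np.ndarray
    criterion_names: list

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        self.criterion_names = [str(c) for c in self.criterion_names]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (alternatives x criteria)")
        n, c = self.values.shape
        if n < 1:
            raise ValueError("criteria table must contain at least one alternative")
        if c < 2:
            raise ValueError("at least two criteria are required")
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} rows")
        if len(self.criterion_names) != c:
            raise ValueError(f"{len(self.criterion_names)} names for {c} criteria")
        if len(set(self.ids)) != n:
            raise ValueError("alternative ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("criteria values must be finite (no NaN/inf)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_criteria(self) -> int:
        return self.values.shape[1]

    def subset(self, indices) -> "CriteriaTable":
        indices = np.asarray(indices)
        return CriteriaTable(
            [self.ids[i] for i in indices],
            self.values[indices],
            list(self.criterion_names),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"),
                            columns=self.criterion_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CriteriaTable":
        return cls(list(df.index), df.to_numpy(dtype=np.float64), list(df.columns))

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "CriteriaTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls.from_dataframe(df)


@dataclasses.dataclass
class DominanceWork:
    """Intermediate matrices of one frontier computation (small n only)."""

    W: int
    alpha: np.ndarray   # (n, n) int64
    gamma: np.ndarray   # (n, n) float64, exact multiples of W/2
    beta: np.ndarray    # (n,) float64


@dataclasses.dataclass
class FrontierResult:
    """Identities of Pareto-efficient alternatives plus diagnostics.

    ``beta`` maps every alternative *present in this layer's comparison set*
    to its penalty row sum; frontier members always have
    ``beta == (C/2) * W``.  ``layer`` 0 is the first (global) frontier.
    """

    frontier_ids: list
    beta: Optional[pd.Series]
    layer: int = 0
    duplicate_groups: list = dataclasses.field(default_factory=list)

    def __contains__(self, item) -> bool:
        return item in set(self.frontier_ids)

    def __len__(self) -> int:
        return len(self.frontier_ids)


# ---------------------------------------------------------------------------
# elementary penalty-matrix operations (full matrices; pedagogical / small n)


def build_delta(criteria: CriteriaTable, k: int, W: int = DEFAULT_PENALTY) -> np.ndarray:
    """Pairwise comparison matrix for criterion ``k`` (0-based).

    Entry ``(i, j)`` is ``-1`` if ``m_i^k < m_j^k``, ``0`` on equality and
    ``W`` if ``m_i^k > m_j^k``, so a penalty marks the *losing* side of each
    pair and the diagonal is zero.
    """
    if not 0 <= k < criteria.n_criteria:
        raise IndexError(f"criterion index {k} out of range [0, {criteria.n_criteria})")
    _check_penalty(W, criteria.n_criteria)
    col = criteria.values[:, k]
    left, right = col[:, None], col[None, :]
    delta = np.zeros((criteria.n, criteria.n), dtype=np.int64)
    delta[left < right] = -1
    delta[left > right] = W
    return delta


def accumulate_alpha(deltas: Sequence[np.ndarray]) -> np.ndarray:
    """Sum the per-criterion delta matrices into ``alpha``."""
    deltas = list(deltas)
    if not deltas:
        raise ValueError("need at least one delta matrix")
    shape = deltas[0].shape
    for d in deltas:
        if d.shape != shape:
            raise ValueError("delta matrices differ in shape")
    alpha = np.zeros(shape, dtype=np.int64)
    for d in deltas:
        alpha += d.astype(np.int64)
    return alpha


def assess_gamma(alpha: np.ndarray, C: int, W: int = DEFAULT_PENALTY) -> np.ndarray:
    """Map ``alpha`` to ``gamma``: ``(C/2)W`` where alternative ``i`` is
    tied-or-worse than ``j`` on every criterion (``alpha`` a multiple of ``W``
    in ``{0, W, ..., (C-1)W}``), ``CW`` where it is worse on every criterion
    (``alpha == CW``), and 0 otherwise."""
    _check_penalty(W, C)
    alpha = np.asarray(alpha, dtype=np.int64)
    # every alpha entry must decompose as p*W - q with p penalty counts and
    # q win counts, each at most C; anything else signals corruption
    q = (-alpha) % W
    p = (alpha + q) // W
    ok = (q <= C) & (p >= 0) & (p <= C)
    if not ok.all():
        bad = alpha[~ok].ravel()[0]
        raise ValueError(f"alpha value {bad} not producible from delta entries")
    gamma2 = np.zeros_like(alpha)
    mult = (alpha >= 0) & (alpha <= (C - 1) * W) & (alpha % W == 0)
    gamma2[mult] = C * W
    gamma2[alpha == C * W] = 2 * C * W
    return gamma2 / 2.0


def beta_sums(gamma: np.ndarray) -> np.ndarray:
    """Row sums of ``gamma`` (the diagonal self-term included)."""
    gamma = np.asarray(gamma)
    if gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
        raise ValueError("gamma must be square")
    return gamma.sum(axis=1)


def dominance_work(criteria: CriteriaTable, W: int = DEFAULT_PENALTY) -> DominanceWork:
    """Materialize the full alpha/gamma/beta pipeline (small tables only)."""
    deltas = [build_delta(criteria, k, W) for k in range(criteria.n_criteria)]
    alpha = accumulate_alpha(deltas)
    gamma = assess_gamma(alpha, criteria.n_criteria, W)
    return DominanceWork(W=W, alpha=alpha, gamma=gamma, beta=beta_sums(gamma))


# ---------------------------------------------------------------------------
# chunked production path


def _check_penalty(W, C: int) -> int:
    W = int(W)
    if W <= C:
        raise ValueError(
            f"penalty W={W} must exceed the criteria count C={C}; otherwise "
            f"mixed win/loss alpha values can collide with multiples of W")
    return W


def _beta2(values: np.ndarray, W: int, tol: float = 0.0,
           rows: Optional[np.ndarray] = None) -> np.ndarray:
    """Doubled beta vector (int64) for ``values`` rows vs all rows.

    ``rows`` restricts which row indices beta is computed for (all by
    default); comparisons always run against the full set.  Row-chunked so
    peak memory is O(chunk * n).
    """
    n, C = values.shape
    CW = C * W
    if rows is None:
        rows = np.arange(n)
    out = np.empty(len(rows), dtype=np.int64)
    chunk = max(1, _CHUNK_ELEMS // max(n, 1))
    for s in range(0, len(rows), chunk):
        idx = rows[s:s + chunk]
        alpha = np.zeros((len(idx), n), dtype=np.int64)
        for k in range(C):
            col = values[:, k]
            left = col[idx][:, None]
            right = col[None, :]
            if tol > 0:
                alpha -= (left < right - tol).astype(np.int64)
                alpha += (left > right + tol).astype(np.int64) * W
            else:
                alpha -= (left < right).astype(np.int64)
                alpha += (left > right).astype(np.int64) * W
        gamma2 = np.zeros_like(alpha)
        gamma2[(alpha >= 0) & (alpha <= (C - 1) * W) & (alpha % W == 0)] = CW
        gamma2[alpha == CW] = 2 * CW
        out[s:s + chunk] = gamma2.sum(axis=1)
    return out


def _tournament_beta2(values: np.ndarray, W: int, partition_size: int,
                      tol: float = 0.0) -> tuple:
    """Frontier mask and doubled-beta vector via tournament partitioning.

    The table is split into consecutive blocks, local frontiers are pooled
    and the frontier of the pool is the global frontier.  The returned beta
    entries are relative to each row's last comparison set (its block for
    eliminated rows, the pool for local winners); frontier membership is
    identical to the direct computation.
    """
    n, C = values.shape
    threshold2 = 2 * C * W
    beta2 = np.empty(n, dtype=np.int64)
    pool = []
    for s in range(0, n, partition_size):
        idx = np.arange(s, min(s + partition_size, n))
        local = _beta2(values[idx], W, tol)
        beta2[idx] = local
        pool.append(idx[local < threshold2])
    pool = np.concatenate(pool)
    final = _beta2(values[pool], W, tol)
    beta2[pool] = final
    mask = np.zeros(n, dtype=bool)
    mask[pool[final < threshold2]] = True
    return mask, beta2


def _duplicate_groups(values: np.ndarray):
    """Row indices grouped by exactly identical criteria vectors."""
    _, inverse, counts = np.unique(values, axis=0, return_inverse=True,
                                   return_counts=True)
    groups = []
    for u in np.flatnonzero(counts >= 2):
        groups.append(np.flatnonzero(inverse == u))
    return groups, inverse


# ---------------------------------------------------------------------------
# estimator


class ParetoFrontierFinder(BaseEstimator):
    """Find Pareto-efficient alternatives of a criteria matrix.

    Fit on ``X`` of shape ``(n_alternatives, n_criteria)`` with every column
    in minimization sense.  After fitting, ``frontier_mask_`` flags the
    nondominated rows (the first frontier), ``layers_`` assigns consecutive
    peeled frontier layers, and ``beta_`` holds the penalty row sums whose
    comparison against ``threshold_ = C * penalty`` defines membership.

    Parameters
    ----------
    penalty : int, default 1000
        The penalty constant ``W``; must exceed the criteria count.
    n_layers : int, default 1
        Number of consecutive frontiers to peel.  Layer 0 is the frontier of
        the full table; layer ``l`` is the frontier after removing all
        earlier layers.  Peeling mitigates false negatives from experimental
        error: a gene nudged off the first frontier by noise surfaces on the
        next one.
    partition_size : int or None, default None
        If set, compute each frontier in tournament fashion with consecutive
        blocks of at most this size.  Membership is invariant to the
        partitioning; ``None`` uses the direct (row-chunked) computation.
    collapse_duplicates : bool, default True
        Alternatives with exactly identical criteria vectors cannot strictly
        dominate one another under classical Pareto conditions, yet the raw
        penalty scheme pushes each of them past the threshold.  When True
        (default), exact duplicates are collapsed to one representative
        before the computation and all members are restored in the output,
        so nondominated duplicates stay on the frontier.  When False the raw
        scheme is applied verbatim and whole duplicate groups drop off the
        frontier.  Duplicate groups are reported either way.
    tol : float, default 0.0
        Optional tie tolerance: values within ``tol`` of each other count as
        equal on a criterion.  Off by default (exact comparison of raw
        values).

    Attributes
    ----------
    n_criteria_ : int
    threshold_ : int
        The membership cutoff ``C * penalty`` applied to ``beta_``.
    beta_ : ndarray of shape (n,)
        Layer-0 penalty row sums; frontier members have exactly
        ``threshold_ / 2``.
    frontier_mask_ : ndarray of bool, shape (n,)
        True for rows on the first frontier.
    layers_ : ndarray of int, shape (n,)
        Peeled layer index per row; ``-1`` for rows not reached within
        ``n_layers``.
    duplicate_groups_ : list of ndarray
        Row-index groups with identical criteria vectors (full table).

    Examples
    --------
    >>> import numpy as np
    >>> X = np.array([[1, 4], [3, 4], [5, 6], [7, 5], [3, 2], [4, 1]])
    >>> finder = ParetoFrontierFinder().fit(X)
    >>> np.flatnonzero(finder.frontier_mask_)
    array([0, 4, 5])
    >>> finder.threshold_
    2000
    """

    def __init__(self, penalty: int = DEFAULT_PENALTY, n_layers: int = 1,
                 partition_size: Optional[int] = None,
                 collapse_duplicates: bool = True, tol: float = 0.0):
        self.penalty = penalty
        self.n_layers = n_layers
        self.partition_size = partition_size
        self.collapse_duplicates = collapse_duplicates
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (alternatives x criteria)")
        n, C = X.shape
        if n < 1:
            raise ValueError("empty criteria table")
        if C < 2:
            raise ValueError("at least two criteria are required")
        if not np.isfinite(X).all():
            raise ValueError("criteria values must be finite")
        W = _check_penalty(self.penalty, C)
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.partition_size is not None and self.partition_size < 2:
            raise ValueError("partition_size must be >= 2")

        self.n_criteria_ = C
        self.threshold_ = C * W
        self.duplicate_groups_, _ = _duplicate_groups(X)

        layers = np.full(n, -1, dtype=np.int64)
        beta0 = None
        remaining = np.arange(n)
        for layer in range(self.n_layers):
            if remaining.size == 0:
                break
            mask, beta2 = self._layer_frontier(X[remaining], W)
            if layer == 0:
                beta0 = beta2
            layers[remaining[mask]] = layer
            remaining = remaining[~mask]
        self.layers_ = layers
        self.beta_ = beta0 / 2.0
        self.frontier_mask_ = layers == 0
        return self

    def _layer_frontier(self, values: np.ndarray, W: int):
        """Frontier mask + doubled beta for one comparison set."""
        threshold2 = 2 * values.shape[1] * W
        if self.collapse_duplicates:
            uniq, inverse = np.unique(values, axis=0, return_inverse=True)
            if len(uniq) < len(values):
                umask, ubeta2 = self._raw_frontier(uniq, W, threshold2)
                return umask[inverse], ubeta2[inverse]
        return self._raw_frontier(values, W, threshold2)

    def _raw_frontier(self, values: np.ndarray, W: int, threshold2: int):
        if self.partition_size is not None and len(values) > self.partition_size:
            return _tournament_beta2(values, W, int(self.partition_size), self.tol)
        beta2 = _beta2(values, W, self.tol)
        return beta2 < threshold2, beta2

    def get_support(self, indices: bool = False):
        """Indices (or boolean mask) of first-frontier rows."""
        mask = self.frontier_mask_
        return np.flatnonzero(mask) if indices else mask


# ---------------------------------------------------------------------------
# functional wrappers on named criteria tables


def _result_from_mask(criteria: CriteriaTable, mask, beta, layer,
                      dup_groups) -> FrontierResult:
    ids = np.asarray(criteria.ids, dtype=object)
    groups = [list(ids[g]) for g in dup_groups]
    return FrontierResult(
        frontier_ids=list(ids[mask]),
        beta=pd.Series(beta, index=criteria.ids, name="beta"),
        layer=layer,
        duplicate_groups=groups,
    )


def layered_results(finder: "ParetoFrontierFinder",
                    criteria: CriteriaTable) -> list:
    """FrontierResult per peeled layer of a fitted finder.

    Layer 0 carries the beta vector and duplicate groups; deeper layers
    report membership only (their betas refer to shrinking comparison sets).
    """
    ids = np.asarray(criteria.ids, dtype=object)
    results = []
    n_found = finder.layers_.max() + 1 if len(finder.layers_) else 0
    for layer in range(max(n_found, 1)):
        mask = finder.layers_ == layer
        if layer > 0 and not mask.any():
            break
        results.append(FrontierResult(
            frontier_ids=list(ids[mask]),
            beta=(pd.Series(finder.beta_, index=criteria.ids, name="beta")
                  if layer == 0 else None),
            layer=layer,
            duplicate_groups=([list(ids[g]) for g in finder.duplicate_groups_]
                              if layer == 0 else []),
        ))
    return results


def pareto_frontier(criteria: CriteriaTable, W: int = DEFAULT_PENALTY,
                    collapse_duplicates: bool = True,
                    tol: float = 0.0) -> FrontierResult:
    """The Pareto-efficient frontier of a criteria table.

    Returns the alternatives whose penalty row sum ``beta`` falls below the
    cutoff ``C*W`` — exactly the nondominated set.
    """
    finder = ParetoFrontierFinder(penalty=W, collapse_duplicates=collapse_duplicates,
                                  tol=tol).fit(criteria.values)
    return _result_from_mask(criteria, finder.frontier_mask_, finder.beta_, 0,
                             finder.duplicate_groups_)


def brute_force_frontier(criteria: CriteriaTable) -> FrontierResult:
    """Nondominated set by literal application of the dominance conditions.

    Alternative ``j`` dominates ``i`` when ``j`` is no worse on every
    criterion and strictly better on at least one.  Identical vectors do not
    dominate each other and are all retained.  Independent of the penalty
    scheme; used as a cross-check oracle.
    """
    vals = criteria.values
    n = vals.shape[0]
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        no_worse = (vals <= vals[i]).all(axis=1)
        better = (vals < vals[i]).any(axis=1)
        if (no_worse & better).any():
            mask[i] = False
    dup_groups, _ = _duplicate_groups(vals)
    ids = np.asarray(criteria.ids, dtype=object)
    return FrontierResult(
        frontier_ids=list(ids[mask]),
        beta=None,
        layer=0,
        duplicate_groups=[list(ids[g]) for g in dup_groups],
    )


def tournament_frontier(criteria: CriteriaTable, partition_size: int,
                        W: int = DEFAULT_PENALTY,
                        collapse_duplicates: bool = True) -> FrontierResult:
    """Frontier via consecutive-block tournament; equals the direct result.

    Blocks of at most ``partition_size`` alternatives are solved locally,
    local winners are pooled, and the frontier of the pool is returned.
    Membership does not depend on the partitioning or input order.
    """
    if partition_size < 2:
        raise ValueError("partition_size must be >= 2")
    finder = ParetoFrontierFinder(penalty=W, partition_size=partition_size,
                                  collapse_duplicates=collapse_duplicates)
    finder.fit(criteria.values)
    return _result_from_mask(criteria, finder.frontier_mask_, finder.beta_, 0,
                             finder.duplicate_groups_)


def peel_frontiers(criteria: CriteriaTable, layers: int,
                   W: int = DEFAULT_PENALTY,
                   collapse_duplicates: bool = True) -> list:
    """Consecutive frontier layers: layer 0 is the frontier of the full
    table, layer ``l`` the frontier after removing all earlier layers.
    Stops early once no alternatives remain."""
    if layers < 1:
        raise ValueError("layers must be >= 1")
    results = []
    current = criteria
    for layer in range(layers):
        if current is None or current.n == 0:
            break
        finder = ParetoFrontierFinder(penalty=W,
                                      collapse_duplicates=collapse_duplicates)
        finder.fit(current.values)
        results.append(_result_from_mask(current, finder.frontier_mask_,
                                         finder.beta_, layer,
                                         finder.duplicate_groups_))
        keep = np.flatnonzero(~finder.frontier_mask_)
        current = current.subset(keep) if keep.size else None
    return results
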