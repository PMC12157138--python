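"""Gaussian-copula mutual information and conditional-independence testing.

The estimator rank-transforms each marginal to standard-normal scores
(the Gaussian copula), then measures dependence through covariance
determinants:

    I(X; Y) = 1/2 * log( |R_X| * |R_Y| / |R_XY| )    [nats]

Because only ranks enter, the estimate is exactly invariant under
strictly increasing marginal transforms, and it captures monotone
nonlinear dependence that plain correlation misses.  Conditioning is
handled through the Gaussian identity I(X;Y|Z) = I(X;YZ) - I(X;Z), and
the conditional-independence decision refers the likelihood-ratio
statistic 2n*CMI to a chi-square with one degree of freedom (both X and
Y univariate), with an optional permutation fallback for small samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.special import ndtri

from .exceptions import DegenerateInput, InsufficientData, InvalidInput

__all__ = [
    "copula_transform",
    "gcmi",
    "conditional_gcmi",
    "ci_test",
    "CITestResult",
    "MICache",
    "TableScores",
]

#: minimum samples for the raw MI estimator
_MIN_N = 10


def copula_transform(x: Sequence[float]) -> np.ndarray:
    """Map a sample to standard-normal scores via its empirical ranks.

    z_i = Phi^{-1}( rank(x_i) / (n + 1) ), ties receiving average ranks.
    The output preserves the rank order of the input exactly.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise InvalidInput(f"need at least 3 samples, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInput("constant vector has a degenerate marginal")
    r = stats.rankdata(x, method="average")
    return ndtri(r / (x.size + 1))


def _score_matrix(a: np.ndarray) -> np.ndarray:
    """Column-wise copula transform of a 1-D or 2-D array -> (n, d)."""
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return np.column_stack([copula_transform(a[:, j]) for j in range(a.shape[1])])


def _logdet(c: np.ndarray) -> float:
    c = np.atleast_2d(c)
    sign, ld = np.linalg.slogdet(c)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-positive-definite covariance")
    return ld


def gcmi(x: Sequence[float], y: Sequence[float]) -> float:
    """Gaussian-copula mutual information between X and Y in nats.

    ``x`` and ``y`` may be 1-D vectors or (n, d) blocks; marginals are
    transformed per column.  Symmetric in its arguments; >= 0 up to
    numerical tolerance.  A singular joint covariance (e.g. a duplicated
    variable) yields ``inf`` with a warning.
    """
    zx = _score_matrix(np.asarray(x, dtype=float))
    zy = _score_matrix(np.asarray(y, dtype=float))
    if zx.shape[0] != zy.shape[0]:
        raise InvalidInput("x and y must have equal sample sizes")
    if zx.shape[0] < _MIN_N:
        raise InsufficientData(f"need n >= {_MIN_N} samples, got {zx.shape[0]}")
    z = np.hstack([zx, zy])
    c = np.cov(z, rowvar=False)
    dx = zx.shape[1]
    try:
        return 0.5 * (_logdet(c[:dx, :dx]) + _logdet(c[dx:, dx:]) - _logdet(c))
    except np.linalg.LinAlgError:
        warnings.warn("singular joint covariance; returning inf sentinel")
        return float("inf")


def conditional_gcmi(
    x: Sequence[float], y: Sequence[float], z: Sequence[float] | None = None
) -> float:
    """I(X; Y | Z) via the Gaussian identity I(X;YZ) - I(X;Z).

    With ``z`` empty or None this reduces exactly to :func:`gcmi`.
    """
    if z is None:
        return gcmi(x, y)
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[1] == 0:
        return gcmi(x, y)
    zy = np.asarray(y, dtype=float)
    if zy.ndim == 1:
        zy = zy[:, None]
    return gcmi(x, np.hstack([zy, z])) - gcmi(x, z)


@dataclass(frozen=True)
class CITestResult:
    statistic: float
    p_value: float
    independent: bool
    n: int
    df: int = 1


def ci_test(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float] | None = None,
    alpha: float = 0.05,
    method: str = "chi2",
    n_perm: int = 500,
    rng: np.random.Generator | None = None,
) -> CITestResult:
    """Conditional-independence test based on the copula-MI likelihood ratio.

    The statistic 2n * I(X;Y|Z) is referred to chi-square(1); with
    ``method="permutation"`` a permutation null (permuting x) replaces
    the parametric reference, which is preferable for n < 100.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    n_cond = 0
    if z is not None:
        za = np.asarray(z, dtype=float)
        n_cond = 1 if za.ndim == 1 else za.shape[1]
        if n_cond == 0:
            z = None
    if n < 10 * (n_cond + 2):
        raise InsufficientData(
            f"n={n} unreliable for a CI test with {n_cond} conditioning variables"
        )
    try:
        cmi = conditional_gcmi(x, y, z)
    except DegenerateInput:
        # constant marginals are declared independent of everything
        return CITestResult(0.0, 1.0, True, n)
    stat = 2.0 * n * max(cmi, 0.0)
    if method == "chi2":
        p = float(stats.chi2.sf(stat, df=1))
    elif method == "permutation":
        rng = rng if rng is not None else np.random.default_rng(0)
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = max(conditional_gcmi(rng.permutation(x), y, z), 0.0)
        p = float((np.sum(2.0 * n * null >= stat) + 1) / (n_perm + 1))
    else:
        raise InvalidInput(f"unknown CI test method {method!r}")
    return CITestResult(float(stat), p, p >= alpha, n)


class TableScores:
    """Pre-computed copula scores and covariance for one feature table.

    Rank-transforming every column once and caching the full score
    covariance makes each subsequent (conditional) MI a small-matrix
    determinant, which is what keeps blanket discovery tractable.
    Constant columns are flagged degenerate and treated as independent
    of everything.
    """

    def __init__(self, data, columns: Sequence[str] | None = None):
        if hasattr(data, "columns"):  # DataFrame
            columns = list(columns) if columns is not None else list(data.columns)
            mat = np.asarray(data[columns], dtype=float)
        else:
            mat = np.asarray(data, dtype=float)
            if columns is None:
                columns = [str(j) for j in range(mat.shape[1])]
        self.columns = list(columns)
        self.index = {c: j for j, c in enumerate(self.columns)}
        self.n = mat.shape[0]
        z = np.zeros_like(mat)
        self.degenerate: set[str] = set()
        for j, name in enumerate(self.columns):
            col = mat[:, j]
            if np.ptp(col) == 0 or not np.all(np.isfinite(col)):
                self.degenerate.add(name)
            else:
                z[:, j] = copula_transform(col)
        self.cov = np.cov(z, rowvar=False) if len(self.columns) > 1 else np.atleast_2d(np.var(z, ddof=1))

    def _idx(self, names: Sequence[str]) -> list[int]:
        return [self.index[c] for c in names]

    def _ld(self, idx: Sequence[int]) -> float:
        if not idx:
            return 0.0
        sub = self.cov[np.ix_(idx, idx)]
        return _logdet(sub)

    def mi(self, a: str, b: str) -> float:
        """I(a; b) in nats."""
        if a in self.degenerate or b in self.degenerate:
            return 0.0
        ia, ib = self.index[a], self.index[b]
        try:
            return 0.5 * (self._ld([ia]) + self._ld([ib]) - self._ld([ia, ib]))
        except np.linalg.LinAlgError:
            return float("inf")

    def cmi(self, a: str, b: str, cond: Sequence[str] = ()) -> float:
        """I(a; b | cond) in nats."""
        cond = [c for c in cond if c not in self.degenerate]
        if a in self.degenerate or b in self.degenerate:
            return 0.0
        if not cond:
            return self.mi(a, b)
        ia, ib = self.index[a], self.index[b]
        ic = self._idx(cond)
        try:
            return 0.5 * (
                self._ld([ib] + ic)
                - self._ld([ia, ib] + ic)
                - self._ld(ic)
                + self._ld([ia] + ic)
            )
        except np.linalg.LinAlgError:
            return float("inf")

    def ci_test(self, a: str, b: str, cond: Sequence[str] = (), alpha: float = 0.05) -> CITestResult:
        if a in self.degenerate or b in self.degenerate:
            return CITestResult(0.0, 1.0, True, self.n)
        stat = 2.0 * self.n * max(self.cmi(a, b, cond), 0.0)
        p = float(stats.chi2.sf(stat, df=1))
        return CITestResult(float(stat), p, p >= alpha, self.n)


class MICache:
    """Cache of (dataset_id, feature) -> MI-with-target values in nats.

    Values are whatever the supplied compute function returns; the cache
    is transparent (a cached value equals fresh recomputation on the
    same data) and serializable for audit trails.
    """

    def __init__(self) -> None:
        self._store: dict[tuple[str, str], float] = {}

    def get_or_compute(self, dataset_id: str, feature: str, fn: Callable[[], float]) -> float:
        key = (dataset_id, feature)
        if key not in self._store:
            self._store[key] = float(fn())
        return self._store[key]

    def get(self, dataset_id: str, feature: str) -> float:
        return self._store[(dataset_id, feature)]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._store

    def __len__(self) -> int:
        return len(self._store)

    def to_json(self) -> str:
        return json.dumps(
            {f"{d}::{f}": v for (d, f), v in sorted(self._store.items())}, sort_keys=True
        )

    @classmethod
    def from_json(cls, text: str) -> "MICache":
        cache = cls()
        for key, v in json.loads(text).items():
            d, f = key.split("::", 1)
            cache._store[(d, f)] = float(v)
        return cache
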