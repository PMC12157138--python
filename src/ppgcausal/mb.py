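"""Per-dataset Markov-blanket discovery.

Two complementary engines are provided:

* HITON-MB — constraint-based local structure learning.  Parents and
  children of the target are found by interleaved forward inclusion
  (candidates ranked by copula MI with the target) and backward
  elimination through conditional-independence tests over subsets of
  the current parent/children estimate; spouses are then recovered by
  testing each parent/child's own neighbours against the target given
  the recorded separating set plus the common child.  Suits larger
  samples.

* PPFS — predictive-permutation feature selection.  A feature joins the
  blanket estimate if, across k cross-validation folds, permuting its
  held-out column significantly degrades a k-NN regressor's loss given
  the features already selected (one-sided paired t-test); a shrink
  phase re-tests every selected feature given the rest.  Suits small
  samples and distributions where faithfulness is shaky.

Both operate on continuous targets (blood pressure) and are
deterministic for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor

from .exceptions import ConfigurationError, InsufficientData
from .gcmi import TableScores

__all__ = ["MarkovBlanket", "hiton_pc", "hiton_mb", "ppfs_mb", "META_COLUMNS"]

#: columns of a feature table that are never candidate features
META_COLUMNS = ("subject_id", "dataset")


@dataclass(frozen=True)
class MarkovBlanket:
    features: frozenset[str]
    algorithm: str
    dataset_id: str
    alpha: float

    def to_dict(self) -> dict:
        return {
            "dataset_id": self.dataset_id,
            "algorithm": self.algorithm,
            "alpha": self.alpha,
            "features": sorted(self.features),
        }


def _feature_columns(table: pd.DataFrame, target: str) -> list[str]:
    return sorted(c for c in table.columns if c != target and c not in META_COLUMNS)


def _scores_for(table: pd.DataFrame, target: str) -> TableScores:
    cols = _feature_columns(table, target) + [target]
    return TableScores(table, cols)


def _ranked(scores: TableScores, target: str, candidates: list[str]) -> list[str]:
    # descending MI with the target; ties broken lexicographically by name
    return sorted(candidates, key=lambda f: (-scores.mi(f, target), f))


def _find_sepset(
    scores: TableScores,
    x: str,
    target: str,
    context: list[str],
    alpha: float,
    max_cond: int,
) -> tuple[bool, tuple[str, ...] | None]:
    """Search subsets of ``context`` (size 0..max_cond) separating x from target."""
    pool = [c for c in context if c != x]
    for size in range(0, min(max_cond, len(pool)) + 1):
        for sub in itertools.combinations(pool, size):
            if scores.ci_test(x, target, sub, alpha).independent:
                return True, sub
    return False, None


def hiton_pc(
    table: pd.DataFrame,
    target: str,
    alpha: float = 0.05,
    max_cond: int = 3,
    scores: TableScores | None = None,
) -> tuple[list[str], dict[str, tuple[str, ...]]]:
    """Parents/children estimate of ``target`` with separating sets.

    Returns the PC set (in admission order) and, for every rejected
    candidate, the subset of the PC estimate that separated it from the
    target (used later for spouse recovery).
    """
    candidates = _feature_columns(table, target)
    if len(candidates) < 2:
        raise InsufficientData("need at least 2 candidate features")
    if len(table) < 50:
        raise InsufficientData("HITON requires n >= 50")
    if scores is None:
        scores = _scores_for(table, target)
    pc: list[str] = []
    sepsets: dict[str, tuple[str, ...]] = {}
    for cand in _ranked(scores, target, candidates):
        independent, sep = _find_sepset(scores, cand, target, pc, alpha, max_cond)
        if independent:
            sepsets[cand] = sep
            continue
        pc.append(cand)
        # interleaved backward elimination over the existing members
        for member in pc[:-1]:
            independent, sep = _find_sepset(scores, member, target, pc, alpha, max_cond)
            if independent:
                pc.remove(member)
                sepsets[member] = sep
    return pc, sepsets


def hiton_mb(
    table: pd.DataFrame,
    target: str,
    alpha: float = 0.05,
    max_cond: int = 3,
    dataset_id: str = "dataset",
    scores: TableScores | None = None,
) -> MarkovBlanket:
    """HITON Markov blanket: PC(target) plus recovered spouses.

    Y is admitted as a spouse iff Y is in PC(X) for some X in
    PC(target), Y is not itself in PC(target), and Y remains dependent
    on the target given its separating set augmented with X (the
    collider check).
    """
    if scores is None:
        scores = _scores_for(table, target)
    pc, sepsets = hiton_pc(table, target, alpha, max_cond, scores=scores)
    mb = set(pc)
    for x in pc:
        pc_x, _ = hiton_pc(table, x, alpha, max_cond, scores=scores)
        for y in pc_x:
            if y == target or y in mb:
                continue
            sep = sepsets.get(y, ())
            cond = tuple(dict.fromkeys(sep + (x,)))
            if not scores.ci_test(y, target, cond, alpha).independent:
                mb.add(y)
    return MarkovBlanket(frozenset(mb), "HITON", dataset_id, alpha)


def _fold_losses(
    xmat: np.ndarray,
    y: np.ndarray,
    feat_col: int,
    folds: list[tuple[np.ndarray, np.ndarray]],
    perm_seeds: list[np.random.Generator],
    n_neighbors: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold test MSE with the candidate column intact vs permuted."""
    orig = np.empty(len(folds))
    perm = np.empty(len(folds))
    for f, (tr, te) in enumerate(folds):
        mu = xmat[tr].mean(axis=0)
        sd = xmat[tr].std(axis=0)
        sd[sd == 0] = 1.0
        xtr = (xmat[tr] - mu) / sd
        xte = (xmat[te] - mu) / sd
        model = KNeighborsRegressor(n_neighbors=min(n_neighbors, len(tr)))
        model.fit(xtr, y[tr])
        orig[f] = float(np.mean((model.predict(xte) - y[te]) ** 2))
        xte_p = xte.copy()
        xte_p[:, feat_col] = perm_seeds[f].permutation(xte_p[:, feat_col])
        perm[f] = float(np.mean((model.predict(xte_p) - y[te]) ** 2))
    return orig, perm


def _perm_test_accepts(
    table_vals: dict[str, np.ndarray],
    y: np.ndarray,
    feature: str,
    context: list[str],
    folds: list[tuple[np.ndarray, np.ndarray]],
    alpha: float,
    seed: int,
    feat_rank: dict[str, int],
    n_neighbors: int = 5,
) -> bool:
    """One-sided paired t-test: does permuting ``feature`` raise the loss?"""
    cols = context + [feature]
    xmat = np.column_stack([table_vals[c] for c in cols])
    gens = [
        np.random.default_rng(
            np.random.SeedSequence([seed, feat_rank[feature], f])
        )
        for f in range(len(folds))
    ]
    orig, perm = _fold_losses(xmat, y, len(cols) - 1, folds, gens, n_neighbors)
    diffs = perm - orig
    if np.allclose(diffs, 0.0):
        return False
    t = stats.ttest_rel(perm, orig, alternative="greater")
    p = float(t.pvalue)
    return bool(np.isfinite(p) and p < alpha)


def ppfs_mb(
    table: pd.DataFrame,
    target: str,
    alpha: float = 0.05,
    k_folds: int = 5,
    seed: int = 0,
    dataset_id: str = "dataset",
    max_features: int | None = None,
) -> MarkovBlanket:
    """Predictive-permutation Markov-blanket discovery.

    Growth: candidates (ordered by copula MI with the target) are
    admitted when the permutation test accepts them given the features
    selected so far.  Shrink: each selected feature is re-tested given
    the rest and dropped when it no longer contributes.  The internal
    predictor is a 5-nearest-neighbour regressor on standardized
    features with mean-squared-error loss.
    """
    n = len(table)
    if n < 30:
        raise InsufficientData("PPFS requires n >= 30")
    if k_folds < 2 or n < 2 * k_folds:
        raise ConfigurationError(f"cannot build {k_folds} folds from {n} rows")
    candidates = _feature_columns(table, target)
    scores = _scores_for(table, target)
    order = _ranked(scores, target, candidates)
    feat_rank = {f: i for i, f in enumerate(sorted(candidates))}
    y = np.asarray(table[target], dtype=float)
    vals = {c: np.asarray(table[c], dtype=float) for c in candidates}
    splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed % (2**32))
    folds = [(tr, te) for tr, te in splitter.split(np.arange(n))]

    selected: list[str] = []
    for cand in order:
        if max_features is not None and len(selected) >= max_features:
            break
        if _perm_test_accepts(vals, y, cand, selected, folds, alpha, seed, feat_rank):
            selected.append(cand)
    # shrink phase
    for feat in list(selected):
        rest = [f for f in selected if f != feat]
        if not rest:
            continue
        if not _perm_test_accepts(vals, y, feat, rest, folds, alpha, seed, feat_rank):
            selected.remove(feat)
    return MarkovBlanket(frozenset(selected), "PPFS", dataset_id, alpha)
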