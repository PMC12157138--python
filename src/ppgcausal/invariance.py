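"""Multi-source causally-invariant feature selection.

Given K feature tables over one shared namespace and a continuous
target (SBP or DBP), the selector proceeds in three steps:

1. **Blanket bounds.**  Per dataset, an ensemble Markov blanket is the
   union of the HITON-MB and PPFS estimates.  Across datasets,
   ``maxMB`` is the union of the ensemble blankets, ``minMB`` their
   intersection, and ``supMB = maxMB - minMB`` the disputed features
   whose cross-dataset stability must be adjudicated.

2. **Importance ranking.**  Every disputed feature is ranked by its
   average mutual information (AMI) with the target — Gaussian-copula
   MI per dataset, averaged over the K datasets, served from a cache.

3. **Invariant-set search.**  Candidate subsets of the ranked disputed
   features are enumerated (largest size first by default, prefix-
   biased toward high-AMI features).  A subset S passes when, for every
   dataset i, a one-sample t-test cannot distinguish the profile
   {MI(f; target | D_i) : f in S} from the grand AMI(S); the first
   passing subset is kept.

The final selection is ``minMB`` (features every dataset agrees on)
united with the invariant subset.  Baselines (per-engine union/
intersection, tree-importance) and Kendall ranking-consistency
diagnostics are provided for comparison.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .exceptions import ConfigurationError, DegenerateInput, InvalidInput
from .gcmi import MICache, TableScores
from .mb import META_COLUMNS, MarkovBlanket, hiton_mb, ppfs_mb

__all__ = [
    "MultiSourceStudy",
    "InvariantSelection",
    "ensemble_mb",
    "blanket_bounds",
    "rank_by_ami",
    "invariance_test",
    "find_invariant_set",
    "select",
    "baseline_select",
    "combine_blankets",
    "tree_importance_select",
    "ranking_consistency",
]


@dataclass
class MultiSourceStudy:
    """K feature tables sharing one feature namespace and target."""

    datasets: dict[str, pd.DataFrame]
    target: str

    def __post_init__(self) -> None:
        if len(self.datasets) < 2:
            raise ConfigurationError("a multi-source study needs K >= 2 datasets")
        namespaces = {
            ds: frozenset(c for c in df.columns if c not in META_COLUMNS)
            for ds, df in self.datasets.items()
        }
        ref = next(iter(namespaces.values()))
        if any(ns != ref for ns in namespaces.values()):
            raise ConfigurationError("datasets must share one feature namespace")
        if self.target not in ref:
            raise ConfigurationError(f"target {self.target!r} missing from tables")

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.datasets)

    @property
    def feature_names(self) -> list[str]:
        df = next(iter(self.datasets.values()))
        return sorted(
            c for c in df.columns if c != self.target and c not in META_COLUMNS
        )


@dataclass
class InvariantSelection:
    """Full audit trail of one selection run."""

    target: str
    alpha: float
    n_max: int
    seed: int
    blankets: list[MarkovBlanket]
    max_mb: list[str]
    min_mb: list[str]
    sup_mb: list[str]
    ranking: list[tuple[str, float]]
    tested_subsets: list[dict]
    best_feature: list[str]
    final_set: list[str]
    search_status: str = "ok"
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "target": self.target,
            "alpha": self.alpha,
            "n_max": self.n_max,
            "seed": self.seed,
            "blankets": [b.to_dict() for b in self.blankets],
            "max_mb": self.max_mb,
            "min_mb": self.min_mb,
            "sup_mb": self.sup_mb,
            "ranking": [[f, v] for f, v in self.ranking],
            "tested_subsets": self.tested_subsets,
            "best_feature": self.best_feature,
            "final_set": self.final_set,
            "search_status": self.search_status,
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def ensemble_mb(
    table: pd.DataFrame,
    target: str,
    alpha: float = 0.05,
    seed: int = 0,
    dataset_id: str = "dataset",
) -> frozenset[str]:
    """Union of the HITON-MB and PPFS blankets for one dataset."""
    h = hiton_mb(table, target, alpha=alpha, dataset_id=dataset_id)
    p = ppfs_mb(table, target, alpha=alpha, seed=seed, dataset_id=dataset_id)
    return frozenset(h.features | p.features)


def blanket_bounds(
    blankets: Sequence[Iterable[str]],
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """(maxMB, minMB, supMB) across per-dataset blankets.

    maxMB is the union and minMB the intersection over all blankets
    (initialized to the first blanket — intersecting from the empty set
    would make minMB trivially empty); supMB = maxMB - minMB.
    """
    sets = [frozenset(b) for b in blankets]
    if len(sets) < 2:
        raise InvalidInput("need at least two blankets")
    max_mb = frozenset().union(*sets)
    min_mb = sets[0]
    for s in sets[1:]:
        min_mb = min_mb & s
    return max_mb, min_mb, max_mb - min_mb


def _fill_cache(study: MultiSourceStudy, cache: MICache) -> None:
    for ds, df in study.datasets.items():
        scores = TableScores(df, study.feature_names + [study.target])
        for f in study.feature_names:
            cache.get_or_compute(ds, f, lambda f=f: scores.mi(f, study.target))


def _ami(features: Iterable[str], study: MultiSourceStudy, cache: MICache) -> float:
    vals = [
        np.mean([cache.get(ds, f) for ds in study.dataset_ids]) for f in features
    ]
    return float(np.mean(vals))


def rank_by_ami(
    sup_mb: Iterable[str], study: MultiSourceStudy, cache: MICache | None = None
) -> list[tuple[str, float]]:
    """Disputed features in descending average-MI order (ties by name)."""
    sup_mb = list(sup_mb)
    if not sup_mb:
        raise InvalidInput("supMB is empty, nothing to rank")
    if cache is None:
        cache = MICache()
    if not all((ds, f) in cache for ds in study.dataset_ids for f in sup_mb):
        _fill_cache(study, cache)
    ami = {
        f: float(np.mean([cache.get(ds, f) for ds in study.dataset_ids]))
        for f in sup_mb
    }
    ordered = sorted(sup_mb, key=lambda f: (-ami[f], f))
    return [(f, ami[f]) for f in ordered]


def invariance_test(
    subset: Sequence[str],
    study: MultiSourceStudy,
    alpha: float = 0.4,
    cache: MICache | None = None,
) -> tuple[bool, dict[str, float]]:
    """Cross-dataset stability test for one candidate subset.

    For each dataset i the per-feature MI profile {MI(f; M | D_i)} is
    compared with the grand AMI of the subset by a one-sample t-test;
    the subset passes iff every dataset's p-value is >= alpha.  Needs
    |S| >= 2 (the t-test is undefined on a single value).

    The default screening level is far above a conventional 0.05
    because the test's power is structurally bounded: a profile in
    which exactly one feature is inflated yields |t| = 1 exactly,
    whatever the subset size or effect size, so only alpha above
    P(|T| >= 1) ~ 0.33 lets the screen reject single-feature
    contamination at all.  Genuinely invariant subsets sit near t = 0
    (the between-feature spread in the denominator dwarfs the sampling
    noise of the dataset mean) and still pass comfortably.
    """
    subset = list(subset)
    if len(subset) < 2:
        raise InvalidInput("invariance test needs subsets of size >= 2")
    if cache is None:
        cache = MICache()
    if not all((ds, f) in cache for ds in study.dataset_ids for f in subset):
        _fill_cache(study, cache)
    popmean = _ami(subset, study, cache)
    pvals: dict[str, float] = {}
    for ds in study.dataset_ids:
        vals = np.array([cache.get(ds, f) for f in subset], dtype=float)
        if vals.std(ddof=1) == 0:
            pvals[ds] = 1.0 if abs(vals.mean() - popmean) < 1e-12 else 0.0
        else:
            pvals[ds] = float(stats.ttest_1samp(vals, popmean).pvalue)
    return all(p >= alpha for p in pvals.values()), pvals


def find_invariant_set(
    ranking: Sequence[tuple[str, float]] | Sequence[str],
    study: MultiSourceStudy,
    alpha: float = 0.4,
    n_max: int = 25,
    order: str = "descending",
    budget: int = 50000,
    prune: bool = True,
    cache: MICache | None = None,
    tested_log: list[dict] | None = None,
) -> tuple[frozenset[str], str]:
    """First candidate subset of the ranked disputed features that passes.

    Sizes are enumerated from min(n_max, |ranking|) down to 2 by
    default (``order="ascending"`` reverses this); within each size,
    combinations are generated in ranking order, so prefixes of the
    top-AMI features come first.  Pruning skips any superset of a
    subset that already failed in every dataset.  Returns the empty set
    with status ``"exhausted"`` when nothing passes within the budget.
    """
    names = [f if isinstance(f, str) else f[0] for f in ranking]
    if not names:
        raise InvalidInput("ranking is empty")
    if n_max > len(names):
        n_max = len(names)
    if cache is None:
        cache = MICache()
        _fill_cache(study, cache)
    sizes = range(min(n_max, len(names)), 1, -1)
    if order == "ascending":
        sizes = range(2, min(n_max, len(names)) + 1)
    elif order != "descending":
        raise ConfigurationError(f"unknown search order {order!r}")
    failed_everywhere: list[frozenset[str]] = []
    tested = 0
    for size in sizes:
        for combo in itertools.combinations(names, size):
            sset = frozenset(combo)
            if prune and any(bad <= sset for bad in failed_everywhere):
                continue
            if tested >= budget:
                return frozenset(), "budget_exhausted"
            passed, pvals = invariance_test(combo, study, alpha, cache)
            tested += 1
            if tested_log is not None:
                tested_log.append(
                    {"subset": sorted(combo), "p_values": pvals, "passed": passed}
                )
            if passed:
                return sset, "ok"
            if all(p < alpha for p in pvals.values()):
                failed_everywhere.append(sset)
    return frozenset(), "exhausted"


def select(
    study: MultiSourceStudy,
    alpha: float = 0.05,
    n_max: int = 25,
    seed: int = 0,
    order: str = "descending",
    budget: int = 50000,
    alpha_invariance: float = 0.4,
) -> InvariantSelection:
    """Full multi-source selection pipeline with audit trail.

    ``alpha`` governs the conditional-independence testing inside the
    blanket engines; ``alpha_invariance`` is the (deliberately much
    larger) screening level of the cross-dataset invariance t-test —
    see :func:`invariance_test` for why the two levels must differ.
    The final set is minMB united with the invariant subset found among
    the disputed features; with an empty supMB (all datasets agree) the
    final set is simply minMB.
    """
    blankets: list[MarkovBlanket] = []
    ens: list[frozenset[str]] = []
    for ds, df in study.datasets.items():
        h = hiton_mb(df, study.target, alpha=alpha, dataset_id=ds)
        p = ppfs_mb(df, study.target, alpha=alpha, seed=seed, dataset_id=ds)
        blankets.extend([h, p])
        ens.append(frozenset(h.features | p.features))
    max_mb, min_mb, sup_mb = blanket_bounds(ens)
    cache = MICache()
    _fill_cache(study, cache)
    tested_log: list[dict] = []
    if sup_mb:
        ranking = rank_by_ami(sup_mb, study, cache)
        if len(sup_mb) >= 2:
            best, status = find_invariant_set(
                ranking, study, alpha_invariance, n_max, order, budget,
                cache=cache, tested_log=tested_log,
            )
        else:
            best, status = frozenset(), "sup_mb_singleton"
    else:
        ranking, best, status = [], frozenset(), "sup_mb_empty"
    final = frozenset(min_mb | best)
    return InvariantSelection(
        target=study.target,
        alpha=alpha,
        n_max=n_max,
        seed=seed,
        blankets=blankets,
        max_mb=sorted(max_mb),
        min_mb=sorted(min_mb),
        sup_mb=sorted(sup_mb),
        ranking=ranking,
        tested_subsets=tested_log,
        best_feature=sorted(best),
        final_set=sorted(final),
        search_status=status,
    )


def combine_blankets(sets: Sequence[Iterable[str]], mode: str) -> frozenset[str]:
    """Union or intersection of per-dataset feature sets."""
    sets = [frozenset(s) for s in sets]
    if not sets:
        raise InvalidInput("no blankets to combine")
    if mode == "union":
        return frozenset().union(*sets)
    if mode == "intersection":
        out = sets[0]
        for s in sets[1:]:
            out = out & s
        return out
    raise ConfigurationError(f"unknown combination mode {mode!r}")


def baseline_select(
    study: MultiSourceStudy,
    engine: str = "HITON",
    mode: str = "union",
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[frozenset[str], str]:
    """Single-engine per-dataset selection combined by union/intersection.

    The empty intersection is a legitimate outcome (overly strict
    agreement) and is returned as the empty set with a status flag.
    """
    engine = engine.upper()
    per_ds: list[frozenset[str]] = []
    for ds, df in study.datasets.items():
        if engine == "HITON":
            per_ds.append(hiton_mb(df, study.target, alpha=alpha, dataset_id=ds).features)
        elif engine == "PPFS":
            per_ds.append(
                ppfs_mb(df, study.target, alpha=alpha, seed=seed, dataset_id=ds).features
            )
        elif engine == "TREE":
            per_ds.append(tree_importance_select(df, study.target, seed=seed))
        else:
            raise ConfigurationError(f"unknown engine {engine!r}")
    combined = combine_blankets(per_ds, mode)
    return combined, ("empty" if not combined else "ok")


def tree_importance_select(
    table: pd.DataFrame,
    target: str,
    seed: int = 0,
    threshold: float | str = "mean",
    n_estimators: int = 300,
) -> frozenset[str]:
    """Impurity-importance baseline: features above the mean importance.

    Importances are the mean impurity reduction across all splits of a
    random-forest regressor, normalized to sum to 1.
    """
    feats = sorted(c for c in table.columns if c != target and c not in META_COLUMNS)
    model = RandomForestRegressor(
        n_estimators=n_estimators, random_state=seed % (2**32), n_jobs=1
    )
    model.fit(np.asarray(table[feats], dtype=float), np.asarray(table[target], dtype=float))
    imp = model.feature_importances_
    total = imp.sum()
    imp = imp / total if total > 0 else imp
    cut = float(np.mean(imp)) if threshold == "mean" else float(threshold)
    return frozenset(f for f, w in zip(feats, imp) if w > cut)


def ranking_consistency(rankings: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Pairwise Kendall tau-b between per-dataset feature rankings.

    Rankings must cover a common feature set of at least two features;
    the result is a symmetric matrix with unit diagonal.
    """
    ids = list(rankings)
    common = set(rankings[ids[0]])
    for i in ids[1:]:
        common &= set(rankings[i])
    common = sorted(common)
    if len(common) < 2:
        raise DegenerateInput("need at least 2 common features for Kendall tau")
    pos = {i: {f: r for r, f in enumerate(rankings[i]) if f in common} for i in ids}
    mat = np.eye(len(ids))
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            ra = [pos[ids[a]][f] for f in common]
            rb = [pos[ids[b]][f] for f in common]
            tau = stats.kendalltau(ra, rb).statistic
            mat[a, b] = mat[b, a] = tau
    return pd.DataFrame(mat, index=ids, columns=ids)
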