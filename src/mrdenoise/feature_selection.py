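"""Feature ranking by paired t-tests across noise levels, and SFFS subset search."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, cross_val_score

__all__ = [
    "SelectionResult",
    "ttest_rank",
    "sffs_select",
    "cv_accuracy_criterion",
    "select_features",
]

LABEL_COL = "noise_level"
ANATOMY_COL = "anatomy_id"
_META_COLS = (LABEL_COL, ANATOMY_COL, "noise_class", "bias", "thickness", "seed", "split")


@dataclass
class SelectionResult:
    """Ranked features, the p < 0.05 candidates, and the SFFS subset."""

    ranked: pd.DataFrame  # columns: feature, mean_p
    candidates: list[str]
    selected: list[str] = field(default_factory=list)
    criterion_trace: list[tuple[float, tuple[str, ...]]] = field(default_factory=list)


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLS]


def ttest_rank(table: pd.DataFrame, alpha: float = 0.05) -> SelectionResult:
    """Rank features by the mean paired-t p-value over all level pairs.

    For each feature, a paired-samples t-test is run between every unordered
    pair of noise levels, pairing rows on the anatomy identifier; the
    p-values are averaged and features ranked ascending (ties broken by
    name).  Features with mean p below ``alpha`` become SFFS candidates.
    """
    if LABEL_COL not in table.columns or ANATOMY_COL not in table.columns:
        raise ValueError(f"table must contain {LABEL_COL!r} and {ANATOMY_COL!r} columns")
    levels = sorted(table[LABEL_COL].unique())
    if len(levels) < 2:
        raise ValueError("need at least two noise levels")
    if table.duplicated([ANATOMY_COL, LABEL_COL]).any():
        raise ValueError("each (anatomy_id, noise_level) pair may appear at most once")

    by_level = {
        lv: table[table[LABEL_COL] == lv].set_index(ANATOMY_COL) for lv in levels
    }
    features = _feature_columns(table)
    rows = []
    for feat in features:
        pvals = []
        for la, lb in combinations(levels, 2):
            a = by_level[la][feat]
            b = by_level[lb][feat]
            common = a.index.intersection(b.index)
            if len(common) < 3:
                raise ValueError(
                    f"need >= 3 paired observations for levels {la} vs {lb}"
                )
            diff = a.loc[common].to_numpy() - b.loc[common].to_numpy()
            if np.allclose(diff, diff[0]):
                warnings.warn(
                    f"zero-variance differences for {feat} ({la} vs {lb}): p set to 1",
                    RuntimeWarning, stacklevel=2,
                )
                pvals.append(1.0)
            else:
                pvals.append(float(stats.ttest_rel(a.loc[common], b.loc[common]).pvalue))
        rows.append((feat, float(np.mean(pvals))))
    ranked = (
        pd.DataFrame(rows, columns=["feature", "mean_p"])
        .sort_values(["mean_p", "feature"], kind="stable")
        .reset_index(drop=True)
    )
    candidates = ranked.loc[ranked["mean_p"] < alpha, "feature"].tolist()
    return SelectionResult(ranked=ranked, candidates=candidates)


def cv_accuracy_criterion(table: pd.DataFrame, label_col: str = "noise_class",
                          n_splits: int = 5, seed: int = 0) -> Callable[[Sequence[str]], float]:
    """Subset score = seeded k-fold CV accuracy of a linear noise-class classifier.

    A stand-in for the downstream first-stage classifier that is cheap enough
    to sit inside the SFFS loop.
    """
    y = table[label_col].to_numpy()
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)

    def criterion(subset: Sequence[str]) -> float:
        x = table[list(subset)].to_numpy()
        clf = LinearDiscriminantAnalysis()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = cross_val_score(clf, x, y, cv=cv, scoring="accuracy")
        return float(scores.mean())

    return criterion


def sffs_select(candidates: Sequence[str], criterion: Callable[[Sequence[str]], float],
                k_max: int = 5, floating: bool = True,
                search_margin: int = 3) -> SelectionResult:
    """Sequential forward floating selection over the candidate features.

    Repeats best-single-feature inclusion, each followed by conditional
    exclusions accepted only while they strictly improve on the best subset
    recorded at the smaller size (which also guarantees termination).  The
    forward search runs ``search_margin`` sizes past ``k_max`` (backtracking
    can then improve the smaller subsets) and the best subset of size
    <= ``k_max`` found anywhere in the search is returned.  With
    ``floating=False`` this reduces to plain sequential forward selection.
    """
    candidates = sorted(dict.fromkeys(candidates))
    if not candidates:
        raise ValueError("candidates must be nonempty")
    cache: dict[tuple[str, ...], float] = {}

    def score(subset: Sequence[str]) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            cache[key] = float(criterion(list(key)))
        return cache[key]

    best_by_size: dict[int, tuple[float, tuple[str, ...]]] = {}
    trace: list[tuple[float, tuple[str, ...]]] = []

    def record(subset: Sequence[str], value: float) -> None:
        key = tuple(sorted(subset))
        trace.append((value, key))
        k = len(key)
        if k not in best_by_size or value > best_by_size[k][0]:
            best_by_size[k] = (value, key)

    k_search = min(len(candidates), k_max + (search_margin if floating else 0))
    current: list[str] = []
    while len(current) < k_search:
        remaining = [f for f in candidates if f not in current]
        if not remaining:
            break
        # inclusion: best single addition (ties -> lexicographically first)
        add_scores = [(score(current + [f]), f) for f in remaining]
        best_val, best_feat = max(add_scores, key=lambda t: (t[0], _neg(t[1])))
        current.append(best_feat)
        record(current, best_val)
        # conditional exclusion while it beats the recorded best at that size
        while floating and len(current) > 2:
            drop_scores = [
                (score([f for f in current if f != g]), g) for g in current
            ]
            val, feat = max(drop_scores, key=lambda t: (t[0], _neg(t[1])))
            if val > best_by_size.get(len(current) - 1, (-np.inf,))[0]:
                current.remove(feat)
                record(current, val)
            else:
                break

    best_val, best_subset = max(
        (v for k, v in best_by_size.items() if k <= k_max),
        key=lambda t: (t[0], -len(t[1])),
    )
    return SelectionResult(
        ranked=pd.DataFrame(columns=["feature", "mean_p"]),
        candidates=list(candidates),
        selected=list(best_subset),
        criterion_trace=trace,
    )


class _neg(str):
    """Inverts string comparison so max() breaks ties toward the smaller name."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)


def select_features(table: pd.DataFrame, k_max: int = 5, alpha: float = 0.05,
                    seed: int = 0, floating: bool = True,
                    criterion: Callable[[Sequence[str]], float] | None = None) -> SelectionResult:
    """Full pipeline: paired-t ranking, p < alpha gate, then SFFS."""
    ranked = ttest_rank(table, alpha=alpha)
    candidates = ranked.candidates or ranked.ranked["feature"].head(k_max).tolist()
    if criterion is None:
        criterion = cv_accuracy_criterion(table, seed=seed)
    result = sffs_select(candidates, criterion, k_max=k_max, floating=floating)
    result.ranked = ranked.ranked
    result.candidates = ranked.candidates
    return result
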