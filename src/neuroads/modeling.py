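"""Rating binarization, feature selection and leave-one-ad-out classification.

The protocol: per-subject min-max normalization of ratings with a 0.5
high/low split; a two-stage correlation filter (redundancy pruning at
|r| > 0.8, then relevance at |r| > 0.1 against the normalized rating);
SVM-based recursive feature elimination with the kept-set size chosen by
inner 4-fold cross-validation; and leave-one-ad-out evaluation of four
classifiers (RBF-SVM, random forest, decision tree, logistic regression)
with accuracy, F1 and AUC per fold.  All selection steps are fitted on
training folds only (a global mode exists behind a flag).

The linear-SVM RFE works on a precomputed Gram matrix that is downdated as
features are eliminated, which keeps the nested search cheap at high feature
counts without changing the fitted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from neuroads.types import ParameterError

__all__ = [
    "normalize_and_binarize",
    "SelectionState",
    "prune_redundant",
    "relevance_filter",
    "RfeResult",
    "svm_rfe",
    "EvaluationReport",
    "loao_evaluate",
    "PermutationResult",
    "permutation_test",
    "accuracy",
    "f1_score",
    "auc_score",
]

COARSE_C_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
FINE_C_GRID: tuple[float, ...] = (0.1, 0.15, 0.2, 0.25, 0.3, 0.35)


# -- ratings ---------------------------------------------------------------


def normalize_and_binarize(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-subject min-max rating normalization and HR/LR labeling.

    Adds ``normalized`` (in [0, 1]) and ``label`` ('HR' iff normalized >=
    0.5).  A subject whose ratings are all equal maps to 1 (HR) with a
    warning.
    """
    if "rating" not in ratings.columns or "subject_id" not in ratings.columns:
        raise ParameterError("rating table needs subject_id and rating columns")
    out = ratings.copy()
    normalized = np.empty(len(out), dtype=float)
    for subj, grp in out.groupby("subject_id", sort=False):
        x = grp["rating"].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            warnings.warn(f"subject {subj}: constant ratings; normalized set to 1 (HR)")
            normalized[out["subject_id"] == subj] = 1.0
        else:
            normalized[out["subject_id"] == subj] = (x - lo) / (hi - lo)
    out["normalized"] = normalized
    out["label"] = np.where(out["normalized"] >= 0.5, "HR", "LR")
    return out


# -- correlation filters ---------------------------------------------------


@dataclass
class SelectionState:
    """Feature names surviving each selection stage (stage2 subset of stage1)."""

    stage1_kept: tuple[str, ...]
    stage2_kept: Optional[tuple[str, ...]] = None
    rfe_kept: Optional[tuple[str, ...]] = None
    prune_threshold: float = 0.8
    relevance_threshold: float = 0.1
    dropped_zero_variance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.stage2_kept is not None and not set(self.stage2_kept) <= set(self.stage1_kept):
            raise ParameterError("stage2_kept must be a subset of stage1_kept")
        if self.rfe_kept is not None and self.stage2_kept is not None \
                and not set(self.rfe_kept) <= set(self.stage2_kept):
            raise ParameterError("rfe_kept must be a subset of stage2_kept")


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def prune_redundant(X: pd.DataFrame, threshold: float = 0.8) -> SelectionState:
    """Stage-1 redundancy pruning by pairwise correlation.

    Features are scanned in column (registry) order; a feature is dropped iff
    its absolute Pearson correlation with an already-kept feature exceeds the
    threshold (first-seen-wins tie-break).  Zero-variance features are
    dropped up front with a warning.  Must be fitted on training rows only.
    """
    if X.shape[1] < 2:
        raise ParameterError("need at least 2 features to prune")
    sd = X.to_numpy().std(axis=0)
    zero_var = tuple(X.columns[sd == 0])
    if zero_var:
        warnings.warn(f"dropping {len(zero_var)} zero-variance feature(s)")
    cols = [c for c, s in zip(X.columns, sd) if s > 0]
    Z = _standardize(X[cols].to_numpy(dtype=np.float32))
    n = Z.shape[0]
    C = np.abs(Z.T @ Z / n)
    kept: list[int] = []
    for j in range(len(cols)):
        if kept and float(C[j, kept].max()) > threshold:
            continue
        kept.append(j)
    return SelectionState(
        stage1_kept=tuple(cols[j] for j in kept),
        prune_threshold=threshold,
        dropped_zero_variance=zero_var,
    )


def relevance_filter(X: pd.DataFrame, normalized_ratings: np.ndarray,
                     threshold: float = 0.1,
                     state: Optional[SelectionState] = None) -> SelectionState:
    """Stage-2 relevance filter: keep features with |r| vs rating > threshold.

    The absolute value is used so negatively informative features survive.
    """
    cols = list(state.stage1_kept) if state is not None else list(X.columns)
    y = np.asarray(normalized_ratings, dtype=float)
    if np.ptp(y) == 0:
        raise ParameterError("normalized ratings are constant; relevance undefined")
    Z = _standardize(X[cols].to_numpy(dtype=float))
    yz = (y - y.mean()) / y.std()
    r = Z.T @ yz / len(y)
    kept = tuple(c for c, ri in zip(cols, r) if abs(ri) > threshold)
    if not kept:
        raise ParameterError(
            f"no feature passes the relevance threshold {threshold}; lower the threshold")
    if state is None:
        state = SelectionState(stage1_kept=tuple(cols), prune_threshold=np.nan)
    return SelectionState(
        stage1_kept=state.stage1_kept, stage2_kept=kept,
        prune_threshold=state.prune_threshold, relevance_threshold=threshold,
        dropped_zero_variance=state.dropped_zero_variance,
    )


# -- SVM-RFE ---------------------------------------------------------------


@dataclass
class RfeResult:
    """Outcome of recursive feature elimination on one training split."""

    ranking: tuple[str, ...]  # most to least important
    kept: tuple[str, ...]
    chosen_c: float
    cv_scores: dict[int, float] = field(default_factory=dict)  # set size -> CV accuracy


def _cv_folds(y: np.ndarray, n_folds: int, seed: int):
    classes, counts = np.unique(y, return_counts=True)
    k = min(n_folds, int(counts.min()))
    if k < 2:
        return None
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def _gram_cv_accuracy(K: np.ndarray, y: np.ndarray, c: float, folds) -> float:
    acc = 0.0
    for tr, te in folds:
        clf = SVC(kernel="precomputed", C=c)
        clf.fit(K[np.ix_(tr, tr)], y[tr])
        acc += float((clf.predict(K[np.ix_(te, tr)]) == y[te]).mean())
    return acc / len(folds)


def svm_rfe(X: pd.DataFrame, y: Sequence, inner_folds: int = 4, seed: int = 0,
            c: Optional[float] = None,
            coarse_grid: Sequence[float] = COARSE_C_GRID,
            fine_grid: Sequence[float] = FINE_C_GRID,
            halve_until: int = 32) -> RfeResult:
    """Linear-SVM recursive feature elimination with inner-CV size selection.

    The regularization constant is tuned by inner cross-validation over a
    coarse then a fine grid (unless ``c`` is given).  Elimination halves the
    surviving set until ``halve_until`` features remain, then steps by one;
    at every visited size the inner-CV accuracy is recorded and the kept set
    is the one maximizing it (ties broken toward fewer features).  Weights
    are taken from the dual solution on a precomputed Gram matrix that is
    downdated as features are dropped.
    """
    names = list(X.columns)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ParameterError("training data contains a single class")
    if X.shape[1] < 2:
        raise ParameterError("need at least 2 features for RFE")
    Z = _standardize(X.to_numpy(dtype=float))
    n = Z.shape[0]
    K = Z @ Z.T
    folds = _cv_folds(y, inner_folds, seed)
    if folds is None:
        warnings.warn("too few samples per class for inner CV; keeping all features")
        return RfeResult(ranking=tuple(names), kept=tuple(names),
                         chosen_c=c if c is not None else 1.0)

    if c is None:
        candidates = list(coarse_grid) + list(fine_grid)
        scores = [(_gram_cv_accuracy(K, y, cc, folds), -cc) for cc in candidates]
        c = -max(scores)[1]  # ties broken toward the smaller C

    active = np.arange(len(names))
    K_act = K.copy()
    eliminated: list[int] = []
    cv_scores: dict[int, float] = {}
    history: dict[int, np.ndarray] = {}
    while True:
        size = len(active)
        cv_scores[size] = _gram_cv_accuracy(K_act, y, c, folds)
        history[size] = active.copy()
        if size == 1:
            break
        clf = SVC(kernel="precomputed", C=c)
        clf.fit(K_act, y)
        sv = clf.support_
        w = clf.dual_coef_ @ Z[np.ix_(sv, active)]
        order = np.argsort(np.abs(w[0]), kind="stable")
        n_next = max(size // 2, halve_until) if size > halve_until else size - 1
        drop_local = order[: size - n_next]
        drop = active[drop_local]
        eliminated.extend(drop.tolist())
        Zd = Z[:, drop]
        K_act = K_act - Zd @ Zd.T
        mask = np.ones(size, dtype=bool)
        mask[drop_local] = False
        active = active[mask]

    best_size = max(cv_scores, key=lambda s: (cv_scores[s], -s))
    kept = tuple(names[j] for j in history[best_size])
    ranking = tuple(names[j] for j in list(active) + eliminated[::-1])
    return RfeResult(ranking=ranking, kept=kept, chosen_c=float(c), cv_scores=cv_scores)


# -- metrics ---------------------------------------------------------------


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(Tp + Tn) / (Tp + Fp + Tn + Fn)."""
    if min(tp, tn, fp, fn) < 0:
        raise ParameterError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ParameterError("all confusion counts are zero")
    return (tp + tn) / total


def f1_score(tp: int, fp: int, fn: int) -> float:
    """Tp / (Tp + 0.5 (Fp + Fn))."""
    if min(tp, fp, fn) < 0:
        raise ParameterError("confusion counts must be non-negative")
    denom = tp + 0.5 * (fp + fn)
    if denom == 0:
        raise ParameterError("F1 undefined: no positives in predictions or truth")
    return tp / denom


def auc_score(scores: Sequence[float], labels: Sequence) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) statistic.

    ``labels`` are boolean (or {0,1}) with True the positive class.  Returns
    NaN when only one class is present (the undefined marker used for
    single-class test folds).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# -- leave-one-ad-out evaluation -------------------------------------------


@dataclass
class EvaluationReport:
    """Per-fold and averaged LOAO results plus the per-fold selections."""

    per_fold: pd.DataFrame  # ad_id, model, accuracy, f1, auc, n_test, ...
    averages: pd.DataFrame  # model, accuracy, f1, auc (AUC over defined folds)
    selections: dict
    settings: dict

    def to_csv(self, path) -> None:
        """Table-3-style layout: rows = ads + average, columns = model x metric."""
        wide = self.per_fold.pivot(index="ad_id", columns="model",
                                   values=["accuracy", "f1", "auc"])
        wide.columns = [f"{m}_{v}" for v, m in wide.columns]
        avg = {f"{row.model}_{v}": getattr(row, v)
               for row in self.averages.itertuples() for v in ("accuracy", "f1", "auc")}
        wide.loc["average"] = pd.Series(avg)
        wide.to_csv(path)

    def to_json(self, path) -> None:
        import json
        payload = dict(
            settings=self.settings,
            per_fold=self.per_fold.to_dict(orient="records"),
            averages=self.averages.to_dict(orient="records"),
            selections={ad: dict(
                stage1=len(s.stage1_kept),
                stage2=len(s.stage2_kept) if s.stage2_kept else None,
                rfe_kept=list(s.rfe_kept) if s.rfe_kept else None,
            ) for ad, s in self.selections.items()},
        )
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def _make_classifiers(which: Sequence[str], svm_c: float, svm_gamma: float, seed: int):
    registry = {
        "svm": lambda: SVC(C=svm_c, gamma=svm_gamma, kernel="rbf"),
        "rf": lambda: RandomForestClassifier(random_state=seed),
        "dt": lambda: DecisionTreeClassifier(random_state=seed),
        "lr": lambda: LogisticRegression(max_iter=1000),
    }
    unknown = set(which) - set(registry)
    if unknown:
        raise ParameterError(f"unknown classifiers: {sorted(unknown)}")
    return {name: registry[name] for name in which}


def _align(features: pd.DataFrame, rating_table: pd.DataFrame) -> pd.DataFrame:
    rt = rating_table.set_index(["subject_id", "ad_id"]).loc[features.index]
    return rt


def loao_evaluate(features: pd.DataFrame, rating_table: pd.DataFrame,
                  classifiers: Sequence[str] = ("svm", "rf", "dt", "lr"),
                  prune_threshold: float = 0.8, relevance_threshold: float = 0.1,
                  rfe: bool = True, inner_folds: int = 4,
                  svm_c: float = 10.0, svm_gamma: float = 0.01, seed: int = 0,
                  selection_scope: str = "per_fold",
                  rfe_c: Optional[float] = None,
                  _stage1_cache: Optional[dict] = None) -> EvaluationReport:
    """Leave-one-ad-out evaluation with nested feature selection.

    ``features`` is the (subject, ad)-indexed feature matrix; ``rating_table``
    must already contain ``normalized`` and ``label`` columns (see
    :func:`normalize_and_binarize`).  For every ad, the two-stage correlation
    filter and the SVM-RFE are fitted on the seven training ads only
    (``selection_scope='global'`` fits the correlation filters once on all
    rows, for fidelity comparisons; it is not leakage-safe).  AUC is the
    undefined marker (NaN) when the held-out ad has a single class, and such
    folds are excluded from the AUC average.
    """
    if selection_scope not in ("per_fold", "global"):
        raise ParameterError(f"unknown selection_scope {selection_scope!r}")
    if "normalized" not in rating_table.columns or "label" not in rating_table.columns:
        rating_table = normalize_and_binarize(rating_table)
    rt = _align(features, rating_table)
    y_all = (rt["label"] == "HR").to_numpy()
    r_all = rt["normalized"].to_numpy(dtype=float)
    ad_ids = features.index.get_level_values("ad_id")
    ads = list(dict.fromkeys(ad_ids))
    if len(ads) < 2:
        raise ParameterError("need at least 2 ads for leave-one-ad-out")
    models = _make_classifiers(classifiers, svm_c, svm_gamma, seed)

    global_state = None
    if selection_scope == "global":
        global_state = prune_redundant(features, prune_threshold)
        global_state = relevance_filter(features, r_all, relevance_threshold, global_state)

    rows = []
    selections = {}
    for ad in ads:
        te = np.asarray(ad_ids == ad)
        tr = ~te
        if te.sum() == 0:
            warnings.warn(f"ad {ad!r} has no rows; skipped")
            continue
        Xtr, Xte = features.loc[tr], features.loc[te]
        ytr, yte = y_all[tr], y_all[te]
        if selection_scope == "global":
            state = global_state
        elif _stage1_cache is not None and ad in _stage1_cache:
            state = _stage1_cache[ad]
        else:
            state = prune_redundant(Xtr, prune_threshold)
            if _stage1_cache is not None:
                _stage1_cache[ad] = state
        state = relevance_filter(Xtr, r_all[tr], relevance_threshold,
                                 SelectionState(stage1_kept=state.stage1_kept,
                                                prune_threshold=prune_threshold,
                                                dropped_zero_variance=state.dropped_zero_variance))
        cols = list(state.stage2_kept)
        chosen_c = np.nan
        if rfe and len(cols) >= 2:
            res = svm_rfe(Xtr[cols], ytr, inner_folds=inner_folds, seed=seed, c=rfe_c)
            cols = list(res.kept)
            chosen_c = res.chosen_c
        state = SelectionState(
            stage1_kept=state.stage1_kept, stage2_kept=state.stage2_kept,
            rfe_kept=tuple(cols), prune_threshold=prune_threshold,
            relevance_threshold=relevance_threshold,
            dropped_zero_variance=state.dropped_zero_variance)
        selections[ad] = state

        mu = Xtr[cols].to_numpy().mean(axis=0)
        sd = Xtr[cols].to_numpy().std(axis=0)
        sd[sd == 0] = 1.0
        Ztr = (Xtr[cols].to_numpy() - mu) / sd
        Zte = (Xte[cols].to_numpy() - mu) / sd

        for name, factory in models.items():
            clf = factory()
            clf.fit(Ztr, ytr)
            pred = clf.predict(Zte)
            if hasattr(clf, "decision_function"):
                score = clf.decision_function(Zte)
            else:
                score = clf.predict_proba(Zte)[:, 1]
            tp = int(np.sum(pred & yte)); tn = int(np.sum(~pred & ~yte))
            fp = int(np.sum(pred & ~yte)); fn = int(np.sum(~pred & yte))
            rows.append(dict(
                ad_id=ad, model=name,
                accuracy=accuracy(tp, tn, fp, fn),
                f1=f1_score(tp, fp, fn) if (tp + fp + fn) > 0 else 1.0,
                auc=auc_score(score, yte),
                n_test=int(te.sum()), n_selected=len(cols), rfe_c=chosen_c,
            ))

    per_fold = pd.DataFrame(rows)
    averages = (per_fold.groupby("model", sort=False)
                .agg(accuracy=("accuracy", "mean"), f1=("f1", "mean"),
                     auc=("auc", lambda s: float(np.nanmean(s)) if s.notna().any() else np.nan))
                .reset_index())
    settings = dict(classifiers=list(classifiers), prune_threshold=prune_threshold,
                    relevance_threshold=relevance_threshold, rfe=rfe,
                    inner_folds=inner_folds, svm_c=svm_c, svm_gamma=svm_gamma,
                    seed=seed, selection_scope=selection_scope)
    return EvaluationReport(per_fold, averages, selections, settings)


@dataclass
class PermutationResult:
    """Observed LOAO accuracy against a label-permutation null."""

    observed: float
    null: np.ndarray
    p_value: float
    majority_rate: float


def permutation_test(features: pd.DataFrame, rating_table: pd.DataFrame,
                     n_permutations: int = 100, seed: int = 0,
                     classifier: str = "svm", **kwargs) -> PermutationResult:
    """Compare LOAO accuracy with a label-shuffle baseline.

    The rating-to-epoch assignment (normalized rating and HR/LR label
    together) is permuted across all epochs and the full training procedure
    — relevance filter, RFE, classifier — is re-fitted per permutation.
    Stage-1 redundancy pruning depends only on the features, so it is
    computed once per fold and shared.  The p-value uses the standard
    (1 + #null >= observed) / (n + 1) estimator.
    """
    if "normalized" not in rating_table.columns:
        rating_table = normalize_and_binarize(rating_table)
    rt = _align(features, rating_table).reset_index()
    cache: dict = {}
    obs = loao_evaluate(features, rt, classifiers=(classifier,), seed=seed,
                        _stage1_cache=cache, **kwargs)
    observed = float(obs.averages.loc[obs.averages["model"] == classifier, "accuracy"].iloc[0])
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    cols = ["rating", "normalized", "label"]
    for b in range(n_permutations):
        perm = rng.permutation(len(rt))
        rt_b = rt.copy()
        rt_b[cols] = rt[cols].to_numpy()[perm]
        rep = loao_evaluate(features, rt_b, classifiers=(classifier,), seed=seed,
                            _stage1_cache=cache, **kwargs)
        null[b] = float(rep.averages["accuracy"].iloc[0])
    p = float((1 + np.sum(null >= observed)) / (n_permutations + 1))
    y = (rt["label"] == "HR").to_numpy()
    majority = float(max(y.mean(), 1 - y.mean()))
    return PermutationResult(observed=observed, null=null, p_value=p, majority_rate=majority)
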