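"""LASSO-logistic stability classification with permutation testing.

Seven task setups over the three stability classes (stable S,
slow-degrading SD, fast-degrading FD): the three pairwise contrasts,
the three one-vs-rest contrasts, and the three-class multinomial task.
Performance is the AUC under repeated stratified cross-validation
(default 10 repeats of 10-fold), with the L1 penalty chosen per outer
fold by nested stratified cross-validation over a logarithmic grid.
Features are median-imputed and standardized inside each training fold
(an L1 penalty is scale-sensitive, so unscaled heterogeneous features
would be penalized inconsistently). A permutation null re-runs the same
inference on label-shuffled data; real-vs-null significance is a
one-sided Welch t-test, BH-corrected across tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .kinetics import bh_adjust

CLASS_NAMES = ("stable", "slow", "fast")

#: Label code of the exported tables: 0 slow, 1 fast, 2 stable.
CODE_TO_NAME = {0: "slow", 1: "fast", 2: "stable"}

DEFAULT_C_GRID = tuple(np.logspace(-3, 3, 20))


@dataclass(frozen=True)
class TaskSpec:
    """One classification setup over the stability classes.

    Binary tasks define positive and negative class sets (proteins in
    neither set are excluded); the multiclass task uses all three
    classes with macro-averaged one-vs-rest AUC.
    """

    name: str
    positive: frozenset = frozenset()
    negative: frozenset = frozenset()
    multiclass: bool = False

    def select(self, labels: pd.Series) -> tuple[np.ndarray, np.ndarray]:
        """Return (row mask, y) for this task; y is 0/1 or class names."""
        labels = normalize_labels(labels)
        if self.multiclass:
            mask = labels.isin(CLASS_NAMES).to_numpy()
            return mask, labels[mask].to_numpy()
        pos = labels.isin(self.positive)
        neg = labels.isin(self.negative)
        mask = (pos | neg).to_numpy()
        return mask, pos[mask].to_numpy().astype(int)


TASKS: dict[str, TaskSpec] = {
    "FDvsSD": TaskSpec("FDvsSD", frozenset({"fast"}), frozenset({"slow"})),
    "FDvsS": TaskSpec("FDvsS", frozenset({"fast"}), frozenset({"stable"})),
    "SDvsS": TaskSpec("SDvsS", frozenset({"slow"}), frozenset({"stable"})),
    "FDvsRest": TaskSpec("FDvsRest", frozenset({"fast"}),
                         frozenset({"slow", "stable"})),
    "SDvsRest": TaskSpec("SDvsRest", frozenset({"slow"}),
                         frozenset({"fast", "stable"})),
    "SvsRest": TaskSpec("SvsRest", frozenset({"stable"}),
                        frozenset({"slow", "fast"})),
    "FDvsSDvsS": TaskSpec("FDvsSDvsS", multiclass=True),
}


@dataclass
class CVResult:
    """Repeated-CV performance summary for one task."""

    task: str
    repeat_aucs: np.ndarray          # one mean-over-folds AUC per repeat
    grand_auc: float
    ci95: tuple[float, float]
    chosen_c: list[float]            # per outer fold, all repeats concatenated
    coef_mean_abs: pd.Series         # mean |standardized coef| per feature
    selection_freq: pd.Series        # fraction of outer fits with coef != 0
    oof_y: np.ndarray | None = None  # first repeat's out-of-fold truths
    oof_score: np.ndarray | None = None  # matching positive-class scores


@dataclass
class PermutationNull:
    """Label-permutation null distribution of the CV AUC."""

    task: str
    aucs: np.ndarray


def normalize_labels(labels) -> pd.Series:
    """Accept class names or the 0/1/2 numeric code; return names."""
    s = pd.Series(labels).reset_index(drop=True)
    if s.dtype.kind in "iuf":
        s = s.astype(int).map(CODE_TO_NAME)
        if s.isna().any():
            raise ValueError("numeric labels must use the 0/1/2 code")
    return s.astype(str)


def _make_model(C: float, multiclass: bool, seed: int,
                final: bool = True) -> LogisticRegression:
    # Selection fits use a lower iteration cap: at large C on
    # near-separable folds the L1 solution diverges slowly and the AUC
    # ranking across the grid is insensitive to tail convergence.
    solver = "saga" if multiclass else "liblinear"
    return LogisticRegression(
        l1_ratio=1.0, C=C, solver=solver,  # pure L1 (LASSO) penalty
        max_iter=1000 if final else 100,
        tol=1e-4 if final else 1e-3,
        random_state=seed,
    )


def _preprocess(Xtr: np.ndarray, Xte: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median-impute and standardize using training-fold statistics only."""
    med = np.nanmedian(Xtr, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    Xtr = np.where(np.isnan(Xtr), med, Xtr)
    Xte = np.where(np.isnan(Xte), med, Xte)
    mean = Xtr.mean(axis=0)
    std = Xtr.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (Xtr - mean) / std, (Xte - mean) / std


def _auc(y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray,
         multiclass: bool) -> float:
    if not multiclass:
        pos_col = int(np.where(classes == 1)[0][0])
        return roc_auc_score(y_true, proba[:, pos_col])
    # macro-averaged one-vs-rest AUC
    aucs = []
    for i, c in enumerate(classes):
        ind = (y_true == c).astype(int)
        if ind.min() == ind.max():  # class absent from the fold
            continue
        aucs.append(roc_auc_score(ind, proba[:, i]))
    return float(np.mean(aucs))


def _choose_c(X, y, c_grid, inner_folds, multiclass, seed) -> float:
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                            random_state=seed)
    scores = np.zeros(len(c_grid))
    for tr, te in inner.split(X, y):
        Xtr, Xte = _preprocess(X[tr], X[te])
        for i, C in enumerate(c_grid):
            model = _make_model(C, multiclass, seed, final=False)
            model.fit(Xtr, y[tr])
            proba = model.predict_proba(Xte)
            scores[i] += _auc(y[te], proba, model.classes_, multiclass)
    # argmax takes the first maximum, so ties keep the smallest C
    # (the stronger penalty)
    return c_grid[int(np.argmax(scores))]


def _one_cv(
    X: np.ndarray,
    y: np.ndarray,
    multiclass: bool,
    n_folds: int,
    c_grid,
    inner_folds: int,
    seed: int,
    collect,
) -> float:
    """One stratified n-fold CV with nested penalty selection.

    Returns the mean fold AUC; ``collect`` (or None) receives per-fold
    diagnostics.
    """
    outer = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_aucs = []
    for tr, te in outer.split(X, y):
        C = _choose_c(X[tr], y[tr], c_grid, inner_folds, multiclass, seed)
        Xtr, Xte = _preprocess(X[tr], X[te])
        model = _make_model(C, multiclass, seed)
        model.fit(Xtr, y[tr])
        proba = model.predict_proba(Xte)
        auc = _auc(y[te], proba, model.classes_, multiclass)
        fold_aucs.append(auc)
        if collect is not None:
            collect(C, model.coef_, y[te], proba, model.classes_)
    return float(np.mean(fold_aucs))


def run_cv(
    features: pd.DataFrame,
    labels,
    task: TaskSpec | str = "FDvsSD",
    n_repeats: int = 10,
    n_folds: int = 10,
    c_grid=DEFAULT_C_GRID,
    inner_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified CV of the L1-logistic classifier on one task."""
    task = TASKS[task] if isinstance(task, str) else task
    mask, y = task.select(pd.Series(labels))
    X = np.asarray(features, dtype=float)[mask]
    y = np.asarray(y)
    _check_class_sizes(y, n_folds)
    columns = list(features.columns)

    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s) for s in
                    ss.generate_state(n_repeats) % (2 ** 31 - 1)]

    chosen_c: list[float] = []
    coef_abs_sum = np.zeros(X.shape[1])
    coef_nonzero = np.zeros(X.shape[1])
    n_fits = 0
    oof: dict = {"y": [], "score": []}

    repeat_aucs = []
    for r, rseed in enumerate(repeat_seeds):
        def collect(C, coef, y_te, proba, classes, _r=r):
            nonlocal n_fits
            chosen_c.append(C)
            mean_abs = np.abs(coef).mean(axis=0)  # rows>1 for multinomial
            coef_abs_sum[:] += mean_abs
            coef_nonzero[:] += (mean_abs > 0).astype(float)
            n_fits += 1
            if _r == 0 and not task.multiclass:
                pos_col = int(np.where(classes == 1)[0][0])
                oof["y"].append(y_te)
                oof["score"].append(proba[:, pos_col])

        repeat_aucs.append(
            _one_cv(X, y, task.multiclass, n_folds, c_grid, inner_folds,
                    rseed, collect)
        )

    repeat_aucs = np.asarray(repeat_aucs)
    grand = float(repeat_aucs.mean())
    if n_repeats > 1:
        half = 1.96 * repeat_aucs.std(ddof=1) / np.sqrt(n_repeats)
    else:
        half = 0.0
    return CVResult(
        task=task.name,
        repeat_aucs=repeat_aucs,
        grand_auc=grand,
        ci95=(grand - half, grand + half),
        chosen_c=chosen_c,
        coef_mean_abs=pd.Series(coef_abs_sum / max(n_fits, 1), index=columns),
        selection_freq=pd.Series(coef_nonzero / max(n_fits, 1), index=columns),
        oof_y=np.concatenate(oof["y"]) if oof["y"] else None,
        oof_score=np.concatenate(oof["score"]) if oof["score"] else None,
    )


def permutation_null(
    features: pd.DataFrame,
    labels,
    task: TaskSpec | str = "FDvsSD",
    n_permutations: int = 100,
    n_folds: int = 10,
    c_grid=DEFAULT_C_GRID,
    inner_folds: int = 5,
    seed: int = 0,
) -> PermutationNull:
    """Null AUC distribution from label permutations.

    Each permutation shuffles the class labels once across all proteins
    and runs a single stratified ``n_folds``-fold CV with the same
    nested penalty selection as the real analysis.
    """
    task = TASKS[task] if isinstance(task, str) else task
    mask, y = task.select(pd.Series(labels))
    X = np.asarray(features, dtype=float)[mask]
    y = np.asarray(y)
    _check_class_sizes(y, n_folds)

    ss = np.random.SeedSequence(seed)
    perm_seeds = ss.generate_state(n_permutations) % (2 ** 31 - 1)
    aucs = []
    for pseed in perm_seeds:
        rng = np.random.default_rng(int(pseed))
        y_perm = rng.permutation(y)
        aucs.append(
            _one_cv(X, y_perm, task.multiclass, n_folds, c_grid,
                    inner_folds, int(pseed), None)
        )
    return PermutationNull(task=task.name, aucs=np.asarray(aucs))


def compare_real_vs_null(cv: CVResult, null: PermutationNull) -> float:
    """One-sided p-value that the real CV AUC exceeds the permutation null.

    Welch two-sample t-test of the real repeat AUCs against the null
    AUCs (the two samples have different sizes and variances, so the
    paired form is not applicable).
    """
    if cv.task != null.task:
        raise ValueError("CV result and null belong to different tasks")
    res = stats.ttest_ind(cv.repeat_aucs, null.aucs, equal_var=False,
                          alternative="greater")
    return float(res.pvalue)


def adjust_across_tasks(p_values: dict[str, float]) -> dict[str, float]:
    """BH-adjust the per-task real-vs-null p-values."""
    names = list(p_values)
    q = bh_adjust([p_values[n] for n in names])
    return dict(zip(names, q))


def top_features(cv: CVResult, k: int = 5) -> pd.DataFrame:
    """Features ranked by mean |standardized coefficient| across outer fits.

    Ties break alphabetically; ``k`` larger than the feature count
    returns the full ranking.
    """
    df = pd.DataFrame(
        {
            "mean_abs_coef": cv.coef_mean_abs,
            "selection_freq": cv.selection_freq,
        }
    )
    # alphabetical order first, then a stable sort by coefficient, so
    # exact ties stay alphabetically ordered
    df = df.sort_index()
    df = df.sort_values(by="mean_abs_coef", ascending=False, kind="mergesort")
    return df.head(min(k, len(df)))


def _check_class_sizes(y: np.ndarray, n_folds: int) -> None:
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; "
            f"use at most that many folds (requested {n_folds})"
        )
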