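"""Two-class Fisher LDA over attenuation/speckle feature combinations,
with a Se+Sp-maximizing threshold, patient-grouped k-fold cross-validation,
confusion metrics and ROC/AUC.

The discriminant direction w maximizes the Fisher criterion
J(w) = (w' S_B w) / (w' S_W w) with S_B the outer product of the class
mean difference and S_W the summed within-class scatter; the maximizer
solves S_W w = m2 - m1. Samples are projected on w and classified against
a scalar threshold chosen to maximize sensitivity + specificity on the
training data. Cross-validation folds partition *patients*, never
individual scans, so no patient ever straddles the train/test split.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import (ConfigurationError, DegenerateModelError, ParameterError,
                   UndefinedMetricError)

__all__ = [
    "FEATURE_NAMES",
    "DEFAULT_COMBINATIONS",
    "LDAModel",
    "ClassificationMetrics",
    "FoldResult",
    "CVResult",
    "fisher_lda",
    "fisher_criterion",
    "select_threshold",
    "confusion_metrics",
    "grouped_kfold_cv",
    "roc_auc",
    "evaluate_combinations",
]

FEATURE_NAMES = ("mu", "sigma_mu", "p1", "sigma_p1", "p2", "sigma_p2")

#: The 15 feature combinations examined for every tissue pair: single
#: features, feature+dispersion pairs, attenuation-speckle mixtures and
#: speckle-only sets.
DEFAULT_COMBINATIONS: Tuple[Tuple[str, ...], ...] = (
    ("mu",),
    ("mu", "sigma_mu"),
    ("p1",),
    ("p1", "sigma_p1"),
    ("p2",),
    ("p2", "sigma_p2"),
    ("mu", "p1"),
    ("mu", "p2"),
    ("p1", "p2"),
    ("mu", "sigma_mu", "p1"),
    ("mu", "sigma_mu", "p2"),
    ("mu", "p1", "p2"),
    ("mu", "sigma_mu", "p1", "sigma_p1"),
    ("mu", "sigma_mu", "p2", "sigma_p2"),
    ("p1", "sigma_p1", "p2", "sigma_p2"),
)


@dataclass
class LDAModel:
    """Fisher discriminant: projection vector and decision threshold.

    ``w`` is unit length and oriented so the class-2 (positive) mean
    projects higher; a projection strictly above ``threshold`` is
    assigned to class 2.
    """

    w: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    threshold: float = float("nan")
    orientation: int = 1
    ridge: float = 0.0

    def project(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return x @ self.w

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Boolean class-2 membership."""
        if not np.isfinite(self.threshold):
            raise ParameterError("threshold not set; call select_threshold first")
        return self.project(x) > self.threshold


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def fisher_criterion(w: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> float:
    """J(w) = (w' S_B w) / (w' S_W w) for a candidate direction."""
    x1, x2 = _as_2d(x1), _as_2d(x2)
    w = np.asarray(w, dtype=float).ravel()
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    d1, d2 = x1 - m1, x2 - m2
    sb = float((w @ (m2 - m1)) ** 2)
    sw = float(np.sum((d1 @ w) ** 2) + np.sum((d2 @ w) ** 2))
    if sw == 0:
        return np.inf if sb > 0 else 0.0
    return sb / sw


def fisher_lda(x1: np.ndarray, x2: np.ndarray, ridge: float = 0.0) -> LDAModel:
    """Closed-form Fisher discriminant for two classes.

    Solves S_W w = m2 - m1 (the maximizer of the Fisher criterion) with
    the within-class scatter built from per-sample outer products. A
    singular scatter triggers ridge escalation: multiples of
    1e-8 * trace(S_W)/d are added to the diagonal until the solve
    succeeds.
    """
    x1, x2 = _as_2d(x1), _as_2d(x2)
    if x1.shape[0] < 2 or x2.shape[0] < 2:
        raise ParameterError("need at least 2 samples per class")
    if x1.shape[1] != x2.shape[1]:
        raise ParameterError("class matrices differ in dimension")
    d = x1.shape[1]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    dm = m2 - m1
    scale = max(np.abs(m1).max(), np.abs(m2).max(), 1e-300)
    if np.linalg.norm(dm) <= 1e-12 * scale:
        raise DegenerateModelError("class means coincide; no discriminant exists")
    d1, d2 = x1 - m1, x2 - m2
    sw = d1.T @ d1 + d2.T @ d2

    tr = np.trace(sw)
    base = 1e-8 * (tr / d if tr > 0 else 1.0)
    ridge_eff = ridge
    for attempt in range(12):
        try:
            w = np.linalg.solve(sw + ridge_eff * np.eye(d), dm)
        except np.linalg.LinAlgError:
            w = None
        if w is not None and np.all(np.isfinite(w)) and np.linalg.norm(w) > 0:
            break
        ridge_eff = base * (10.0 ** attempt) if ridge_eff == 0 else ridge_eff * 10.0
    else:
        raise DegenerateModelError("within-class scatter irreparably singular")
    w = w / np.linalg.norm(w)
    if w @ m2 < w @ m1:
        w = -w
    return LDAModel(w=w, m1=m1, m2=m2, ridge=ridge_eff)


def select_threshold(projections: np.ndarray,
                     is_positive: np.ndarray) -> float:
    """Threshold on the projected axis maximizing Se + Sp.

    Candidates are the midpoints between consecutive sorted unique
    projections plus one candidate below the minimum and one above the
    maximum. A sample is predicted positive when its projection is
    strictly above the threshold (positives assumed to project higher).
    Ties in Se + Sp are broken toward the candidate closest to the
    midpoint of the two class medians.
    """
    proj = np.asarray(projections, dtype=float).ravel()
    pos = np.asarray(is_positive, dtype=bool).ravel()
    if proj.size != pos.size:
        raise ParameterError("projections and labels differ in length")
    if pos.all() or (~pos).all():
        raise ParameterError("both classes must be present")
    uniq = np.unique(proj)
    span = uniq[-1] - uniq[0]
    delta = span if span > 0 else 1.0
    cands = np.concatenate(([uniq[0] - delta / 2],
                            (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else [],
                            [uniq[-1] + delta / 2]))
    n_pos, n_neg = pos.sum(), (~pos).sum()
    se = np.array([(proj[pos] > c).sum() for c in cands]) / n_pos
    sp = np.array([(proj[~pos] <= c).sum() for c in cands]) / n_neg
    score = se + sp
    best = score.max()
    tied = np.flatnonzero(score == best)
    center = (np.median(proj[pos]) + np.median(proj[~pos])) / 2
    return float(cands[tied[np.argmin(np.abs(cands[tied] - center))]])


@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion counts with sensitivity, specificity, precision and AUC.

    A metric whose denominator is zero is None and its name is listed in
    ``undefined`` rather than silently set to zero.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    se: Optional[float]
    sp: Optional[float]
    pr: Optional[float]
    undefined: Tuple[str, ...] = ()
    auc: Optional[float] = None


def confusion_metrics(tp: int, tn: int, fp: int, fn: int,
                      auc: Optional[float] = None) -> ClassificationMetrics:
    """Se = TP/(TP+FN), Sp = TN/(TN+FP), Pr = TP/(TP+FP)."""
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ParameterError(f"{name} must be nonnegative")
    if tp + tn + fp + fn == 0:
        raise UndefinedMetricError("all confusion counts are zero")
    undefined = []
    se = tp / (tp + fn) if tp + fn > 0 else None
    sp = tn / (tn + fp) if tn + fp > 0 else None
    pr = tp / (tp + fp) if tp + fp > 0 else None
    for name, v in (("se", se), ("sp", sp), ("pr", pr)):
        if v is None:
            undefined.append(name)
    return ClassificationMetrics(tp=tp, tn=tn, fp=fp, fn=fn,
                                 se=se, sp=sp, pr=pr,
                                 undefined=tuple(undefined), auc=auc)


def roc_auc(projections: np.ndarray,
            is_positive: np.ndarray) -> Tuple[np.ndarray, float]:
    """ROC points (1-Sp, Se) over the threshold sweep and trapezoidal AUC.

    The AUC equals the Mann-Whitney U statistic normalized by n1*n2
    (ties credited 1/2).
    """
    proj = np.asarray(projections, dtype=float).ravel()
    pos = np.asarray(is_positive, dtype=bool).ravel()
    if pos.all() or (~pos).all():
        raise ParameterError("both classes must be present")
    order = np.argsort(-proj, kind="stable")
    proj_s, pos_s = proj[order], pos[order]
    n_pos, n_neg = pos.sum(), (~pos).sum()
    tps = np.cumsum(pos_s)
    fps = np.cumsum(~pos_s)
    # keep only the last index of each tied score block
    distinct = np.r_[proj_s[1:] != proj_s[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass(frozen=True)
class FoldResult:
    fold: int
    train_patients: Tuple[str, ...]
    test_patients: Tuple[str, ...]
    metrics: ClassificationMetrics
    threshold: float


@dataclass
class CVResult:
    """Patient-grouped cross-validation outcome for one feature set.

    ``se``, ``sp``, ``pr`` are unweighted means over folds in which the
    metric was defined; ``auc`` and ``roc`` are computed on the pooled
    held-out projections of all folds, each centered at its fold's
    decision threshold so the folds share one scale.
    """

    combination: Tuple[str, ...]
    positive_label: str
    negative_label: str
    k: int
    se: float
    sp: float
    pr: float
    auc: float
    roc: np.ndarray
    folds: List[FoldResult] = field(default_factory=list)
    folds_skipped: int = 0

    @property
    def se_plus_sp(self) -> float:
        return self.se + self.sp

    def summary(self) -> str:
        lines = [
            f"Fisher LDA, features [{', '.join(self.combination)}], "
            f"positive = {self.positive_label} vs {self.negative_label}",
            f"patient-grouped {self.k}-fold CV "
            f"({len(self.folds)} folds used, {self.folds_skipped} skipped)",
            f"  Se = {self.se:.3f}   Sp = {self.sp:.3f}   Pr = {self.pr:.3f}"
            f"   AUC = {self.auc:.3f}",
        ]
        return "\n".join(lines)


def _fold_assignment(patients: Sequence[str], k: int) -> Dict[str, int]:
    return {p: i % k for i, p in enumerate(sorted(patients))}


def grouped_kfold_cv(features: pd.DataFrame,
                     combination: Sequence[str],
                     k: Union[int, str] = "max",
                     positive_label: Optional[str] = None,
                     ridge: float = 0.0) -> CVResult:
    """Patient-grouped k-fold CV of the LDA classifier.

    ``features`` needs one row per scan with the feature columns plus
    ``label`` and ``patient_id``. ``k="max"`` uses the patient count of
    the smaller class (leave-one-patient-out with respect to the limiting
    class). Folds whose training split contains fewer than two samples of
    either class are skipped with a warning.
    """
    combination = tuple(combination)
    for name in combination:
        if name not in features.columns:
            raise ConfigurationError(f"unknown feature {name!r}")
    labels = sorted(features["label"].unique())
    if len(labels) != 2:
        raise ParameterError(f"need exactly 2 classes, got {labels}")
    if positive_label is None:
        positive_label = labels[1]
    if positive_label not in labels:
        raise ParameterError(f"positive label {positive_label!r} not in {labels}")
    negative_label = labels[0] if labels[1] == positive_label else labels[1]

    pats = {lab: sorted(features.loc[features["label"] == lab, "patient_id"].unique())
            for lab in labels}
    for lab in labels:
        if len(pats[lab]) < 2:
            raise ParameterError(f"class {lab!r} has fewer than 2 patients")
    k_max = min(len(pats[lab]) for lab in labels)
    k_eff = k_max if k == "max" else int(k)
    if not 2 <= k_eff <= k_max:
        raise ParameterError(f"k must lie in [2, {k_max}]")

    fold_of = {}
    for lab in labels:
        fold_of.update(_fold_assignment(pats[lab], k_eff))

    x = features[list(combination)].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ParameterError("non-finite feature values")
    y_pos = (features["label"] == positive_label).to_numpy()
    fold_idx = features["patient_id"].map(fold_of).to_numpy()

    folds: List[FoldResult] = []
    skipped = 0
    pooled_proj: List[np.ndarray] = []
    pooled_pos: List[np.ndarray] = []
    for f in range(k_eff):
        test = fold_idx == f
        train = ~test
        n_train_pos = int((y_pos & train).sum())
        n_train_neg = int((~y_pos & train).sum())
        if n_train_pos < 2 or n_train_neg < 2 or not test.any():
            warnings.warn(f"fold {f} skipped (degenerate train/test split)")
            skipped += 1
            continue
        try:
            model = fisher_lda(x[train & ~y_pos], x[train & y_pos], ridge=ridge)
        except DegenerateModelError:
            warnings.warn(f"fold {f} skipped (degenerate LDA)")
            skipped += 1
            continue
        proj_train = model.project(x[train])
        model.threshold = select_threshold(proj_train, y_pos[train])
        proj_test = model.project(x[test])
        pred_pos = proj_test > model.threshold
        actual = y_pos[test]
        tp = int((pred_pos & actual).sum())
        tn = int((~pred_pos & ~actual).sum())
        fp = int((pred_pos & ~actual).sum())
        fn = int((~pred_pos & actual).sum())
        m = confusion_metrics(tp, tn, fp, fn)
        folds.append(FoldResult(
            fold=f,
            train_patients=tuple(sorted(
                features.loc[train, "patient_id"].unique())),
            test_patients=tuple(sorted(
                features.loc[test, "patient_id"].unique())),
            metrics=m, threshold=model.threshold))
        pooled_proj.append(proj_test - model.threshold)
        pooled_pos.append(actual)
    if not folds:
        raise ParameterError("all cross-validation folds were skipped")

    def _avg(name: str) -> float:
        vals = [getattr(fr.metrics, name) for fr in folds
                if getattr(fr.metrics, name) is not None]
        return float(np.mean(vals)) if vals else float("nan")

    roc, auc = roc_auc(np.concatenate(pooled_proj), np.concatenate(pooled_pos))
    return CVResult(combination=combination,
                    positive_label=positive_label,
                    negative_label=negative_label,
                    k=k_eff, se=_avg("se"), sp=_avg("sp"), pr=_avg("pr"),
                    auc=auc, roc=roc, folds=folds, folds_skipped=skipped)


def evaluate_combinations(features: pd.DataFrame,
                          combinations: Optional[Sequence[Sequence[str]]] = None,
                          k: Union[int, str] = "max",
                          positive_labels: Optional[Dict[Tuple[str, str], str]] = None,
                          ridge: float = 0.0) -> pd.DataFrame:
    """Grouped-CV metrics for every class pair and feature combination.

    Returns one row per (pair, combination) with Se/Sp/Pr/AUC and a
    ``best`` flag marking the combination with the highest Se + Sp within
    each pair. By default the lexicographically later label of a pair
    plays the positive (tumor) role; ``positive_labels`` overrides this
    per sorted pair.
    """
    if combinations is None:
        combinations = DEFAULT_COMBINATIONS
    combinations = [tuple(c) for c in combinations]
    for combo in combinations:
        for name in combo:
            if name not in features.columns:
                raise ConfigurationError(f"unknown feature {name!r} in {combo}")
    labels = sorted(features["label"].unique())
    if len(labels) < 2:
        raise ParameterError("need at least 2 classes")
    rows = []
    results: Dict[Tuple[str, str, Tuple[str, ...]], CVResult] = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            pair = (labels[i], labels[j])
            pos = (positive_labels or {}).get(pair, pair[1])
            sub = features[features["label"].isin(pair)]
            for combo in combinations:
                res = grouped_kfold_cv(sub, combo, k=k,
                                       positive_label=pos, ridge=ridge)
                results[(pair[0], pair[1], combo)] = res
                rows.append({
                    "pair": f"{pair[0]} vs {pair[1]}",
                    "positive": pos,
                    "combination": "+".join(combo),
                    "se": res.se, "sp": res.sp, "pr": res.pr,
                    "auc": res.auc, "k": res.k,
                    "folds_used": len(res.folds),
                    "folds_skipped": res.folds_skipped,
                })
    table = pd.DataFrame(rows)
    table["best"] = False
    for pair, grp in table.groupby("pair"):
        best_idx = (grp["se"] + grp["sp"]).idxmax()
        table.loc[best_idx, "best"] = True
    table.attrs["results"] = results
    return table
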