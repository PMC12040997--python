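"""Validation machinery: cutoffs, classification metrics, permutation tests,
partograph baselines, interpretability reports and subgroup analyses.

Conventions: a prediction is positive iff score >= threshold; the operating
threshold is learned on training data only, by cross-validated maximisation
of min(sensitivity, specificity); AUC is the rank-based (Mann-Whitney)
statistic with tie correction; its significance is the fraction of label
permutations whose AUC is at least the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .cohort import DILATATION
from .exceptions import ValidationError


@dataclass
class EvalReport:
    """Classification report for one score at one threshold."""

    threshold: float
    se: float
    sp: float
    ppv: float
    npv: float
    n: int
    n_positive: int
    auc: float | None = None
    p_value: float | None = None
    flags: list = field(default_factory=list)

    def min_se_sp(self) -> float:
        return min(self.se, self.sp)

    def to_dict(self) -> dict:
        return {
            "Th": self.threshold, "SE": self.se, "SP": self.sp, "PPV": self.ppv,
            "NPV": self.npv, "AUC": self.auc, "p_value": self.p_value,
            "n": self.n, "n_positive": self.n_positive,
        }


def confusion_metrics(scores, labels, threshold: float) -> EvalReport:
    """SE/SP/PPV/NPV at a fixed threshold (positive iff score >= Th)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    flags = []
    if labels.all() or not labels.any():
        flags.append("single_class")
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))

    def _rate(num, den):
        return num / den if den > 0 else np.nan

    return EvalReport(
        threshold=float(threshold),
        se=_rate(tp, tp + fn), sp=_rate(tn, tn + fp),
        ppv=_rate(tp, tp + fp), npv=_rate(tn, tn + fn),
        n=int(labels.size), n_positive=int(labels.sum()), flags=flags,
    )


def _min_se_sp_at(scores: np.ndarray, labels: np.ndarray, cand: np.ndarray) -> np.ndarray:
    """Vectorised min(SE, SP) over candidate thresholds."""
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    se = (scores[labels][:, None] >= cand[None, :]).sum(axis=0) / n_pos
    sp = (scores[~labels][:, None] < cand[None, :]).sum(axis=0) / n_neg
    return np.minimum(se, sp)


def _best_threshold(
    scores: np.ndarray, labels: np.ndarray,
    val_scores: np.ndarray | None = None, val_labels: np.ndarray | None = None,
) -> tuple[float, float]:
    """Exhaustive search over midpoints of sorted unique scores.

    Candidates come from ``scores``; when a validation set is supplied the
    balance criterion min(SE, SP) is evaluated there (cross-validated
    selection), otherwise in-sample.  Returns (threshold, criterion value);
    ties go to the *larger* threshold.
    """
    uniq = np.unique(scores)
    if uniq.size < 2:
        return float(uniq[0]) if uniq.size else np.nan, 0.5
    cand = (uniq[:-1] + uniq[1:]) / 2.0
    if val_scores is None:
        crit = _min_se_sp_at(scores, labels, cand)
    else:
        crit = _min_se_sp_at(val_scores, val_labels, cand)
    best = np.max(crit)
    idx = np.where(crit >= best - 1e-15)[0][-1]  # ties toward larger Th
    return float(cand[idx]), float(best)


@dataclass
class CutoffModel:
    """Cross-validated operating threshold for one score."""

    threshold: float
    fold_thresholds: list
    fold_min_se_sp: list
    criterion: str = "max min(SE, SP), mean of fold-optimal thresholds"
    flags: list = field(default_factory=list)


def learn_cutoff(scores, labels, n_folds: int = 3, seed: int = 0) -> CutoffModel:
    """Learn Th by stratified k-fold CV on training data only.

    For each fold, the candidate thresholds are the midpoints of sorted
    unique scores in the fold's training portion; the fold-optimal
    threshold maximises min(SE, SP) on the held-out fold (cross-validated
    selection); the final Th is the mean of the fold-optimal thresholds.
    Degenerate folds (one class) are skipped with a flag.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    if labels.all() or not labels.any():
        raise ValidationError("cutoff learning requires both classes")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_th, fold_crit, flags = [], [], []
    for train_idx, val_idx in skf.split(scores[:, None], labels):
        s, y = scores[train_idx], labels[train_idx]
        sv, yv = scores[val_idx], labels[val_idx]
        if y.all() or not y.any() or yv.all() or not yv.any():
            flags.append("degenerate_fold_skipped")
            continue
        th, crit = _best_threshold(s, y, sv, yv)
        fold_th.append(th)
        fold_crit.append(crit)
    if not fold_th:
        raise ValidationError("all folds degenerate; cannot learn a cutoff")
    return CutoffModel(
        threshold=float(np.mean(fold_th)), fold_thresholds=fold_th,
        fold_min_se_sp=fold_crit, flags=flags,
    )


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with tie correction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def permutation_pvalue(scores, labels, n_perm: int = 10000, seed: int = 0) -> float:
    """Fraction of label permutations with AUC >= the observed AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    observed = auc(scores, labels)
    rng = np.random.default_rng(seed)
    ranks = rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    offset = n1 * (n1 + 1) / 2.0
    count = 0
    block = max(1, min(n_perm, int(2e7 // max(labels.size, 1))))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        # each row: ranks of a random subset of size n1 (a label permutation)
        keys = rng.random((b, labels.size))
        idx = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        perm_auc = (ranks[idx].sum(axis=1) - offset) / (n1 * n0)
        count += int(np.sum(perm_auc >= observed - 1e-12))
        done += b
    return count / n_perm


def evaluate_score(scores, labels, threshold, n_perm=0, seed=0) -> EvalReport:
    """Confusion metrics plus AUC (and optionally its permutation p-value)."""
    report = confusion_metrics(scores, labels, threshold)
    labels_b = np.asarray(labels).astype(bool)
    if labels_b.any() and not labels_b.all():
        report.auc = auc(scores, labels)
        if n_perm:
            report.p_value = permutation_pvalue(scores, labels, n_perm=n_perm, seed=seed)
    return report


# -- partograph baseline -----------------------------------------------------


def partograph_classify(times, dilatation, line: str = "alert", threshold_cm: float = 4.0):
    """Classify a dilatation series against the partograph alert/action lines.

    The alert line expects >= 1 cm/h progress from the first assessment at
    >= 4 cm dilatation; the action line runs parallel, 4 h to its right.  A
    series is positive when any assessment falls strictly to the right of
    the line (on-line points are negative).  Returns ``None`` (flagged not
    evaluable) when the series never reaches 4 cm.
    """
    if line not in ("alert", "action"):
        raise ValidationError(f"unknown partograph line {line!r}")
    times = np.asarray(times, dtype=float)
    dil = np.asarray(dilatation, dtype=float)
    ok = np.isfinite(dil)
    reached = ok & (dil >= threshold_cm)
    if not reached.any():
        return None
    k0 = int(np.argmax(reached))
    t0, d0 = times[k0], dil[k0]
    lag = 0.0 if line == "alert" else 4.0
    later = ok & (times >= t0)
    # strictly right of the line: elapsed time exceeds expected time by > lag
    excess = (times[later] - t0) - (dil[later] - d0)
    return bool(np.any(excess > lag + 1e-12))


def partograph_scores(cohort, subject_ids=None, line="alert"):
    """Vector of partograph classifications (1/0/NaN not-evaluable) per subject."""
    ids = list(subject_ids) if subject_ids is not None else cohort.subject_ids
    dyn_names = cohort.schema.dynamic_names
    if DILATATION not in dyn_names:
        raise ValidationError("cohort has no dilatation feature")
    mean, sd = cohort.encoder.moments.get(DILATATION, (0.0, 1.0))
    out = np.full(len(ids), np.nan)
    for i, sid in enumerate(ids):
        times, states = cohort.state_matrix(sid)
        col = cohort.feature_names.index(DILATATION)
        dil_cm = states[:, col] * sd + mean
        res = partograph_classify(times, dil_cm, line=line)
        if res is not None:
            out[i] = float(res)
    return pd.Series(out, index=ids, name=f"partograph_{line}")


# -- interpretability --------------------------------------------------------


def dimension_correlations(embedding: np.ndarray, variables: pd.DataFrame) -> pd.DataFrame:
    """Pearson rho between each embedding dimension and each clinical variable.

    Zero-variance variables yield NaN entries (flagged in ``attrs``).
    """
    Y = np.asarray(embedding, dtype=float)
    out = pd.DataFrame(
        index=[f"dim{p + 1}" for p in range(Y.shape[1])], columns=variables.columns, dtype=float
    )
    flagged = []
    for name in variables.columns:
        v = pd.to_numeric(variables[name], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(v)
        if ok.sum() < 2 or np.std(v[ok]) == 0.0:
            flagged.append(name)
            continue
        for p in range(Y.shape[1]):
            y = Y[ok, p]
            if np.std(y) == 0.0:
                flagged.append(f"dim{p + 1}")
                continue
            out.loc[f"dim{p + 1}", name] = float(np.corrcoef(y, v[ok])[0, 1])
    out.attrs["zero_variance"] = flagged
    return out


def outcome_rate_profile(values, outcome_flags, n_bins: int = 20) -> pd.DataFrame:
    """Per-bin outcome rate and data density along one embedding dimension.

    Equal-width bins over the observed range; rate is NaN (flagged) for
    empty bins; densities sum to one.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    x = np.asarray(values, dtype=float)
    y = np.asarray(outcome_flags).astype(bool)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    pos = np.bincount(idx, weights=y.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(counts > 0, pos / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1], "bin_right": edges[1:], "count": counts,
            "rate": rate, "density": counts / x.size, "empty": counts == 0,
        }
    )


# -- subgroup analysis -------------------------------------------------------


def assign_spatial_boxes(embedding, train_embedding=None, n1: int = 3, n2: int = 2) -> np.ndarray:
    """Axis-aligned quantile boxes over embedding dimensions 1-2.

    Box edges are quantiles of the *training* embedding so train/test share
    the same partition of the space.
    """
    Y = np.asarray(embedding, dtype=float)
    ref = np.asarray(train_embedding, dtype=float) if train_embedding is not None else Y
    q1 = np.quantile(ref[:, 0], np.linspace(0, 1, n1 + 1)[1:-1])
    q2 = np.quantile(ref[:, 1], np.linspace(0, 1, n2 + 1)[1:-1])
    b1 = np.digitize(Y[:, 0], q1)
    b2 = np.digitize(Y[:, 1], q2)
    return b1 * n2 + b2


@dataclass
class SubgroupResult:
    group: object
    n_train: int
    n_test: int
    best_score: str | None
    cutoffs: dict
    reports: dict
    flags: list = field(default_factory=list)


@dataclass
class SubgroupPartition:
    rule: str
    results: list

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"group": r.group, "n_train": r.n_train, "n_test": r.n_test,
                   "best_score": r.best_score, "flags": ";".join(r.flags)}
            for name, rep in r.reports.items():
                row[f"{name}_Th"] = rep.threshold
                row[f"{name}_SE"] = rep.se
                row[f"{name}_SP"] = rep.sp
                row[f"{name}_min_se_sp"] = rep.min_se_sp()
            rows.append(row)
        return pd.DataFrame(rows)


def subgroup_analysis(
    train_scores: pd.DataFrame, train_labels, train_groups,
    test_scores: pd.DataFrame, test_labels, test_groups,
    score_names=None, rule: str = "custom", n_folds: int = 3, seed: int = 0,
) -> SubgroupPartition:
    """Per-subgroup cutoff learning (train) and evaluation (test).

    For each subgroup, each score's cutoff is relearned on the subgroup's
    training members and applied to its testing members; the best score per
    subgroup is the one maximising min(SE, SP) in testing.  Subgroups
    without both classes are flagged and their metrics omitted.
    """
    score_names = list(score_names) if score_names is not None else list(train_scores.columns)
    train_labels = np.asarray(train_labels).astype(bool)
    test_labels = np.asarray(test_labels).astype(bool)
    train_groups = np.asarray(train_groups)
    test_groups = np.asarray(test_groups)
    results = []
    for g in np.unique(np.concatenate([train_groups, test_groups])):
        tr = train_groups == g
        te = test_groups == g
        res = SubgroupResult(
            group=g, n_train=int(tr.sum()), n_test=int(te.sum()),
            best_score=None, cutoffs={}, reports={},
        )
        y_tr, y_te = train_labels[tr], test_labels[te]
        if y_tr.sum() in (0, tr.sum()) or y_te.sum() in (0, te.sum()):
            res.flags.append("single_class_subgroup")
            results.append(res)
            continue
        best_crit = -np.inf
        for name in score_names:
            s_tr = train_scores.loc[tr, name].to_numpy(dtype=float)
            s_te = test_scores.loc[te, name].to_numpy(dtype=float)
            cut = learn_cutoff(s_tr, y_tr, n_folds=n_folds, seed=seed)
            rep = evaluate_score(s_te, y_te, cut.threshold)
            res.cutoffs[name] = cut
            res.reports[name] = rep
            if rep.min_se_sp() > best_crit:
                best_crit = rep.min_se_sp()
                res.best_score = name
        results.append(res)
    return SubgroupPartition(rule=rule, results=results)
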