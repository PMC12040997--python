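"""End-to-end pipeline stages shared by the CLI and analysis scripts.

Stage order follows the evaluation protocol: split first, learn every
statistic (encoding moments, imputation values, kernel bandwidths, kernel
weights, cutoffs) on the training partition only, then apply to the test
partition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CS_EVENT
from .embedding import MKLEmbedding, MKLEmbeddingResults
from .evaluation import evaluate_score, learn_cutoff, partograph_scores
from .monitoring import MonitoringSession, TrajectoryIndex
from .pipeline import FeatureSchema, apply_exclusions, split_train_test, validate_and_encode

SCORE_NAMES = ("vpi", "vpiz", "vpizt")


def prepare_cohort(tables, schema: FeatureSchema, fraction: float = 0.75, seed: int = 0):
    """Split, encode (train statistics only), propagate and exclude.

    Returns ``(cohort, train_ids, test_ids, exclusion_report)`` where the
    id lists contain retained subjects only.
    """
    static_table = tables[0]
    train_ids, test_ids = split_train_test(list(static_table["subject_id"]), fraction, seed)
    cohort = validate_and_encode(tables, schema, train_ids=train_ids)
    cohort.propagate()
    cohort, report = apply_exclusions(cohort)
    retained = set(cohort.subject_ids)
    train_ids = [s for s in train_ids if s in retained]
    test_ids = [s for s in test_ids if s in retained]
    return cohort, train_ids, test_ids, report


def fit_embedding(
    cohort, train_ids, n_dims: int = 6, n_neighbors: int = 10,
    max_alternations: int = 50, tol: float = 1e-6,
) -> MKLEmbeddingResults:
    model = MKLEmbedding.from_cohort(cohort, train_ids, n_dims=n_dims, n_neighbors=n_neighbors)
    return model.fit(max_alternations=max_alternations, tol=tol)


def monitor_cohort(
    results: MKLEmbeddingResults, cohort, train_ids, subject_ids,
    event: str = CS_EVENT, exclude_self: bool = False, index: TrajectoryIndex | None = None,
    **session_kw,
):
    """Score ``subject_ids`` against the training trajectory index.

    Returns ``(scores, session)``; pass ``exclude_self=True`` when scoring
    training subjects so nobody is their own peer.
    """
    if index is None:
        index = TrajectoryIndex.from_cohort(results, cohort, train_ids)
    session = MonitoringSession(results, index, **session_kw)
    scores = session.score_cohort(cohort, subject_ids, event=event, exclude_self=exclude_self)
    return scores, session


def evaluate_predictors(
    train_scores: pd.DataFrame, train_labels, test_scores: pd.DataFrame, test_labels,
    cohort=None, train_ids=None, test_ids=None,
    n_folds: int = 3, n_perm: int = 0, seed: int = 0,
) -> pd.DataFrame:
    """Cutoffs on training scores, metrics on both partitions.

    Adds partograph alert/action baselines when a cohort is provided.  NaN
    scores (all-flagged subjects, non-evaluable partograph series) are
    scored as negative at evaluation time.
    """
    rows = []
    train_labels = np.asarray(train_labels).astype(bool)
    test_labels = np.asarray(test_labels).astype(bool)
    for name in SCORE_NAMES:
        if name not in train_scores.columns:
            continue
        s_tr = _fill(train_scores[name])
        s_te = _fill(test_scores[name])
        cut = learn_cutoff(s_tr, train_labels, n_folds=n_folds, seed=seed)
        rep_tr = evaluate_score(s_tr, train_labels, cut.threshold, n_perm=n_perm, seed=seed)
        rep_te = evaluate_score(s_te, test_labels, cut.threshold)
        rows.append({"predictor": name, "partition": "train", **rep_tr.to_dict()})
        rows.append({"predictor": name, "partition": "test", **rep_te.to_dict()})
    if cohort is not None:
        for line in ("alert", "action"):
            for part, ids, labels in (
                ("train", train_ids, train_labels), ("test", test_ids, test_labels)
            ):
                s = _fill(partograph_scores(cohort, ids, line=line))
                rep = evaluate_score(s, labels, 0.5)
                rows.append({"predictor": f"{line}_line", "partition": part, **rep.to_dict()})
    return pd.DataFrame(rows)


def _fill(series) -> np.ndarray:
    """Flagged (NaN) scores are treated as most-negative at evaluation time."""
    arr = np.asarray(series, dtype=float)
    if np.isnan(arr).any():
        finite = arr[np.isfinite(arr)]
        floor = float(finite.min()) - 1.0 if finite.size else 0.0
        arr = np.where(np.isnan(arr), floor, arr)
    return arr


def cs_labels(cohort, subject_ids) -> np.ndarray:
    return cohort.outcomes.loc[list(subject_ids), "cs_flag"].astype(bool).to_numpy()
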