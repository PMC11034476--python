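"""Minority-rule consensus over trained models and external evaluation.

The consensus deliberately trades precision for sensitivity: a variant is
called pathogenic as soon as any one member model calls it pathogenic
(minority rule), and its consensus pathogenicity score is the maximum of
the members' pathogenic-class probabilities. Consequently consensus
sensitivity is never below any member's and consensus precision never
above a positive-calling member's.

External evaluation takes an assay-labeled variant panel, removes panel
variants from the training rows (so the panel is genuinely held out),
scores each member model and the consensus, and exports a side-by-side
prediction table for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .encoding import FeatureMatrix
from .modeling import MetricsReport, PathogenicityClassifier, compute_metrics

__all__ = [
    "minority_vote",
    "consensus_score",
    "deoverlap",
    "evaluate_external",
    "MinorityConsensusClassifier",
    "ASSAY_INTERPRETATION",
]

# Functional-assay phenotype -> binary label used as external ground truth.
ASSAY_INTERPRETATION: dict[str, str] = {
    "as WT": "benign",
    "slightly reduced": "benign",
    "no response": "pathogenic",
    "reduced": "pathogenic",
}


def minority_vote(predictions: Sequence[int]) -> int:
    """Pathogenic (1) iff any model predicts pathogenic; benign otherwise."""
    preds = list(predictions)
    if not preds:
        raise ValueError("minority vote needs at least one model prediction")
    return int(any(int(p) == 1 for p in preds))


def consensus_score(probabilities: Sequence[float]) -> float:
    """Consensus pathogenic probability = maximum over the member models."""
    probs = [float(p) for p in probabilities]
    if not probs:
        raise ValueError("consensus score needs at least one probability")
    if any(not (0.0 <= p <= 1.0) for p in probs):
        raise ValueError("probabilities must lie in [0, 1]")
    return max(probs)


class MinorityConsensusClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn ensemble applying the minority rule over fitted members.

    ``fit`` fits each member on the same data (members may also be passed
    in pre-fitted and ``fit`` skipped); ``predict`` is the minority vote
    and ``predict_proba``'s pathogenic column the member maximum (its
    complement fills the benign column, so rows sum to 1).
    """

    def __init__(self, members: list[PathogenicityClassifier] | None = None):
        self.members = members

    def fit(self, X, y=None):
        if not self.members:
            raise ValueError("no member models")
        self.members_ = [m.fit(X, y) for m in self.members]
        self.classes_ = np.array([0, 1])
        return self

    def _fitted_members(self) -> list[PathogenicityClassifier]:
        if hasattr(self, "members_"):
            return self.members_
        if not self.members:
            raise ValueError("no member models")
        for m in self.members:
            check_is_fitted(m, "pipeline_")
        return self.members

    def predict(self, X) -> np.ndarray:
        votes = np.column_stack([m.predict(X) for m in self._fitted_members()])
        return np.apply_along_axis(minority_vote, 1, votes)

    def predict_proba(self, X) -> np.ndarray:
        probs = np.column_stack([m.pathogenic_proba(X) for m in self._fitted_members()])
        pos = probs.max(axis=1)
        return np.column_stack([1.0 - pos, pos])

    def pathogenic_proba(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]


def deoverlap(
    train: FeatureMatrix, external_ids: Iterable[str]
) -> tuple[FeatureMatrix, list[str]]:
    """Remove training rows that also occur in the external set.

    Row identity is the ``seq_id:variant`` row id. Returns the reduced
    matrix and the list of moved row ids; idempotent.
    """
    ids = set(external_ids)
    moved = [r for r in train.row_ids if r in ids]
    keep = train.data.index.difference(moved, sort=False)
    prov = dict(train.provenance)
    prov["moved_to_external"] = prov.get("moved_to_external", 0) + len(moved)
    return FeatureMatrix(train.data.loc[keep], train.labels.loc[keep], prov), moved


def evaluate_external(
    models: Mapping[str, PathogenicityClassifier],
    external: FeatureMatrix,
    extra_predictions: Mapping[str, Sequence[int]] | None = None,
) -> tuple[dict[str, MetricsReport], MetricsReport, pd.DataFrame]:
    """Score member models and their minority-rule consensus on a panel.

    ``external`` must carry binary ground-truth labels and the training
    feature schema. ``extra_predictions`` (e.g. an external predictor's
    published calls, aligned to rows) are appended to the prediction table
    for side-by-side comparison but take no part in the consensus.

    Returns per-model reports, the consensus report (ROC AUC from the
    max-probability consensus score), and the audit table.
    """
    ext = external.labeled()
    y = ext.y.astype(int)
    table = pd.DataFrame(index=ext.data.index)
    table["truth"] = y
    per_model: dict[str, MetricsReport] = {}
    votes, probs = [], []
    for name, model in models.items():
        pred = model.predict(ext.data)
        score = model.pathogenic_proba(ext.data)
        per_model[name] = compute_metrics(y, pred, score)
        table[f"pred_{name}"] = pred
        votes.append(pred)
        probs.append(score)
    vote_mat = np.column_stack(votes)
    cons_pred = np.apply_along_axis(minority_vote, 1, vote_mat)
    cons_score = np.column_stack(probs).max(axis=1)
    consensus = compute_metrics(y, cons_pred, cons_score)
    table["pred_consensus"] = cons_pred
    table["score_consensus"] = cons_score
    if extra_predictions:
        for name, preds in extra_predictions.items():
            table[f"pred_{name}"] = np.asarray(list(preds), dtype=int)
    return per_model, consensus, table
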