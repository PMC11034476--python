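"""Feature- and domain-level importance analysis.

Two complementary rankings are produced for each fitted model: the
learner's built-in importance (Gini impurity decrease for tree ensembles,
absolute coefficient magnitude for logistic regression — unavailable for
non-linear SVM kernels) and model-agnostic permutation importance (mean
accuracy drop when one feature is shuffled, repeated). Domain-wise feature
names (``d<k>.<component>``) let per-feature scores be aggregated into a
per-domain ranking, and the consensus of the two rankings' top-k sets
identifies the domains that matter regardless of the attribution
technique.
"""

from __future__ import annotations

import re
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance as _sk_permutation_importance

from .encoding import FeatureMatrix
from .modeling import PathogenicityClassifier

__all__ = [
    "UnsupportedImportanceError",
    "builtin_importance",
    "permutation_importance",
    "domain_rank",
    "consensus_features",
]

_DOMAIN_FEATURE_RE = re.compile(r"^d(\d+)\.")


class UnsupportedImportanceError(TypeError):
    """Architecture/kernel has no built-in importance attribute."""


def builtin_importance(model: PathogenicityClassifier) -> pd.Series:
    """Learner-native importance per feature (non-negative).

    Tree ensembles report impurity-based importances (summing to 1);
    logistic regression reports absolute coefficient magnitudes. SVMs with
    non-linear kernels (polynomial, RBF) expose no per-feature attribute
    and raise :class:`UnsupportedImportanceError`.
    """
    est = model.pipeline_.named_steps["clf"]
    names = list(model.feature_names_in_)
    if model.architecture in ("random_forest", "xgboost"):
        scores = np.asarray(est.feature_importances_, dtype=float)
    elif model.architecture == "logistic_regression":
        scores = np.abs(np.asarray(est.coef_, dtype=float).ravel())
    elif model.architecture == "svm":
        kernel = est.kernel
        if kernel == "linear":
            scores = np.abs(np.asarray(est.coef_, dtype=float).ravel())
        else:
            raise UnsupportedImportanceError(
                f"built-in feature importance is impossible for the {kernel!r} SVM kernel; "
                "use permutation importance instead"
            )
    else:  # pragma: no cover - architectures are validated at fit time
        raise UnsupportedImportanceError(model.architecture)
    return pd.Series(scores, index=names, name="builtin_importance")


def permutation_importance(
    model: PathogenicityClassifier,
    matrix: FeatureMatrix,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean accuracy drop (+/- sd) per feature over repeated shuffles.

    Each feature is independently permuted ``n_repeats`` times and the
    decrease in accuracy on the supplied labeled rows recorded;
    deterministic for a given seed.
    """
    m = matrix.labeled()
    res = _sk_permutation_importance(
        model,
        m.data,
        m.y.astype(int),
        scoring="accuracy",
        n_repeats=n_repeats,
        random_state=seed,
    )
    return pd.DataFrame(
        {"mean_drop": res.importances_mean, "sd": res.importances_std},
        index=m.feature_names,
    )


def domain_rank(
    scores: Mapping[str, float] | pd.Series,
    aggregate: Literal["sum", "mean", "max"] = "sum",
) -> list[int]:
    """Rank domains by aggregated absolute per-feature scores, descending.

    Requires domain-wise feature names (``d<k>.<component>``); aggregation
    over a domain's features is the sum of absolute scores by default
    (``mean`` and ``max`` available). Ties break by ascending domain index.
    """
    scores = pd.Series(scores, dtype=float)
    groups: dict[int, list[float]] = {}
    for name, value in scores.items():
        m = _DOMAIN_FEATURE_RE.match(str(name))
        if not m:
            raise ValueError(
                f"feature {name!r} has no domain structure; domain ranking needs "
                "domain-wise names like 'd8.z1'"
            )
        groups.setdefault(int(m.group(1)), []).append(abs(float(value)))
    agg = {"sum": np.sum, "mean": np.mean, "max": np.max}[aggregate]
    totals = {d: float(agg(v)) for d, v in groups.items()}
    return sorted(totals, key=lambda d: (-totals[d], d))


def consensus_features(
    rank_a: Sequence[int], rank_b: Sequence[int], k: int = 6
) -> list[int]:
    """Intersection of the two rankings' top-k sets, in ``rank_a`` order."""
    universe = set(rank_a) | set(rank_b)
    if k > len(rank_a) or k > len(rank_b):
        raise ValueError(f"k={k} exceeds ranking length")
    if k > len(universe):
        raise ValueError(f"k={k} exceeds domain universe of {len(universe)}")
    top_b = set(rank_b[:k])
    return [d for d in rank_a[:k] if d in top_b]
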