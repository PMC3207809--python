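"""Per-feature stratification power ranking.

Each signature feature is assessed individually: patients are split into
low (bottom 15% of the feature's values), intermediate, and high (top
15%) categories, and the 3-group log-rank statistic measures how well
that single feature stratifies outcome. Features are ranked by descending
chi-square (ties broken by feature id); the split is rank-based, so the
ranking is invariant under strictly increasing transforms of any feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import as_outcome, logrank_test

__all__ = ["FeatureRanking", "stratify_by_feature", "rank_features"]

logger = logging.getLogger(__name__)


@dataclass
class FeatureRanking:
    """Ranked table: per-feature thresholds, chi2, p and rank."""

    table: pd.DataFrame  # columns: feature, low_threshold, high_threshold, chi2, p, rank


def stratify_by_feature(values, low_q: float = 0.15, high_q: float = 0.85) -> np.ndarray:
    """Three-way split of a single feature at its distribution tails.

    Thresholds sit at the ``low_q`` and ``high_q`` linear-interpolation
    quantiles; values equal to a threshold go to the lower group.
    """
    values = np.asarray(values, float)
    if values.shape[0] < 7:
        raise ValueError("need at least 7 samples so each tail is nonempty")
    if np.ptp(values) == 0:
        raise ValueError("constant feature cannot stratify")
    lo, hi = np.quantile(values, [low_q, high_q], method="linear")
    return np.where(values <= lo, "low", np.where(values <= hi, "intermediate", "high"))


def rank_features(features: pd.DataFrame, outcome, low_q: float = 0.15,
                  high_q: float = 0.85) -> FeatureRanking:
    """Rank features by individual 3-group log-rank stratification power.

    Degenerate features (constant, or with an empty tail group) are
    skipped with a logged warning and excluded from the ranks.
    """
    outcome = as_outcome(outcome)
    if len(features) != len(outcome):
        raise ValueError("features and outcome disagree on the number of samples")
    rows = []
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        try:
            labels = stratify_by_feature(vals, low_q, high_q)
            levels = np.unique(labels)
            if levels.size < 2:
                raise ValueError("fewer than two groups")
            res = logrank_test(outcome, labels)
        except ValueError as exc:
            logger.warning("skipping degenerate feature %r: %s", col, exc)
            continue
        lo, hi = np.quantile(vals, [low_q, high_q], method="linear")
        rows.append({"feature": col, "low_threshold": float(lo),
                     "high_threshold": float(hi), "chi2": res.chi2, "p": res.p})
    table = pd.DataFrame(rows, columns=["feature", "low_threshold", "high_threshold",
                                        "chi2", "p"])
    if len(table):
        table = table.sort_values(["chi2", "feature"], ascending=[False, True],
                                  key=lambda s: s if s.name == "chi2" else s.astype(str))
        table = table.reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
    else:
        table["rank"] = []
    return FeatureRanking(table=table)
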