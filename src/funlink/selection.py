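"""Feature screening by ROC AUC against gold-standard labels.

Each feature is scored by the area under the ROC curve when its value
alone is used to separate positive (gold-standard) from negative
(random) gene pairs; features with AUC above a strict threshold
(default 0.6) are selected for classifier training.  The AUC is the
Mann-Whitney probability ``P(score_pos > score_neg) + 0.5 * P(tie)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import FeatureMatrix
from .ids import Pair, canonical_pair


def roc_auc(scores, labels) -> float:
    """Mann-Whitney ROC AUC with the half-tie convention.

    Raises on single-class input or non-finite scores.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = rankdata(s, method="average")
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


@dataclass
class FeatureReport:
    """Per-feature AUC table with the selection decision."""

    frame: pd.DataFrame  # columns: feature, category, auc, n_pos, n_neg, selected
    threshold: float

    @property
    def selected(self) -> list[str]:
        return self.frame.loc[self.frame["selected"], "feature"].tolist()

    @property
    def aucs(self) -> dict[str, float]:
        return dict(zip(self.frame["feature"], self.frame["auc"]))

    def __str__(self) -> str:
        return self.frame.to_string(index=False, float_format=lambda v: f"{v:.4f}")


def select_features(
    matrix: FeatureMatrix,
    positives: set[Pair],
    negatives: set[Pair],
    threshold: float = 0.6,
) -> FeatureReport:
    """Score every feature on the labeled pairs; keep AUC > threshold.

    ``positives`` and ``negatives`` must be disjoint, non-empty, and
    present in the feature matrix.  A constant feature column scores
    exactly 0.5 (all ties) and is never selected under a strict
    threshold above 0.5.
    """
    pos = {canonical_pair(*p) for p in positives}
    neg = {canonical_pair(*p) for p in negatives}
    if not pos or not neg:
        raise ValueError("positives and negatives must both be non-empty")
    if pos & neg:
        raise ValueError("positives and negatives overlap")
    order = [p for p in matrix.pairs if p in pos] + [p for p in matrix.pairs if p in neg]
    missing = (pos | neg) - set(matrix.pairs)
    if missing:
        raise KeyError(f"{len(missing)} labeled pairs absent from the feature matrix")
    rows = np.array([matrix._index[p] for p in order])
    y = np.array([p in pos for p in order])
    records = []
    for k, name in enumerate(matrix.feature_names):
        auc = roc_auc(matrix.values[rows, k], y)
        records.append(
            {
                "feature": name,
                "category": matrix.feature_categories[k],
                "auc": auc,
                "n_pos": int(y.sum()),
                "n_neg": int((~y).sum()),
                "selected": auc > threshold,
            }
        )
    return FeatureReport(frame=pd.DataFrame.from_records(records), threshold=threshold)
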