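"""Mutual-information ranking of proteins against the progression class.

MI between a continuous protein abundance and the binary fast/slow label is
estimated with the nearest-neighbor continuous-discrete estimator (k = 3
neighbors), reported in nats. Estimates are clipped into [0, H(label)]:
mutual information with a discrete label cannot exceed the label entropy, and
the k-NN estimator's sampling noise can stray outside the feasible range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.feature_selection import mutual_info_classif

from .containers import AbundanceMatrix

DEFAULT_K_NEIGHBORS = 3


def label_entropy(labels) -> float:
    """Shannon entropy of the label distribution, in nats."""
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information_cd(
    x, labels, n_neighbors: int = DEFAULT_K_NEIGHBORS, seed: int = 0
) -> float:
    """Nearest-neighbor MI estimate (nats) between continuous x and a
    discrete label; clipped into [0, H(label)]."""
    xv = np.asarray(x, dtype=float)
    y = np.asarray(labels)
    if np.isnan(xv).any():
        raise ValueError("x contains missing values; drop pairwise upstream")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 3:
        raise ValueError("need >= 3 samples per class")
    if np.ptp(xv) == 0:
        return 0.0
    mi = mutual_info_classif(
        xv.reshape(-1, 1),
        y,
        discrete_features=False,
        n_neighbors=n_neighbors,
        random_state=seed,
    )[0]
    return float(np.clip(mi, 0.0, label_entropy(y)))


@dataclass
class MiRanking:
    entries: list  # (protein_id, mi_score) sorted by descending score
    k: int
    label_entropy: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["protein_id", "mi_score"])


def rank_by_mi(
    matrix: AbundanceMatrix,
    sample_labels: pd.Series,
    k: int = 20,
    n_neighbors: int = DEFAULT_K_NEIGHBORS,
    seed: int = 0,
) -> MiRanking:
    """Top-k proteins by MI with the progression label.

    Missing values are dropped pairwise per protein. Ties are broken by
    protein ID for determinism.
    """
    if k > matrix.n_proteins:
        raise ValueError("k exceeds the number of proteins")
    y = sample_labels.loc[matrix.sample_ids]
    scores = []
    for pid_, row in matrix.values.iterrows():
        mask = row.notna().to_numpy()
        if mask.sum() == 0:
            scores.append((pid_, 0.0))
            continue
        yv = y.to_numpy()[mask]
        classes, counts = np.unique(yv, return_counts=True)
        if len(classes) < 2 or counts.min() < 3:
            scores.append((pid_, 0.0))
            continue
        scores.append(
            (pid_, mutual_information_cd(row.to_numpy()[mask], yv,
                                         n_neighbors=n_neighbors, seed=seed))
        )
    scores.sort(key=lambda e: (-e[1], e[0]))
    return MiRanking(entries=scores[:k], k=k, label_entropy=label_entropy(y))
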