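"""Loadings-based interpretation of a fitted TCAM model.

The loadings matrix measures each feature's signed contribution to each
factor.  Two pruning views are provided: the top fraction of features by
absolute loading on a single factor, and the projection of the whole
loadings matrix onto an arbitrary direction in score space (for example
the normal of a linear classifier's decision boundary).  Trajectory
distances and scree data support ordination-style downstream analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tcam_core import TcamModel, loadings_matrix

__all__ = [
    "FeatureRanking",
    "top_loadings_features",
    "project_loadings_direction",
    "pairwise_trajectory_distances",
    "scree_table",
]


@dataclass
class FeatureRanking:
    """Features ordered by descending |contribution| to a factor/direction."""

    feature_ids: list[str]
    contributions: np.ndarray
    source: str

    def __len__(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_ids,
                "source": self.source,
                "contribution": self.contributions,
                "rank": np.arange(1, len(self) + 1),
            }
        )


def _labels(model: TcamModel, p: int) -> list[str]:
    if model.feature_labels is not None:
        return list(model.feature_labels)
    return [f"F{j:04d}" for j in range(p)]


def _rank(labels: list[str], contributions: np.ndarray, keep: int,
          source: str) -> FeatureRanking:
    # descending |contribution|; ties broken by feature label for determinism
    order = sorted(
        range(len(labels)),
        key=lambda j: (-abs(contributions[j]), labels[j]),
    )[:keep]
    return FeatureRanking(
        feature_ids=[labels[j] for j in order],
        contributions=contributions[order],
        source=source,
    )


def top_loadings_features(
    model: TcamModel, factor: int, frac: float
) -> FeatureRanking:
    """The ⌈frac·p⌉ features with largest |loading| on one factor (0-based)."""
    if not 0.0 < frac <= 1.0:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    loadings = loadings_matrix(model)
    if not 0 <= factor < loadings.shape[0]:
        raise ValueError(f"factor must be in [0, {loadings.shape[0]}), got {factor}")
    p = loadings.shape[1]
    keep = math.ceil(frac * p)
    return _rank(_labels(model, p), loadings[factor], keep, f"factor_{factor + 1}")


def project_loadings_direction(
    model: TcamModel, direction: np.ndarray
) -> FeatureRanking:
    """Project loadings onto a direction in score space.

    contribution_j = Σ_h direction_h · loading_{h,j}; useful with the
    normal of a classifier's decision boundary to rank the features that
    drive a separation seen in the scores.
    """
    direction = np.asarray(direction, dtype=float)
    loadings = loadings_matrix(model)
    if direction.shape != (loadings.shape[0],):
        raise ValueError(
            f"direction length {direction.shape} does not match q={loadings.shape[0]}"
        )
    contributions = direction @ loadings
    return _rank(_labels(model, loadings.shape[1]), contributions,
                 loadings.shape[1], "direction")


def pairwise_trajectory_distances(scores: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between score rows.

    At full rank these equal the Frobenius distances between the
    MDF-centered subject trajectories.
    """
    scores = np.asarray(scores, dtype=float)
    return squareform(pdist(scores, metric="euclidean"))


def scree_table(model: TcamModel) -> pd.DataFrame:
    """(factor, variance fraction, cumulative fraction) rows for scree plots."""
    frac = model.explained_variance
    return pd.DataFrame(
        {
            "factor": np.arange(1, len(frac) + 1),
            "explained_variance": frac,
            "cumulative": np.cumsum(frac),
        }
    )
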