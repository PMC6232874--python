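"""Fast correlation-based filter (FCBF) over (band, connection) features.

Every unordered channel pair in every band is one candidate feature (at 19
channels and six bands: 1026 features).  FCBF ranks features by symmetrical
uncertainty with the class label, keeps those above a threshold delta, and
walks the ranked list removing any feature that is predominantly redundant
with an already-kept one (approximate Markov-blanket rule: drop F when a kept
F' has SU(F', F) >= SU(F, class)).

The information measures need discrete variables; continuous coupling values
are discretized into equal-frequency rank bins, which makes the whole
procedure invariant under monotone transformations of a feature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .coupling import CouplingMatrix, symmetrize_directed
from .preprocessing import BAND_ORDER

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "FeatureSet",
    "discretize",
    "symmetrical_uncertainty",
    "fcbf",
    "build_feature_table",
    "feature_band",
]


@dataclass
class FeatureTable:
    """Subjects x (band, connection) coupling values with binary labels."""

    x: pd.DataFrame
    y: np.ndarray
    positive_label: str
    split: str | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.x) != self.y.shape[0]:
            raise ValueError("label vector length must match row count")
        if self.x.isna().any().any():
            raise ValueError("feature table contains missing values")
        if np.unique(self.y).size > 2:
            raise ValueError("labels must be binary")


@dataclass
class FeatureSet:
    """Ordered FCBF-selected features with class-relevance (SU) scores."""

    features: list[str]
    su_scores: list[float] = field(default_factory=list)

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)


def feature_band(name: str) -> str:
    """Band of a ``"band:chanA-chanB"`` feature name."""
    return name.split(":", 1)[0]


def default_n_bins(n: int) -> int:
    """Sturges-style bin count for equal-frequency discretization."""
    return int(math.ceil(math.log2(n))) + 1 if n > 1 else 1


def discretize(values: Sequence[float], n_bins: int) -> np.ndarray:
    """Equal-frequency rank bins; ties share one bin deterministically.

    A constant column collapses to a single bin (zero information, flagged).
    """
    v = np.asarray(values, dtype=np.float64)
    n = v.shape[0]
    if n_bins < 2:
        raise ValueError("need at least two bins")
    if n < n_bins:
        raise ValueError("need at least as many samples as bins")
    if np.all(v == v[0]):
        logger.warning("discretize: constant column collapses to one bin")
        return np.zeros(n, dtype=np.int64)
    ranks = rankdata(v, method="min")  # ties get the smallest rank -> same bin
    labels = ((ranks - 1) * n_bins // n).astype(np.int64)
    if np.unique(labels).size < n_bins:
        logger.debug("discretize: bin count collapsed under ties")
    return labels


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.shape[0]
    return float(-np.sum(p * np.log(p)))


def symmetrical_uncertainty(x: Sequence[int], y: Sequence[int]) -> float:
    """SU(X, Y) = 2 I(X;Y) / (H(X) + H(Y)) in [0, 1]; 0 if either entropy is 0."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("length mismatch")
    if x.shape[0] < 2:
        raise ValueError("need at least two samples")
    h_x = _entropy(x)
    h_y = _entropy(y)
    if h_x == 0.0 or h_y == 0.0:
        return 0.0
    joint = _entropy(x.astype(np.int64) * (np.max(y) + 1) + y.astype(np.int64))
    mi = h_x + h_y - joint
    su = 2.0 * mi / (h_x + h_y)
    return float(min(max(su, 0.0), 1.0))


def _sort_key(name: str) -> tuple:
    band = feature_band(name)
    band_idx = BAND_ORDER.index(band) if band in BAND_ORDER else len(BAND_ORDER)
    return (band_idx, name)


def fcbf(table: FeatureTable, delta: float = 0.0, n_bins: int | None = None) -> FeatureSet:
    """FCBF selection on a (training) feature table.

    Features with SU(feature, class) > delta are ranked by decreasing SU (ties
    broken by canonical band order, then feature name) and kept unless an
    earlier kept feature F' satisfies SU(F', F) >= SU(F, class).
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if table.split == "test":
        raise ValueError("feature selection must not run on test-tagged data")
    if table.x.empty:
        raise ValueError("empty feature table")
    n = len(table.x)
    bins = n_bins or default_n_bins(n)
    y_codes = pd.factorize(table.y)[0]
    disc = {c: discretize(table.x[c].to_numpy(), bins) for c in table.x.columns}
    su_class = {c: symmetrical_uncertainty(disc[c], y_codes) for c in table.x.columns}
    candidates = [c for c in table.x.columns if su_class[c] > delta]
    candidates.sort(key=lambda c: (-su_class[c],) + _sort_key(c))
    kept: list[str] = []
    for cand in candidates:
        redundant = any(
            symmetrical_uncertainty(disc[prev], disc[cand]) >= su_class[cand]
            for prev in kept
        )
        if not redundant:
            kept.append(cand)
    logger.info("fcbf: kept %d of %d candidate features", len(kept), len(candidates))
    return FeatureSet(features=kept, su_scores=[su_class[c] for c in kept])


def build_feature_table(
    subject_matrices: Mapping[str, Sequence[Mapping[str, CouplingMatrix]]],
    positive_label: str,
    split: str | None = None,
) -> FeatureTable:
    """Flatten per-subject band matrices into a subjects x features table.

    Column names are ``"band:chanA-chanB"`` over the upper triangle; directed
    matrices are symmetrized first.  Rows are ordered group by group.
    """
    groups = list(subject_matrices)
    if positive_label not in groups:
        raise ValueError(f"positive label {positive_label!r} not among groups {groups}")
    rows = []
    labels = []
    columns: list[str] | None = None
    for group, subjects in subject_matrices.items():
        for subj in subjects:
            bands = [b for b in BAND_ORDER if b in subj] + [
                b for b in subj if b not in BAND_ORDER
            ]
            values = []
            names = []
            for band in bands:
                mat = subj[band]
                if not mat.symmetric:
                    mat = symmetrize_directed(mat)
                ch = mat.channels
                for i in range(len(ch)):
                    for j in range(i + 1, len(ch)):
                        names.append(f"{band}:{ch[i]}-{ch[j]}")
                        values.append(mat.values[i, j])
            if columns is None:
                columns = names
            elif names != columns:
                raise ValueError("inconsistent feature columns across subjects")
            rows.append(values)
            labels.append(group)
    x = pd.DataFrame(rows, columns=columns)
    return FeatureTable(x=x, y=np.asarray(labels), positive_label=positive_label, split=split)
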