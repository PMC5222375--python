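"""K-nearest-neighbour imputation of missing genotype codes.

Neighbours are samples (genotypes); the distance between two samples is
the mean mismatch over their co-observed markers.  Each missing cell is
filled with the mode of the K nearest samples observed at that marker,
with deterministic tie rules so that runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .calling import MISSING, DiploidCodedMatrix


@dataclass
class ImputeConfig:
    """KNN imputation settings (K = 4 by default)."""

    k: int = 4
    min_shared_markers: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.min_shared_markers < 1:
            raise ValueError("min_shared_markers must be >= 1")


def _mismatch_distances(X: np.ndarray, min_shared: int) -> np.ndarray:
    """Pairwise mean-mismatch distance over co-observed markers.

    Pairs with fewer than ``min_shared`` co-observed markers get
    infinite distance.
    """
    obs = (X != MISSING).astype(np.float64)
    co = obs @ obs.T
    match = np.zeros_like(co)
    for code in (0, 1, 2):
        ind = (X == code).astype(np.float64)
        match += ind @ ind.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = (co - match) / co
    dist[co < min_shared] = np.inf
    np.fill_diagonal(dist, np.inf)  # a sample is never its own neighbour
    return dist


class KNNGenotypeImputer(TransformerMixin, BaseEstimator):
    """Impute MISSING genotype codes from the K most similar samples.

    Parameters
    ----------
    k : int, default=4
        Number of neighbours whose observed codes vote for the value.
    min_shared_markers : int, default=1
        Minimum co-observed markers for a finite sample-pair distance.

    Notes
    -----
    Ties are deterministic: neighbours at equal distance are ordered by
    ascending sample index, and a tied mode among the K votes resolves
    to the value of the single nearest neighbour.  Observed cells are
    never changed, so imputing a complete matrix is the identity and
    the transform is idempotent.
    """

    def __init__(self, k: int = 4, min_shared_markers: int = 1):
        self.k = k
        self.min_shared_markers = min_shared_markers

    def fit(self, X, y=None):
        ImputeConfig(self.k, self.min_shared_markers)  # validate
        X = np.asarray(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X)
        out = X.copy()
        missing_cells = X == MISSING
        if not missing_cells.any():
            return out
        n, p = X.shape
        dist = _mismatch_distances(X, self.min_shared_markers)
        # stable order: distance ascending, sample index breaking ties
        order = np.argsort(dist, axis=1, kind="stable")

        rows_with_missing = np.flatnonzero(missing_cells.any(axis=1))
        for i in rows_with_missing:
            finite = np.isfinite(dist[i, order[i]])
            if finite.sum() < self.k:
                raise ValueError(
                    f"sample {i} shares >= {self.min_shared_markers} observed "
                    f"markers with only {int(finite.sum())} other samples; "
                    f"KNN imputation with k={self.k} is impossible"
                )
        for j in np.flatnonzero(missing_cells.any(axis=0)):
            observed_j = X[:, j] != MISSING
            if not observed_j.any():
                raise ValueError(f"marker column {j} has no observed genotypes")
            for i in np.flatnonzero(missing_cells[:, j]):
                cand = order[i][observed_j[order[i]] & np.isfinite(dist[i, order[i]])]
                neigh = cand[: self.k]
                if neigh.size == 0:
                    raise ValueError(
                        f"sample {i} has no finite-distance neighbour observed at marker {j}"
                    )
                votes = X[neigh, j]
                counts = np.bincount(votes, minlength=3)
                top = counts.max()
                modes = np.flatnonzero(counts == top)
                out[i, j] = modes[0] if modes.size == 1 else votes[0]
        return out

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)


def knn_impute(m: DiploidCodedMatrix, cfg: ImputeConfig | None = None) -> DiploidCodedMatrix:
    """Impute a coded genotype matrix; the result has no MISSING cells."""
    cfg = cfg or ImputeConfig()
    imputer = KNNGenotypeImputer(k=cfg.k, min_shared_markers=cfg.min_shared_markers)
    codes = imputer.fit_transform(m.codes)
    return DiploidCodedMatrix(codes, list(m.sample_ids), list(m.marker_ids))
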