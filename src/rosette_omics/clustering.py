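"""Variance-based feature selection and Monti consensus clustering.

Samples are clustered hierarchically with the ward.D2 convention: Euclidean
distances squared inside the Lance-Williams update, i.e. Ward's minimum
variance criterion on the observations (scipy's 'ward' linkage).  Consensus
clustering repeatedly subsamples the samples without replacement, clusters
each subsample, and records for every sample pair the fraction of co-sampled
runs in which the pair landed in the same cluster.  The final partition cuts a
ward tree built on (1 - consensus) as the distance.  The default resampling
scheme (1000 resamples at fraction 0.8) follows the standard Monti procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .core_io import OmicsMatrix, ValidationError

__all__ = [
    "select_top_variant",
    "ward_d2_cluster",
    "ConsensusResult",
    "consensus_cluster",
    "adjusted_rand_index",
]


def select_top_variant(m: OmicsMatrix, n: int = 1000) -> list[str]:
    """Feature ids with the n largest sample variances (missing ignored).

    Ties are broken by feature id; if n exceeds the feature count, all
    features are returned with a warning.
    """
    var = m.values.var(axis=1, ddof=1, skipna=True)
    if n > len(var):
        warnings.warn(
            f"n={n} exceeds {len(var)} features; returning all", stacklevel=2
        )
        n = len(var)
    order = sorted(var.index, key=lambda f: (-var[f] if not np.isnan(var[f]) else np.inf, f))
    return order[:n]


def _impute_feature_median(values: pd.DataFrame) -> np.ndarray:
    X = values.to_numpy(float)
    if np.isnan(X).any():
        med = np.nanmedian(X, axis=1)
        X = np.where(np.isnan(X), med[:, None], X)
    return X


def ward_d2_cluster(samples_matrix: np.ndarray, k: int) -> np.ndarray:
    """Ward.D2 agglomerative clustering of row-samples, cut to k clusters.

    ``samples_matrix`` is samples x features with complete values.  Labels are
    integers 1..k in scipy's fcluster convention.
    """
    X = np.asarray(samples_matrix, dtype=float)
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValidationError(f"k={k} outside [1, {n}]")
    if np.isnan(X).any():
        raise ValidationError("ward_d2_cluster requires complete values (impute upstream)")
    Z = linkage(X, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


@dataclass
class ConsensusResult:
    """Consensus matrices and assignments per k, plus the chosen cut."""

    matrices: dict[int, pd.DataFrame]
    assignments: dict[int, pd.Series]
    chosen_k: int
    n_resamples: int
    subsample_frac: float
    within_cluster_consensus: dict[int, float] = field(default_factory=dict)

    @property
    def consensus(self) -> pd.DataFrame:
        return self.matrices[self.chosen_k]

    @property
    def labels(self) -> pd.Series:
        return self.assignments[self.chosen_k]


def consensus_cluster(
    m: OmicsMatrix,
    k_range: list[int],
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    seed: int | None = None,
) -> ConsensusResult:
    """Monti consensus clustering of the matrix's samples.

    Per resample, a fraction of samples is drawn without replacement and
    clustered by ward.D2; consensus(i, j) is the co-clustered count over the
    co-sampled count.  The final partition per k cuts a ward tree on
    (1 - consensus); the chosen k maximizes mean within-cluster consensus.
    Missing values are imputed by the feature median before distances.
    """
    samples = m.sample_ids
    n = len(samples)
    if any(k < 2 or k > n - 1 for k in k_range):
        raise ValidationError(f"k_range must lie within [2, {n - 1}]")
    rng = np.random.default_rng(seed)
    X = _impute_feature_median(m.values).T  # samples x features
    n_sub = max(2, int(np.floor(subsample_frac * n)))

    matrices: dict[int, pd.DataFrame] = {}
    assignments: dict[int, pd.Series] = {}
    dispersion: dict[int, float] = {}
    for k in k_range:
        co_clustered = np.zeros((n, n))
        co_sampled = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = np.sort(rng.choice(n, size=n_sub, replace=False))
            labels = ward_d2_cluster(X[idx], min(k, len(idx)))
            co_sampled[np.ix_(idx, idx)] += 1
            for lab in np.unique(labels):
                members = idx[labels == lab]
                co_clustered[np.ix_(members, members)] += 1
        if np.any(co_sampled == 0):
            raise ValidationError(
                "some sample pair was never co-sampled; increase n_resamples"
            )
        consensus = co_clustered / co_sampled
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2.0
        C = pd.DataFrame(consensus, index=samples, columns=samples)
        Z = linkage(squareform(1.0 - consensus, checks=False), method="ward")
        labels_k = pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=samples)
        matrices[k] = C
        assignments[k] = labels_k
        within = []
        for lab in labels_k.unique():
            members = np.flatnonzero((labels_k == lab).to_numpy())
            if len(members) > 1:
                block = consensus[np.ix_(members, members)]
                within.append(block[np.triu_indices(len(members), 1)].mean())
        dispersion[k] = float(np.mean(within)) if within else 1.0

    chosen_k = max(dispersion, key=lambda k: (dispersion[k], -k))
    return ConsensusResult(
        matrices=matrices,
        assignments=assignments,
        chosen_k=chosen_k,
        n_resamples=n_resamples,
        subsample_frac=subsample_frac,
        within_cluster_consensus=dispersion,
    )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Standard ARI: 1 for identical partitions up to relabeling, ~0 at chance."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValidationError("label vectors must share their length")
    return float(adjusted_rand_score(a, b))
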