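"""Unsupervised proteomic subtyping by consensus clustering, plus the
MSI-status differential analysis.

Consensus clustering: repeated k-means on subsampled, row-standardized
data; the consensus matrix holds the fraction of co-sampled runs in which
two samples co-clustered. The number of classes is picked by the elbow of
the relative change in area under the consensus CDF; final labels come from
hierarchical clustering of 1 - consensus at the chosen k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .containers import AbundanceMatrix
from .genomic import permutation_fdr, two_group_scan

__all__ = ["select_variable_features", "consensus_cluster", "msi_differential", "ConsensusResult"]


def select_variable_features(
    matrix: AbundanceMatrix, top_fraction: float = 0.3
) -> list[str]:
    """Most variable features without missing values.

    Features with any missing measurement are dropped, the rest ranked by
    the SD of their log2 profile; the top ``top_fraction`` is returned.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    complete = matrix.data.dropna(axis=0)
    if complete.empty:
        raise ValueError("no feature is quantified in every sample")
    sd = np.log2(complete + 1.0).std(axis=1, ddof=1)
    n_keep = max(1, int(round(top_fraction * len(sd))))
    return list(sd.sort_values(ascending=False, kind="stable").index[:n_keep])


@dataclass
class ConsensusResult:
    """Consensus matrices per k, the chosen k and final labels."""

    consensus: dict[int, pd.DataFrame] = field(default_factory=dict)
    cdf_area: pd.Series | None = None
    delta_area: pd.Series | None = None
    pac: pd.Series | None = None
    chosen_k: int = 0
    labels: pd.Series | None = None
    cluster_consensus: pd.Series | None = None


def _cdf_area(consensus: np.ndarray) -> float:
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = np.sort(consensus[iu])
    # area under the empirical CDF over [0, 1]
    grid = np.concatenate([[0.0], vals, [1.0]])
    cdf = np.searchsorted(vals, grid, side="right") / len(vals)
    return float(np.sum(np.diff(grid) * cdf[:-1]))


def consensus_cluster(
    matrix: AbundanceMatrix,
    features: list[str] | None = None,
    k_range: tuple[int, int] = (2, 8),
    reps: int = 250,
    subsample: float = 0.8,
    seed: int = 0,
    min_pac_drop: float = 1.5,
    pac_bounds: tuple[float, float] = (0.1, 0.9),
) -> ConsensusResult:
    """Consensus k-means class discovery over a sample panel.

    For each k in ``k_range``: ``reps`` k-means runs on a random
    ``subsample`` fraction of samples (row-standardized log2 data; samples
    are the points). consensus_ij = co-clustered count / co-sampled count.

    The number of classes is the elbow of the clustering-ambiguity curve:
    PAC(k), the fraction of consensus entries inside ``pac_bounds``, drops
    sharply when k reaches the true class count and flattens beyond it, so
    the chosen k is the one with the largest relative PAC drop from k-1.
    When no drop reaches ``min_pac_drop`` the panel shows no stable
    multi-class structure and the smallest k is reported. The consensus-CDF
    area curve and its relative gains are also returned so the choice can
    be overridden by inspection.
    """
    k_lo, k_hi = k_range
    if k_lo < 2:
        raise ValueError("k_range must start at 2 or above")
    data = matrix.data if features is None else matrix.data.loc[features]
    if data.isna().any().any():
        raise ValueError("consensus clustering requires complete data; select features first")
    samples = list(data.columns)
    n = len(samples)
    if n < k_hi:
        raise ValueError("more clusters requested than samples")
    z = np.log2(data.to_numpy() + 1.0)
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
    X = z.T  # samples x features
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample * n)))
    result = ConsensusResult()
    areas = {}
    for k in range(k_lo, k_hi + 1):
        together = np.zeros((n, n))
        sampled = np.zeros((n, n))
        for _ in range(reps):
            idx = rng.choice(n, size=m, replace=False)
            km = KMeans(n_clusters=k, n_init="auto",
                        random_state=int(rng.integers(2**31 - 1)))
            labels = km.fit_predict(X[idx])
            sampled[np.ix_(idx, idx)] += 1.0
            for cluster in range(k):
                members = idx[labels == cluster]
                together[np.ix_(members, members)] += 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(sampled > 0, together / sampled, 0.0)
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2.0
        result.consensus[k] = pd.DataFrame(consensus, index=samples, columns=samples)
        areas[k] = _cdf_area(consensus)
    area = pd.Series(areas)
    delta = {}
    for k in area.index:
        delta[k] = area[k] if k == k_lo else (area[k] - area[k - 1]) / area[k - 1]
    delta = pd.Series(delta)
    pac = {}
    for k, frame in result.consensus.items():
        m = frame.to_numpy()
        iu = np.triu_indices(m.shape[0], k=1)
        vals = m[iu]
        pac[k] = float(((vals > pac_bounds[0]) & (vals < pac_bounds[1])).mean())
    pac = pd.Series(pac)
    eps = 1e-6
    drops = {k: (pac[k - 1] + eps) / (pac[k] + eps) for k in pac.index if k > k_lo}
    drops = pd.Series(drops)
    if len(drops) and drops.max() >= min_pac_drop:
        chosen = int(drops.idxmax())
    else:
        chosen = k_lo
    cons = result.consensus[chosen].to_numpy()
    linkage = average(squareform(1.0 - cons, checks=False))
    labels = fcluster(linkage, t=chosen, criterion="maxclust")
    labels = pd.Series(labels, index=samples, name="subtype")
    cc = {}
    for cluster in sorted(labels.unique()):
        members = np.where(labels.to_numpy() == cluster)[0]
        if len(members) > 1:
            sub = cons[np.ix_(members, members)]
            iu = np.triu_indices(len(members), k=1)
            cc[cluster] = float(sub[iu].mean())
        else:
            cc[cluster] = 1.0
    result.cdf_area = area
    result.delta_area = delta
    result.pac = pac
    result.chosen_k = int(chosen)
    result.labels = labels
    result.cluster_consensus = pd.Series(cc)
    return result


def msi_differential(
    matrix: AbundanceMatrix,
    msi_labels: pd.Series,
    fdr: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
    min_group: int = 3,
) -> pd.DataFrame:
    """Welch's t test per feature between MSI-high and MSI-low lines,
    with the pooled-permutation FDR.

    ``msi_labels`` maps sample -> label; the lexicographically *later*
    label ("MSI-H" vs "MSS" sorts MSI-H first) is irrelevant: the group
    tested as "mutated-like" is the MSI-high set, detected as the label
    containing "H" when present, else the rarer label.
    """
    labels = msi_labels.reindex(matrix.sample_ids).dropna()
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"need exactly two MSI labels, got {uniq}")
    high = next((u for u in uniq if "H" in str(u).upper().replace("MSS", "")), None)
    if high is None:
        high = labels.value_counts().idxmin()
    high_samples = set(labels.index[labels == high])
    groups = {f: high_samples for f in matrix.feature_ids}
    observed = two_group_scan(matrix, groups, min_mutated=min_group,
                              min_wildtype=min_group, welch=True)
    if observed.empty:
        observed["q"] = pd.Series(dtype=float)
        return observed
    return permutation_fdr(matrix, groups, observed, n_perm=n_perm, seed=seed, welch=True)
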