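"""Protein co-variation networks, complex-recovery evaluation and weighted
module detection.

The workflow mirrors weighted gene co-expression network analysis applied
to proteomes: pairwise Pearson correlations on log2 scaled intensities
(pairwise-complete), soft-thresholded adjacency ``|r|**power``, topological
overlap (TOM) as the interaction weight, average-linkage clustering of
``1 - TOM`` with a static cut and a minimum module size, module eigengenes
(first principal components) and hypergeometric set enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix, AnnotationCatalog, canonical_pair

__all__ = [
    "CorrelationNetwork",
    "ModulePartition",
    "RocResult",
    "masked_pearson",
    "pairwise_correlation",
    "pair_class_distributions",
    "interaction_roc",
    "roc_auc_from_scores",
    "complex_cohesion",
    "soft_threshold_select",
    "adjacency_and_tom",
    "detect_modules",
    "module_eigengene",
    "module_enrichment",
    "module_module_correlation",
    "export_network",
]


def masked_pearson(
    values: np.ndarray, min_shared: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise Pearson correlations with pairwise-complete observations.

    Returns ``(r, n_shared)``; pairs with fewer than ``min_shared`` shared
    finite samples, or zero variance on the shared support, get NaN.
    Implemented with masked matrix products so the cost is a handful of
    p x p matmuls rather than a Python loop over pairs.
    """
    mask = np.isfinite(values)
    filled = np.where(mask, values, 0.0)
    maskf = mask.astype(float)
    n = maskf @ maskf.T
    sx = filled @ maskf.T          # sum of i's values over support shared with j
    sxx = (filled**2) @ maskf.T
    sxy = filled @ filled.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = sx / n
        cov = sxy / n - mean_x * mean_x.T
        var_x = sxx / n - mean_x**2
        denom = np.sqrt(var_x * var_x.T)
        r = cov / denom
    r[n < min_shared] = np.nan
    r[~np.isfinite(r)] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r, n.astype(int)


@dataclass
class CorrelationNetwork:
    """Dense pairwise-correlation container over the retained features."""

    features: list[str]
    r: np.ndarray          # p x p Pearson matrix, NaN where skipped
    n_shared: np.ndarray   # p x p shared-sample counts
    n_skipped_pairs: int = 0

    def __post_init__(self) -> None:
        self._index = {f: i for i, f in enumerate(self.features)}

    def __contains__(self, feature: str) -> bool:
        return feature in self._index

    def pair_r(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.features), k=1)
        return self.r[iu]

    def edges(self, min_abs_r: float = 0.0) -> pd.DataFrame:
        iu = np.triu_indices(len(self.features), k=1)
        r = self.r[iu]
        keep = np.isfinite(r) & (np.abs(r) >= min_abs_r)
        feats = np.asarray(self.features)
        return pd.DataFrame(
            {
                "feature_a": feats[iu[0][keep]],
                "feature_b": feats[iu[1][keep]],
                "pearson_r": r[keep],
                "n_shared": self.n_shared[iu][keep],
            }
        )


def pairwise_correlation(
    matrix: AbundanceMatrix,
    min_shared: int = 10,
    min_fraction_quantified: float = 0.8,
    log_transform: bool = True,
) -> CorrelationNetwork:
    """Correlation network over features quantified in enough samples.

    Features must be quantified in at least ``min_fraction_quantified`` of
    the samples; correlations are Pearson on log2(x+1), pairwise-complete.
    """
    frac = matrix.data.notna().mean(axis=1)
    kept = matrix.data.index[frac >= min_fraction_quantified]
    if len(kept) < 2:
        raise ValueError("fewer than 2 features pass the quantified-fraction filter")
    values = matrix.data.loc[kept].to_numpy()
    if log_transform:
        values = np.log2(values + 1.0)
    r, n = masked_pearson(values, min_shared=min_shared)
    iu = np.triu_indices(len(kept), k=1)
    skipped = int(np.sum(~np.isfinite(r[iu])))
    return CorrelationNetwork(list(kept), r, n, n_skipped_pairs=skipped)


@dataclass
class PairClassReport:
    mean_annotated: float
    mean_all: float
    n_annotated: int
    n_all: int
    ranksum_p: float
    annotated_r: np.ndarray
    all_r: np.ndarray


def pair_class_distributions(
    network: CorrelationNetwork, catalog: AnnotationCatalog
) -> PairClassReport:
    """Compare correlations of annotated (known-interaction) pairs vs all pairs.

    One-sided Wilcoxon rank-sum (Mann-Whitney) of annotated pairs against
    the remaining pairs; raises when no annotated pair maps onto the network.
    """
    pair_keys = catalog.pair_keys() | catalog.all_set_pairs()
    ann = [
        network.pair_r(a, b)
        for a, b in pair_keys
        if a in network and b in network and np.isfinite(network.pair_r(a, b))
    ]
    if not ann:
        raise ValueError("no annotated pair maps onto the network features")
    all_r = network.upper_triangle()
    all_r = all_r[np.isfinite(all_r)]
    ann = np.asarray(ann)
    rest = np.setdiff1d(all_r, ann) if len(all_r) > len(ann) else all_r
    stat = stats.mannwhitneyu(ann, rest, alternative="greater")
    return PairClassReport(
        mean_annotated=float(ann.mean()),
        mean_all=float(all_r.mean()),
        n_annotated=len(ann),
        n_all=len(all_r),
        ranksum_p=float(stat.pvalue),
        annotated_r=ann,
        all_r=all_r,
    )


@dataclass
class RocResult:
    """ROC sweep plus the rank-statistic AUC (tie-averaged)."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def roc_auc_from_scores(pos: np.ndarray, neg: np.ndarray) -> RocResult:
    """AUC by the Mann-Whitney rank identity with tie-halving.

    Equals the fraction of (positive, negative) pairs ranked concordantly,
    counting ties as one half — identical to a full threshold sweep.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC needs at least one positive and one negative score")
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2.0) / (
        len(pos) * len(neg)
    )
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return RocResult(thresholds, tpr, fpr, float(auc), len(pos), len(neg))


def interaction_roc(
    network: CorrelationNetwork,
    positive_pairs: set[tuple[str, str]],
    max_negatives: int | None = None,
    seed: int = 0,
) -> RocResult:
    """ROC of pairwise correlation as a classifier of known interactions.

    Positives: the supplied canonical pairs present in the network with a
    finite correlation. Negatives: all other finite pairs among the features
    that occur in positive pairs, optionally down-sampled to
    ``max_negatives`` with a fixed seed.
    """
    feats = sorted({g for pair in positive_pairs for g in pair if g in network})
    pos_keys = {
        canonical_pair(a, b)
        for a, b in positive_pairs
        if a in network and b in network
    }
    pos, neg = [], []
    for i, a in enumerate(feats):
        for b in feats[i + 1 :]:
            r = network.pair_r(a, b)
            if not np.isfinite(r):
                continue
            (pos if (a, b) in pos_keys else neg).append(r)
    if max_negatives is not None and len(neg) > max_negatives:
        rng = np.random.default_rng(seed)
        neg = list(rng.choice(np.asarray(neg), size=max_negatives, replace=False))
    return roc_auc_from_scores(np.asarray(pos), np.asarray(neg))


@dataclass
class ComplexCohesion:
    members: list[str]
    median_pairwise_r: float
    member_mean_r: pd.Series
    outliers: list[str]


def complex_cohesion(
    network: CorrelationNetwork, members: list[str], outlier_factor: float = 0.5
) -> ComplexCohesion:
    """Cohesion of one annotated complex within the correlation network.

    A member is an outlier when its mean correlation to the other members
    falls below ``outlier_factor`` (default 50%) of the complex-average of
    that same quantity. Needs >= 3 quantified members.
    """
    present = [m for m in members if m in network]
    if len(present) < 3:
        raise ValueError("complex cohesion needs >= 3 quantified members")
    idx = [network._index[m] for m in present]
    sub = network.r[np.ix_(idx, idx)].copy()
    iu = np.triu_indices(len(present), k=1)
    median_r = float(np.nanmedian(sub[iu]))
    np.fill_diagonal(sub, np.nan)
    member_mean = pd.Series(np.nanmean(sub, axis=1), index=present)
    complex_avg = float(member_mean.mean())
    outliers = list(member_mean.index[member_mean < outlier_factor * complex_avg])
    return ComplexCohesion(present, median_r, member_mean, outliers)


@dataclass
class SoftThresholdResult:
    power: int
    fit_table: pd.DataFrame  # per power: scale-free R^2 (signed), mean k
    used_default: bool


def soft_threshold_select(
    r_matrix: np.ndarray,
    powers: range = range(1, 21),
    rsq_threshold: float = 0.8,
    default_power: int = 6,
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Smallest soft-threshold power whose network looks scale-free.

    For each candidate power the connectivity distribution is binned and
    log10 p(k) regressed on log10 k; the fit R^2 is sign-flipped when the
    slope is positive (a scale-free topology must have a decreasing tail).
    Falls back to ``default_power`` when no power reaches the threshold.
    """
    rows = []
    chosen, used_default = None, False
    absr = np.abs(np.nan_to_num(r_matrix, nan=0.0))
    np.fill_diagonal(absr, 0.0)
    for power in powers:
        a = absr**power
        k = a.sum(axis=1)
        k = k[k > 0]
        if len(k) < n_bins:
            rows.append((power, np.nan, float(k.mean()) if len(k) else 0.0))
            continue
        edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
        which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
        dk, pk = [], []
        for b in range(n_bins):
            in_bin = which == b
            if in_bin.any():
                dk.append(k[in_bin].mean())
                pk.append(in_bin.mean())
        if len(dk) < 3:
            rows.append((power, np.nan, float(k.mean())))
            continue
        x, y = np.log10(dk), np.log10(pk)
        slope, _, rvalue, _, _ = stats.linregress(x, y)
        rsq = float(rvalue**2) * (-1.0 if slope > 0 else 1.0)
        rows.append((power, rsq, float(k.mean())))
        if chosen is None and rsq >= rsq_threshold:
            chosen = power
    if chosen is None:
        chosen, used_default = default_power, True
    table = pd.DataFrame(rows, columns=["power", "scale_free_rsq", "mean_k"])
    return SoftThresholdResult(int(chosen), table, used_default)


def adjacency_and_tom(
    r_matrix: np.ndarray, power: int, signed: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Soft-thresholded adjacency and topological overlap matrix.

    Unsigned (default) adjacency is ``|r|**power``; signed uses
    ``((1+r)/2)**power``. TOM_ij = (sum_u a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij), with unit diagonal; TOM is symmetric and
    lies in [0, 1].
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    r = np.nan_to_num(r_matrix, nan=0.0)
    adjacency = np.abs(r) ** power if not signed else ((1.0 + r) / 2.0) ** power
    np.fill_diagonal(adjacency, 0.0)
    k = adjacency.sum(axis=1)
    shared = adjacency @ adjacency
    min_k = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + adjacency) / (min_k + 1.0 - adjacency)
    tom = np.nan_to_num(tom, nan=0.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    np.fill_diagonal(tom, 1.0)
    np.fill_diagonal(adjacency, 1.0)
    return adjacency, tom


@dataclass
class ModulePartition:
    """Disjoint module labels over features; label 0 means unassigned."""

    labels: pd.Series                      # feature -> module label
    modules: dict[int, list[str]] = field(default_factory=dict)
    eigengenes: pd.DataFrame | None = None  # module x sample, unit variance
    variance_explained: pd.Series | None = None
    enrichment: pd.DataFrame | None = None

    @property
    def sizes(self) -> pd.Series:
        return pd.Series({m: len(v) for m, v in self.modules.items()}, dtype=int)

    @property
    def n_modules(self) -> int:
        return len(self.modules)


def detect_modules(
    tom: np.ndarray,
    feature_ids: list[str],
    min_module_size: int = 3,
    cut_height_fraction: float = 0.995,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static height cut.

    The tree is cut at ``cut_height_fraction`` of the highest merge; clusters
    below ``min_module_size`` are relabelled 0 (unassigned). Module labels
    are assigned 1..K by decreasing size (ties by first member index), so the
    partition is deterministic for a given TOM.
    """
    p = len(feature_ids)
    if p < min_module_size:
        raise ValueError("fewer features than the minimum module size")
    dissim = 1.0 - tom
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    linkage = average(squareform(dissim, checks=False))
    cut = cut_height_fraction * linkage[:, 2].max()
    raw = fcluster(linkage, t=cut, criterion="distance")
    groups: dict[int, list[int]] = {}
    for i, g in enumerate(raw):
        groups.setdefault(int(g), []).append(i)
    kept = [idx for idx in groups.values() if len(idx) >= min_module_size]
    kept.sort(key=lambda idx: (-len(idx), idx[0]))
    labels = np.zeros(p, dtype=int)
    modules: dict[int, list[str]] = {}
    for new_label, idx in enumerate(kept, start=1):
        labels[idx] = new_label
        modules[new_label] = [feature_ids[i] for i in idx]
    return ModulePartition(pd.Series(labels, index=feature_ids), modules)


def module_eigengene(
    matrix: AbundanceMatrix,
    partition: ModulePartition,
    log_transform: bool = True,
) -> ModulePartition:
    """First-PC eigengene per module, sign-anchored and unit-variance.

    Member rows are log2-transformed, z-scored (missing entries imputed at
    the feature mean, i.e. 0 after standardization) and decomposed by SVD;
    the eigengene is the first right singular vector, flipped so its mean
    correlation with the member profiles is positive and scaled to unit
    sample variance. Variance explained is the top squared singular value's
    share. Fills the ``eigengenes``/``variance_explained`` fields in place.
    """
    samples = matrix.sample_ids
    rows, var_expl = {}, {}
    for label, members in partition.modules.items():
        sub = matrix.data.loc[members].to_numpy()
        if log_transform:
            sub = np.log2(sub + 1.0)
        mean = np.nanmean(sub, axis=1, keepdims=True)
        sd = np.nanstd(sub, axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mean) / sd
        z = np.nan_to_num(z, nan=0.0)
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        member_corr = np.array([np.corrcoef(eig, row)[0, 1] for row in z])
        if np.nanmean(member_corr) < 0:
            eig = -eig
        eig = eig / eig.std(ddof=1)
        rows[label] = eig
        var_expl[label] = float(s[0] ** 2 / (s**2).sum())
    partition.eigengenes = pd.DataFrame(rows, index=samples).T
    partition.variance_explained = pd.Series(var_expl)
    return partition


def module_enrichment(
    partition: ModulePartition,
    sets: dict[str, list[str]],
    universe: list[str] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each gene set in each module.

    The universe defaults to all features in the partition; Benjamini-
    Hochberg correction is applied across every (module, set) test. Returns
    a table with overlap counts, p, q and a significance flag at ``fdr``.
    """
    if universe is None:
        universe = list(partition.labels.index)
    universe_set = set(universe)
    M = len(universe_set)
    rows = []
    for label, members in partition.modules.items():
        module_set = set(members) & universe_set
        for set_name, set_members in sets.items():
            in_universe = set(set_members) & universe_set
            if not in_universe:
                continue
            overlap = len(module_set & in_universe)
            p = stats.hypergeom.sf(overlap - 1, M, len(in_universe), len(module_set))
            rows.append(
                (set_name, label, overlap, len(module_set), len(in_universe), float(p))
            )
    table = pd.DataFrame(
        rows, columns=["set", "module", "overlap", "module_size", "set_size", "p"]
    )
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["q"] < fdr
        table = table.sort_values("q", kind="stable").reset_index(drop=True)
    partition.enrichment = table
    return table


def module_module_correlation(eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between module eigengenes across samples."""
    r = np.corrcoef(eigengenes.to_numpy())
    r = np.atleast_2d(r)
    return pd.DataFrame(r, index=eigengenes.index, columns=eigengenes.index)


def export_network(
    tom: np.ndarray,
    feature_ids: list[str],
    r_matrix: np.ndarray | None = None,
    weight_threshold: float = 0.02,
    known_pairs: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Edge list of pairs whose TOM weight exceeds the export threshold.

    Each edge carries the underlying Pearson r (when supplied) and a flag
    marking known interactions.
    """
    iu = np.triu_indices(len(feature_ids), k=1)
    weights = tom[iu]
    keep = weights > weight_threshold
    feats = np.asarray(feature_ids)
    a, b = feats[iu[0][keep]], feats[iu[1][keep]]
    frame = pd.DataFrame({"feature_a": a, "feature_b": b, "weight": weights[keep]})
    if r_matrix is not None:
        frame["pearson_r"] = r_matrix[iu][keep]
    if known_pairs is not None:
        frame["known_interaction"] = [
            canonical_pair(x, y) in known_pairs for x, y in zip(a, b)
        ]
    return frame.sort_values("weight", ascending=False, kind="stable").reset_index(drop=True)
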