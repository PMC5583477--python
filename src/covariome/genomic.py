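"""Genotype-to-abundance association: mutation/CNA impact scans with
permutation-based FDR, zygosity and position effects, covariate
regression-out, propagation subnetworks and QTL mapping/replication.

The workhorse test is the two-group one-way ANOVA of mutated vs wild-type
samples, identical to the pooled-variance t test (F = t^2); multiplicity is
controlled by a pooled-permutation plug-in FDR: sample labels are permuted
within each feature's test, permuted |t| statistics are pooled across
features, and q(t) is the expected number of null statistics above t over
the observed count, monotonized and capped at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix, MutationTable
from .covariation import CorrelationNetwork

__all__ = [
    "two_group_scan",
    "permutation_fdr",
    "lof_scan",
    "missense_scan",
    "driver_scan",
    "hits_overlap",
    "zygosity_effect",
    "position_effect",
    "regress_out",
    "cna_scan",
    "propagation_network",
    "qtl_scan",
    "qtl_replication",
    "variant_hotspot_ranking",
]

log = logging.getLogger(__name__)


def _two_group_t(values: np.ndarray, indicator: np.ndarray, welch: bool = False):
    """t statistic(s) for group (indicator==1) vs rest over rows of a 2-D
    indicator matrix; returns (t, df, effect). Vectorized over permutations."""
    B = np.atleast_2d(indicator).astype(float)
    v = values
    n = len(v)
    S, SS = v.sum(), (v**2).sum()
    n1 = B.sum(axis=1)
    n0 = n - n1
    s1 = B @ v
    s1sq = B @ (v**2)
    m1 = s1 / n1
    m0 = (S - s1) / n0
    ss1 = s1sq - n1 * m1**2
    ss0 = (SS - s1sq) - n0 * m0**2
    ss1 = np.maximum(ss1, 0.0)
    ss0 = np.maximum(ss0, 0.0)
    effect = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            v1, v0 = ss1 / (n1 - 1) / n1, ss0 / (n0 - 1) / n0
            se = np.sqrt(v1 + v0)
            df = (v1 + v0) ** 2 / (v1**2 / (n1 - 1) + v0**2 / (n0 - 1))
            t = effect / se
        else:
            sp2 = (ss1 + ss0) / (n - 2)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
            df = np.full_like(n1, n - 2)
            t = effect / se
    # zero within-group variance in both groups: equal means -> t = 0
    t = np.where((se == 0) & (effect == 0), 0.0, t)
    t = np.where((se == 0) & (effect != 0), np.sign(effect) * np.inf, t)
    return t, df, effect


def two_group_scan(
    matrix: AbundanceMatrix,
    groups: dict[str, set[str]],
    min_mutated: int = 3,
    min_wildtype: int = 3,
    welch: bool = False,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Two-group one-way ANOVA per feature: mutated vs wild-type samples.

    ``groups`` maps feature id -> set of mutated sample ids. Effects are
    differences of log2 group means (mutated - wild-type). Features whose
    group floors are unmet are skipped (logged). Returns a table with
    columns feature, n_mut, n_wt, effect, t, df, p, direction.
    """
    samples = matrix.sample_ids
    sample_pos = {s: i for i, s in enumerate(samples)}
    values = matrix.data.to_numpy()
    if log_transform:
        values = np.log2(values + 1.0)
    rows, skipped = [], 0
    for feature, mutated in groups.items():
        if feature not in matrix.data.index:
            skipped += 1
            continue
        i = matrix.data.index.get_loc(feature)
        v = values[i]
        finite = np.isfinite(v)
        ind = np.zeros(len(samples), dtype=bool)
        for s in mutated:
            if s in sample_pos:
                ind[sample_pos[s]] = True
        ind_f = ind[finite]
        v_f = v[finite]
        n_mut, n_wt = int(ind_f.sum()), int((~ind_f).sum())
        if n_mut < min_mutated or n_wt < min_wildtype:
            skipped += 1
            continue
        t, df, effect = _two_group_t(v_f, ind_f, welch=welch)
        t, df, effect = float(t[0]), float(df[0]), float(effect[0])
        if np.isinf(t):
            p = 0.0
        elif np.isnan(t):
            p = 1.0
        else:
            p = float(2.0 * stats.t.sf(abs(t), df))
        rows.append(
            dict(feature=feature, n_mut=n_mut, n_wt=n_wt, effect=effect,
                 t=t, df=df, p=p, direction="down" if effect < 0 else "up")
        )
    if skipped:
        log.info("two_group_scan: skipped %d feature(s) below group floors", skipped)
    return pd.DataFrame(rows)


def permutation_fdr(
    matrix: AbundanceMatrix,
    groups: dict[str, set[str]],
    observed: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    welch: bool = False,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Pooled-permutation plug-in FDR for a two-group scan.

    For every tested feature the mutated/wild-type labels are permuted
    within that feature's available samples ``n_perm`` times; permuted |t|
    values are pooled over features. q at threshold t is the permutation
    estimate of the expected false-positive count divided by the observed
    count, monotonized to be non-increasing in t and capped at 1. Returns
    ``observed`` with a ``q`` column added (sorted by |t| descending).
    """
    if n_perm < 100:
        log.warning("permutation_fdr: n_perm=%d is low; q estimates will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    samples = matrix.sample_ids
    sample_pos = {s: i for i, s in enumerate(samples)}
    values = matrix.data.to_numpy()
    if log_transform:
        values = np.log2(values + 1.0)
    perm_stats = []
    for feature in observed["feature"]:
        i = matrix.data.index.get_loc(feature)
        v = values[i]
        finite = np.isfinite(v)
        v_f = v[finite]
        ind = np.zeros(len(samples), dtype=bool)
        for s in groups[feature]:
            if s in sample_pos:
                ind[sample_pos[s]] = True
        ind_f = ind[finite]
        n_f, n_mut = len(v_f), int(ind_f.sum())
        # n_perm random re-assignments of the mutated-group size
        order = np.argsort(rng.random((n_perm, n_f)), axis=1)
        perm_ind = order < n_mut
        t, _, _ = _two_group_t(v_f, perm_ind, welch=welch)
        t = t[np.isfinite(t)]
        perm_stats.append(np.abs(t))
    pooled = np.sort(np.concatenate(perm_stats)) if perm_stats else np.array([])
    out = observed.copy()
    abs_t = np.abs(out["t"].to_numpy())
    ordering = np.argsort(-abs_t, kind="stable")
    q = np.ones(len(out))
    m = len(out)
    for rank, idx in enumerate(ordering, start=1):
        thr = abs_t[idx]
        if np.isinf(thr):
            n_null = 0.0
        else:
            n_null = (len(pooled) - np.searchsorted(pooled, thr, side="left")) / n_perm
        q[idx] = min(1.0, n_null / rank)
    # monotonize: q must be non-increasing as |t| increases
    running = 1.0
    for idx in ordering[::-1]:
        running = min(running, q[idx])
        q[idx] = running
    out = out.copy()
    out["q"] = q
    return out.sort_values("t", key=np.abs, ascending=False, kind="stable").reset_index(drop=True)


def _gene_groups(mutations: MutationTable, matrix: AbundanceMatrix) -> dict[str, set[str]]:
    present = set(matrix.data.index)
    return {g: s for g, s in mutations.mutated_samples().items() if g in present}


def _scan_with_fdr(matrix, groups, min_mutated, n_perm, seed, welch=False):
    observed = two_group_scan(matrix, groups, min_mutated=min_mutated, welch=welch)
    if observed.empty:
        observed["q"] = pd.Series(dtype=float)
        return observed
    return permutation_fdr(matrix, groups, observed, n_perm=n_perm, seed=seed, welch=welch)


def lof_scan(matrix: AbundanceMatrix, mutations: MutationTable,
             min_mutated: int = 3, n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Impact of loss-of-function mutations on the mutated gene's abundance."""
    return _scan_with_fdr(matrix, _gene_groups(mutations.lof(), matrix),
                          min_mutated, n_perm, seed)


def missense_scan(matrix: AbundanceMatrix, mutations: MutationTable,
                  min_mutated: int = 3, n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Impact of single-amino-acid substitutions on the gene's abundance."""
    return _scan_with_fdr(matrix, _gene_groups(mutations.missense(), matrix),
                          min_mutated, n_perm, seed)


def driver_scan(matrix: AbundanceMatrix, mutations: MutationTable,
                min_mutated: int = 5, n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Impact of flagged driver mutations (>= 5 mutated lines by default)."""
    return _scan_with_fdr(matrix, _gene_groups(mutations.drivers(), matrix),
                          min_mutated, n_perm, seed)


def hits_overlap(results_a: pd.DataFrame, results_b: pd.DataFrame, fdr: float = 0.1) -> dict:
    """Overlap of significant features between two scans (protein vs mRNA)."""
    hits_a = set(results_a.loc[results_a["q"] < fdr, "feature"])
    hits_b = set(results_b.loc[results_b["q"] < fdr, "feature"])
    return {
        "only_a": sorted(hits_a - hits_b),
        "only_b": sorted(hits_b - hits_a),
        "both": sorted(hits_a & hits_b),
    }


@dataclass
class ZygosityReport:
    deviations: pd.DataFrame  # gene, sample, zygosity, deviation (log2)
    median_het: float
    median_hom: float


def zygosity_effect(matrix: AbundanceMatrix, mutations: MutationTable) -> ZygosityReport:
    """Per-(gene, sample) abundance deviation from the wild-type mean,
    stratified by zygosity of the LoF mutation.

    An empty stratum yields a NaN median rather than an error.
    """
    lof = mutations.lof()
    by_gene = lof.mutated_samples()
    log2 = np.log2(matrix.data + 1.0)
    rows = []
    for _, rec in lof.records.iterrows():
        gene, sample = rec["gene"], rec["sample"]
        if gene not in log2.index or sample not in log2.columns:
            continue
        wt_cols = [s for s in log2.columns if s not in by_gene[gene]]
        wt = log2.loc[gene, wt_cols].dropna()
        val = log2.loc[gene, sample]
        if len(wt) == 0 or pd.isna(val):
            continue
        rows.append(dict(gene=gene, sample=sample, zygosity=rec["zygosity"],
                         rel_position=rec["rel_position"],
                         deviation=float(val - wt.mean())))
    dev = pd.DataFrame(rows, columns=["gene", "sample", "zygosity", "rel_position", "deviation"])
    med = dev.groupby("zygosity")["deviation"].median() if len(dev) else pd.Series(dtype=float)
    return ZygosityReport(dev, float(med.get("het", np.nan)), float(med.get("hom", np.nan)))


def position_effect(deviations: pd.DataFrame) -> tuple[float, float]:
    """Spearman trend of mutation position (0 = N, 1 = C terminus) vs effect.

    A positive rho means C-terminal mutations are less detrimental (less
    negative deviations). Needs >= 10 mutations with known positions.
    """
    dev = deviations.dropna(subset=["rel_position", "deviation"])
    if len(dev) < 10:
        raise ValueError("position_effect needs >= 10 mutations with positions")
    rho, p = stats.spearmanr(dev["rel_position"], dev["deviation"])
    return float(rho), float(p)


def regress_out(
    target: AbundanceMatrix,
    covariate: AbundanceMatrix,
    min_shared_samples: int = 10,
    log_transform: bool = True,
) -> AbundanceMatrix:
    """Per-gene OLS residuals of target abundance on a matched covariate.

    Gene ids are matched exactly between the two matrices; genes without a
    covariate profile, with too few shared samples or a zero-variance
    covariate are passed through mean-centered. Residuals are exactly
    orthogonal to the covariate on the shared support.
    """
    t_log = np.log2(target.data + 1.0) if log_transform else target.data.copy()
    c_log = np.log2(covariate.data + 1.0) if log_transform else covariate.data.copy()
    c_log = c_log.reindex(index=t_log.index, columns=t_log.columns)
    out = np.full(t_log.shape, np.nan)
    tv, cv = t_log.to_numpy(), c_log.to_numpy()
    for i in range(len(t_log)):
        y, x = tv[i], cv[i]
        y_ok = np.isfinite(y)
        both = y_ok & np.isfinite(x)
        if both.sum() >= min_shared_samples and np.nanstd(x[both]) > 1e-12:
            slope, intercept = np.polyfit(x[both], y[both], 1)
            out[i, both] = y[both] - (slope * x[both] + intercept)
        else:
            out[i, y_ok] = y[y_ok] - y[y_ok].mean()
    data = pd.DataFrame(out, index=t_log.index.copy(), columns=t_log.columns)
    return AbundanceMatrix(data, target.meta.copy())


def cna_scan(
    matrix: AbundanceMatrix,
    cna: pd.DataFrame,
    region_genes: dict[str, list[str]],
    region_kind: dict[str, str] | None = None,
    min_altered: int = 3,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Effect of recurrent binary copy-number alterations on contained genes.

    Per region with >= ``min_altered`` altered samples, each contained
    quantified gene is tested altered vs not (two-group ANOVA + permutation
    FDR across all region-gene tests). Rows carry the region's
    amplification/loss label when supplied.
    """
    tests: list[tuple[str, str, set[str]]] = []
    for region in cna.index:
        altered = set(cna.columns[cna.loc[region] > 0])
        if len(altered) < min_altered:
            continue
        for gene in region_genes.get(region, []):
            if gene in matrix.data.index:
                tests.append((region, gene, altered))
    if not tests:
        return pd.DataFrame(
            columns=["feature", "region", "n_mut", "n_wt", "effect", "t", "df", "p", "direction", "q"]
        )
    # distinct (region, gene) tests may reuse a gene; key tests by position
    aug_index = {}
    groups = {}
    rows = []
    for region, gene, altered in tests:
        key = f"{region}::{gene}"
        aug_index[key] = gene
        groups[key] = altered
    # run on a view whose index is the test key
    sub = matrix.data.loc[[aug_index[k] for k in groups]].copy()
    sub.index = list(groups)
    view = AbundanceMatrix(sub)
    result = _scan_with_fdr(view, groups, min_altered, n_perm, seed)
    if result.empty:
        return result
    result["region"] = [k.split("::")[0] for k in result["feature"]]
    result["feature"] = [aug_index[k] for k in result["feature"]]
    if region_kind:
        result["cna_kind"] = result["region"].map(region_kind)
    return result


def propagation_network(
    lof_results: pd.DataFrame,
    network: CorrelationNetwork,
    tom: np.ndarray,
    known_pairs: set[tuple[str, str]],
    p_threshold: float = 0.05,
    co_variation_floor: float = 0.02,
) -> nx.Graph:
    """Mutation-vulnerable subnetworks around LoF-downregulated proteins.

    Nodes: proteins downregulated by LoF mutations (p < ``p_threshold``,
    negative effect) and their partners. Edges require (i) one endpoint to
    be such a hit, (ii) a known interaction, and (iii) network weight (TOM)
    at or above ``co_variation_floor``. Node attributes carry the scan p
    value; connected components are the reported subnetworks.
    """
    hits = lof_results[(lof_results["p"] < p_threshold) & (lof_results["effect"] < 0)]
    hit_p = dict(zip(hits["feature"], hits["p"]))
    graph = nx.Graph()
    feat_index = {f: i for i, f in enumerate(network.features)}
    for a, b in known_pairs:
        if a not in feat_index or b not in feat_index:
            continue
        if a not in hit_p and b not in hit_p:
            continue
        weight = tom[feat_index[a], feat_index[b]]
        if weight >= co_variation_floor:
            graph.add_edge(a, b, weight=float(weight),
                           pearson_r=float(network.pair_r(a, b)))
    for node in graph.nodes:
        graph.nodes[node]["lof_p"] = hit_p.get(node, np.nan)
        graph.nodes[node]["is_hit"] = node in hit_p
    return graph


def qtl_scan(
    variants: pd.DataFrame,
    matrix: AbundanceMatrix,
    layer: str = "protein",
    min_variant_samples: int = 3,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Linear-regression QTL scan of every (variant, gene) pair.

    ``variants`` is a binary variant x sample matrix. Per pair, abundance is
    regressed on the variant indicator (simple OLS); with a binary regressor
    the t statistic is exactly the pooled two-group t (F = t^2). BH q values
    are computed across all tests within the layer.
    """
    common = [s for s in matrix.sample_ids if s in variants.columns]
    if len(common) < 2 * min_variant_samples:
        raise ValueError("too few shared samples between variants and abundances")
    Y = matrix.data[common].to_numpy()
    if log_transform:
        Y = np.log2(Y + 1.0)
    mask = np.isfinite(Y)
    Yf = np.where(mask, Y, 0.0)
    genes = np.asarray(matrix.feature_ids)
    frames = []
    for variant in variants.index:
        x = (variants.loc[variant, common].to_numpy() > 0).astype(float)
        n1 = mask @ x
        n0 = mask @ (1.0 - x)
        s1 = Yf @ x
        s0 = Yf @ (1.0 - x)
        s1sq = (Yf**2) @ x
        s0sq = (Yf**2) @ (1.0 - x)
        ok = (n1 >= min_variant_samples) & (n0 >= min_variant_samples)
        with np.errstate(divide="ignore", invalid="ignore"):
            m1, m0 = s1 / n1, s0 / n0
            ss1 = np.maximum(s1sq - n1 * m1**2, 0.0)
            ss0 = np.maximum(s0sq - n0 * m0**2, 0.0)
            ntot = n1 + n0
            sp2 = (ss1 + ss0) / (ntot - 2)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
            beta = m1 - m0
            t = beta / se
        t = np.where((se == 0) & (beta == 0), 0.0, t)
        t = np.where((se == 0) & (beta != 0), np.sign(beta) * np.inf, t)
        p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), ntot - 2))
        frames.append(
            pd.DataFrame(
                {
                    "variant": variant,
                    "gene": genes[ok],
                    "beta": beta[ok],
                    "t": t[ok],
                    "p": p[ok],
                    "n_carrier": n1[ok].astype(int),
                    "layer": layer,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["variant", "gene", "beta", "t", "p", "n_carrier", "layer"]
    )
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass
class ReplicationReport:
    rates: pd.DataFrame  # discovery_layer, discover_fdr, replicate_fdr, n, n_replicated, rate


def qtl_replication(
    qtl_a: pd.DataFrame,
    qtl_b: pd.DataFrame,
    discover_fdr: float = 0.1,
    replicate_fdr: float = 0.3,
) -> ReplicationReport:
    """Replication rates between two independently tested QTL layers.

    Both scans are restricted to the common (variant, gene) universe and
    their BH q values recomputed within it. For each direction and for both
    discovery stringencies (``discover_fdr`` and ``replicate_fdr``), the
    rate is the fraction of layer-A discoveries that reach
    q < ``replicate_fdr`` in layer B.
    """
    key = ["variant", "gene"]
    a = qtl_a.set_index(key)
    b = qtl_b.set_index(key)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no common (variant, gene) universe between layers")
    a, b = a.loc[common].copy(), b.loc[common].copy()
    a["q"] = multipletests(a["p"], method="fdr_bh")[1]
    b["q"] = multipletests(b["p"], method="fdr_bh")[1]
    layer_a = str(a["layer"].iloc[0]) if "layer" in a else "A"
    layer_b = str(b["layer"].iloc[0]) if "layer" in b else "B"
    rows = []
    for disc_fdr in (discover_fdr, replicate_fdr):
        for (name, disc, rep) in ((layer_a, a, b), (layer_b, b, a)):
            hits = disc.index[disc["q"] < disc_fdr]
            n = len(hits)
            n_rep = int((rep.loc[hits, "q"] < replicate_fdr).sum()) if n else 0
            rows.append((name, disc_fdr, replicate_fdr, n, n_rep, n_rep / n if n else np.nan))
    return ReplicationReport(
        pd.DataFrame(
            rows,
            columns=["discovery_layer", "discover_fdr", "replicate_fdr",
                     "n_discovered", "n_replicated", "rate"],
        )
    )


def variant_hotspot_ranking(qtl: pd.DataFrame, fdr: float = 0.3) -> pd.DataFrame:
    """Variants ranked by their number of q < fdr associations, with the
    cumulative share of all associations per rank."""
    hits = qtl[qtl["q"] < fdr]
    counts = hits.groupby("variant").size().sort_values(ascending=False)
    total = counts.sum()
    out = counts.to_frame("n_associations")
    out["cumulative_share"] = counts.cumsum() / total if total else np.nan
    return out.reset_index()
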