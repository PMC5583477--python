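"""Intensity scaling, reproducibility (CV) metrics and mRNA-protein coupling.

Scaling follows the TMT convention: spectrum intensities are column
(sample) normalized so every sample carries the same total signal, then each
feature row is scaled to mean 100 over its non-missing entries, so a
10-sample row spans at most 0-1000. The two steps are alternated to their
joint fixed point, which makes the operation idempotent; the first iterate
is exactly the classic single pass.

CVs (CV = SD/mean, percent) are computed on the linear scaled intensities;
correlations downstream always use log2(scaled + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix

__all__ = [
    "scale_intensities",
    "compute_cv",
    "detectable_fold_change",
    "mrna_protein_correlation",
    "CvReport",
    "MrnaProteinReport",
]

log = logging.getLogger(__name__)


def scale_intensities(
    raw: AbundanceMatrix,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> AbundanceMatrix:
    """Column-normalize to equal totals, then scale each row to mean 100.

    Alternates the two normalizations until the matrix stops changing
    (relative change < ``tol``), so the result is a fixed point: column
    totals are equal and every row's non-missing mean is exactly 100 (the
    loop always ends on a row step). All-zero or all-missing rows cannot be
    row-scaled; they are dropped with a log entry.

    Raises ``ValueError`` on negative input values.
    """
    values = raw.values.copy()
    if np.nanmin(values) < 0:
        raise ValueError("raw intensities must be non-negative")
    row_ok = np.nansum(values, axis=1) > 0
    row_has_data = np.isfinite(values).any(axis=1)
    keep = row_ok & row_has_data
    if not keep.all():
        dropped = [f for f, k in zip(raw.feature_ids, keep) if not k]
        log.warning("scale_intensities: dropping %d all-zero/all-missing rows: %s",
                    len(dropped), dropped[:10])
        values = values[keep]
    for _ in range(max_iter):
        previous = values.copy()
        col_totals = np.nansum(values, axis=0)
        if (col_totals <= 0).any():
            raise ValueError("column with zero total signal")
        values = values * (col_totals.mean() / col_totals)[None, :]
        row_means = np.nanmean(values, axis=1, keepdims=True)
        values = values * (100.0 / row_means)
        delta = np.nanmax(np.abs(values - previous) / 100.0)
        if delta < tol:
            break
    index = raw.data.index[keep]
    data = pd.DataFrame(values, index=index, columns=raw.data.columns)
    return AbundanceMatrix(data, raw.meta.loc[index].copy())


@dataclass
class CvReport:
    """Per-feature, per-replicate-group coefficients of variation (percent)."""

    cv: pd.DataFrame  # features x replicate groups, percent
    median_per_group: pd.Series
    median: float
    #: fraction of features whose inter-sample CV exceeds their replicate
    #: baseline (median within-group CV); None when no inter-sample matrix
    #: was supplied.
    fraction_exceeding_baseline: float | None = None


def compute_cv(
    matrix: AbundanceMatrix,
    groups: dict[str, str],
    inter_sample: AbundanceMatrix | None = None,
) -> CvReport:
    """CV = SD/mean (percent; sample SD, n-1) per feature per replicate group.

    ``groups`` maps each column of ``matrix`` to its replicate group; every
    group must contain at least two samples. Features with zero mean within
    a group get a missing CV. When ``inter_sample`` is given, each feature's
    CV across those samples is compared with its replicate baseline.
    """
    by_group: dict[str, list[str]] = {}
    for sample, grp in groups.items():
        by_group.setdefault(grp, []).append(sample)
    for grp, cols in by_group.items():
        if len(cols) < 2:
            raise ValueError(f"replicate group {grp!r} has fewer than 2 samples")

    def _cv(frame: pd.DataFrame) -> pd.Series:
        mean = frame.mean(axis=1)
        sd = frame.std(axis=1, ddof=1)
        out = 100.0 * sd / mean
        out[mean == 0] = np.nan
        return out

    cv = pd.DataFrame(
        {grp: _cv(matrix.data[cols]) for grp, cols in sorted(by_group.items())}
    )
    median_per_group = cv.median()
    median = float(np.nanmedian(cv.to_numpy()))
    fraction = None
    if inter_sample is not None:
        baseline = cv.median(axis=1)
        inter = _cv(inter_sample.data)
        common = baseline.index.intersection(inter.index)
        b, i = baseline[common], inter[common]
        ok = b.notna() & i.notna()
        fraction = float((i[ok] > b[ok]).mean())
    return CvReport(cv, median_per_group, median, fraction)


def detectable_fold_change(cv_percent: float) -> float:
    """Smallest reliably detectable fold change, 1 + 2*CV/100.

    A difference of twice the coefficient of variation separates two
    measurements by two baseline SDs; at CV = 25% this is the familiar
    1.5-fold (50%) detection limit.
    """
    if cv_percent < 0:
        raise ValueError("CV must be non-negative")
    return 1.0 + 2.0 * cv_percent / 100.0


@dataclass
class MrnaProteinReport:
    """Gene-wise mRNA-protein Pearson correlations and variability coupling."""

    per_gene: pd.DataFrame  # columns: r, n_shared, sd_protein, sd_mrna
    median_r: float
    variability_spearman_r: float
    variability_spearman_p: float


def mrna_protein_correlation(
    protein: AbundanceMatrix,
    mrna: AbundanceMatrix,
    min_shared_samples: int = 10,
) -> MrnaProteinReport:
    """Per-gene Pearson r between log2 protein and log2 mRNA profiles.

    Uses pairwise-complete observations over the shared samples; genes with
    fewer than ``min_shared_samples`` complete pairs, or zero variance in
    either layer, get a missing r. Also pairs each gene's protein SD with
    its mRNA SD and reports their Spearman correlation (the
    variability-variability comparison).
    """
    genes = protein.data.index.intersection(mrna.data.index)
    samples = protein.data.columns.intersection(mrna.data.columns)
    if len(genes) == 0 or len(samples) == 0:
        raise ValueError("no shared genes/samples between protein and mRNA")
    p = np.log2(protein.data.loc[genes, samples].to_numpy() + 1.0)
    m = np.log2(mrna.data.loc[genes, samples].to_numpy() + 1.0)
    both = np.isfinite(p) & np.isfinite(m)
    n_shared = both.sum(axis=1)
    rows = []
    for i, gene in enumerate(genes):
        mask = both[i]
        x, y = p[i, mask], m[i, mask]
        r = np.nan
        if mask.sum() >= min_shared_samples and x.std() > 0 and y.std() > 0:
            r = float(np.corrcoef(x, y)[0, 1])
        sd_p = float(np.nanstd(p[i][np.isfinite(p[i])], ddof=1)) if np.isfinite(p[i]).sum() > 1 else np.nan
        sd_m = float(np.nanstd(m[i][np.isfinite(m[i])], ddof=1)) if np.isfinite(m[i]).sum() > 1 else np.nan
        rows.append((gene, r, int(n_shared[i]), sd_p, sd_m))
    per_gene = pd.DataFrame(
        rows, columns=["gene", "r", "n_shared", "sd_protein", "sd_mrna"]
    ).set_index("gene")
    median_r = float(per_gene["r"].median())
    ok = per_gene[["sd_protein", "sd_mrna"]].notna().all(axis=1)
    if ok.sum() >= 3:
        rho, pval = stats.spearmanr(per_gene.loc[ok, "sd_protein"], per_gene.loc[ok, "sd_mrna"])
    else:
        rho, pval = np.nan, np.nan
    return MrnaProteinReport(per_gene, median_r, float(rho), float(pval))
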