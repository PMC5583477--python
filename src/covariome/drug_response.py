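"""Pharmacoproteomic drug-response modelling.

Per drug and per molecular layer an elastic-net model predicts log2 IC50
from the layer's features under nested cross-validation: the inner loop
picks the penalty, the outer loop yields out-of-fold predictions, and the
model is called predictive when Pearson r(predicted, observed) exceeds a
threshold (0.4 by default). Because strong drug-efflux transporter
expression dominates many response profiles, responses can be corrected by
regressing log2 IC50 on the mean abundance of the efflux transporter pair,
after which secondary response determinants become visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .containers import AbundanceMatrix
from .genomic import permutation_fdr, two_group_scan

__all__ = [
    "DrugModelReport",
    "elastic_net_cv",
    "fit_drug_models",
    "per_layer_model_census",
    "census_change",
    "efflux_correction",
    "efflux_group_association",
]


@dataclass
class DrugModelReport:
    drug: str
    layer: str
    r: float                     # out-of-fold Pearson r(predicted, observed)
    predictive: bool
    n_samples: int
    selected: pd.Series          # nonzero coefficients (standardized scale)
    alpha: float
    l1_ratio: float


def elastic_net_cv(
    features: pd.DataFrame,
    response: pd.Series,
    l1_ratio: tuple[float, ...] = (0.5,),
    n_alphas: int = 20,
    outer_folds: int = 10,
    inner_folds: int = 5,
    seed: int = 0,
    r_threshold: float = 0.4,
    drug: str = "",
    layer: str = "",
) -> DrugModelReport:
    """Nested-CV elastic net for one (drug, layer) pair.

    ``features`` is feature x sample; ``response`` is indexed by sample.
    Features are standardized inside each training fold only (no leakage);
    the inner ``ElasticNetCV`` selects alpha/l1_ratio, the outer loop
    collects out-of-fold predictions. A constant response or constant
    out-of-fold prediction yields r = NaN and a non-predictive flag.
    Selected features come from a final inner-CV fit on all samples.
    """
    samples = [s for s in features.columns if s in response.index and np.isfinite(response[s])]
    y = response[samples].to_numpy(dtype=float)
    X = features[samples].to_numpy(dtype=float).T  # samples x features
    col_mean = np.nanmean(X, axis=0)
    nan_pos = np.isnan(X)
    if nan_pos.any():
        X[nan_pos] = np.take(col_mean, np.where(nan_pos)[1])
    n = len(samples)
    if n < 20:
        raise ValueError("elastic_net_cv needs >= 20 samples with a response")
    if np.std(y) == 0:
        return DrugModelReport(drug, layer, np.nan, False, n, pd.Series(dtype=float), np.nan, np.nan)

    def _make_model(rs: int) -> ElasticNetCV:
        return ElasticNetCV(
            l1_ratio=list(l1_ratio), alphas=n_alphas,
            cv=KFold(inner_folds, shuffle=True, random_state=rs),
            max_iter=5000, random_state=rs,
        )

    outer = KFold(outer_folds, shuffle=True, random_state=seed)
    pred = np.empty(n)
    with warnings.catch_warnings():
        # small-n coordinate-descent paths routinely stop at loose duality
        # gaps; the fitted models are fine for out-of-fold scoring
        warnings.simplefilter("ignore", ConvergenceWarning)
        for fold, (train, test) in enumerate(outer.split(X)):
            scaler = StandardScaler().fit(X[train])
            model = _make_model(seed + 1 + fold)
            model.fit(scaler.transform(X[train]), y[train])
            pred[test] = model.predict(scaler.transform(X[test]))
        if np.std(pred) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(pred, y)[0, 1])
        final = _make_model(seed)
        scaler = StandardScaler().fit(X)
        final.fit(scaler.transform(X), y)
    coefs = pd.Series(final.coef_, index=features.index)
    selected = coefs[coefs != 0]
    predictive = bool(np.isfinite(r) and r > r_threshold)
    return DrugModelReport(
        drug, layer, r, predictive, n, selected,
        float(final.alpha_), float(final.l1_ratio_),
    )


def fit_drug_models(
    layers: dict[str, pd.DataFrame],
    ic50: pd.DataFrame,
    seed: int = 0,
    r_threshold: float = 0.4,
    **kwargs,
) -> pd.DataFrame:
    """Fit one elastic-net model per (drug, layer); returns a tidy table."""
    rows = []
    for d_i, drug in enumerate(ic50.index):
        response = ic50.loc[drug]
        for l_i, (layer, feats) in enumerate(sorted(layers.items())):
            report = elastic_net_cv(
                feats, response, seed=seed + 1000 * d_i + l_i,
                r_threshold=r_threshold, drug=drug, layer=layer, **kwargs,
            )
            rows.append(
                dict(drug=drug, layer=layer, r=report.r, predictive=report.predictive,
                     n_features_selected=len(report.selected),
                     top_feature=report.selected.abs().idxmax() if len(report.selected) else "")
            )
    return pd.DataFrame(rows)


def per_layer_model_census(reports: pd.DataFrame, threshold: float = 0.4) -> dict:
    """Tabulate predictive models per layer and the layer-overlap matrix."""
    rep = reports.copy()
    rep["predictive"] = rep["r"].fillna(-np.inf) > threshold
    per_layer = rep.groupby("layer")["predictive"].sum().astype(int)
    predictive_drugs = rep[rep["predictive"]].groupby("drug")["layer"].apply(set)
    layers = sorted(rep["layer"].unique())
    overlap = pd.DataFrame(0, index=layers, columns=layers, dtype=int)
    for layer_set in predictive_drugs:
        for a in layer_set:
            for b in layer_set:
                overlap.loc[a, b] += 1
    return {
        "per_layer": per_layer,
        "n_predictive_drugs": int(len(predictive_drugs)),
        "predictive_drugs": set(predictive_drugs.index),
        "layer_overlap": overlap,
    }


def census_change(pre: pd.DataFrame, post: pd.DataFrame, threshold: float = 0.4) -> dict:
    """Newly/lost predictive models after a response correction.

    Models are counted at the (drug, layer) level, matching a per-data-type
    census. ``n_ever_predictive_models`` counts models predictive in either
    analysis — the cumulative count that grows when the correction uncovers
    additional response determinants; drug-level sets are reported too.
    """
    pre_census = per_layer_model_census(pre, threshold)
    post_census = per_layer_model_census(post, threshold)

    def _model_set(rep: pd.DataFrame) -> set[tuple[str, str]]:
        flagged = rep["r"].fillna(-np.inf) > threshold
        return set(map(tuple, rep.loc[flagged, ["drug", "layer"]].to_numpy()))

    pre_models, post_models = _model_set(pre), _model_set(post)
    pre_drugs = pre_census["predictive_drugs"]
    post_drugs = post_census["predictive_drugs"]
    return {
        "pre": pre_census,
        "post": post_census,
        "newly_predictive_models": sorted(post_models - pre_models),
        "lost_models": sorted(pre_models - post_models),
        "n_ever_predictive_models": len(pre_models | post_models),
        "n_pre_predictive_models": len(pre_models),
        "newly_predictive_drugs": sorted(post_drugs - pre_drugs),
        "n_ever_predictive_drugs": len(pre_drugs | post_drugs),
        "n_pre_predictive_drugs": len(pre_drugs),
    }


def efflux_covariate(protein: AbundanceMatrix, efflux_genes: list[str]) -> pd.Series:
    """Mean of the z-scored log2 profiles of the efflux transporter pair."""
    missing = [g for g in efflux_genes if g not in protein.data.index]
    if missing:
        raise ValueError(f"efflux genes not quantified: {missing}")
    prof = np.log2(protein.data.loc[efflux_genes] + 1.0)
    z = prof.sub(prof.mean(axis=1), axis=0).div(prof.std(axis=1), axis=0)
    return z.mean(axis=0)


def efflux_correction(
    ic50: pd.DataFrame,
    protein: AbundanceMatrix,
    efflux_genes: list[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-drug OLS residuals of log2 IC50 on the efflux covariate.

    Returns the corrected (residual) drug x sample matrix together with the
    covariate; residuals are exactly orthogonal to the covariate per drug.
    """
    cov = efflux_covariate(protein, efflux_genes)
    common = [s for s in ic50.columns if s in cov.index]
    x = cov[common].to_numpy()
    corrected = pd.DataFrame(np.nan, index=ic50.index, columns=common)
    for drug in ic50.index:
        y = ic50.loc[drug, common].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() >= 3 and np.std(x[ok]) > 0:
            slope, intercept = np.polyfit(x[ok], y[ok], 1)
            corrected.loc[drug, np.asarray(common)[ok]] = y[ok] - (slope * x[ok] + intercept)
        else:
            corrected.loc[drug, np.asarray(common)[ok]] = y[ok] - np.nanmean(y[ok])
    return corrected, cov[common]


def efflux_group_association(
    ic50: pd.DataFrame,
    efflux_cov: pd.Series,
    fdr: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Drugs whose response separates low vs high efflux-expression lines.

    Samples are split at the median of the efflux covariate; each drug's
    log2 IC50 is tested high vs low (two-group ANOVA) with the
    pooled-permutation FDR. Returns the association table with q values and
    a significance flag at ``fdr``.
    """
    common = [s for s in ic50.columns if s in efflux_cov.index]
    cov = efflux_cov[common]
    high = set(cov.index[cov > cov.median()])
    matrix = AbundanceMatrix(ic50[common].copy())
    groups = {d: high for d in ic50.index}
    observed = two_group_scan(matrix, groups, min_mutated=3, log_transform=False)
    if observed.empty:
        observed["q"] = pd.Series(dtype=float)
        return observed
    out = permutation_fdr(matrix, groups, observed, n_perm=n_perm, seed=seed,
                          log_transform=False)
    out["significant"] = out["q"] < fdr
    return out
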