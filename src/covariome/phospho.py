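"""Net-phosphorylation estimation and kinase/phosphatase co-phosphorylation.

Phosphopeptide profiles track their parent protein's abundance; to expose
regulatory (net) phosphorylation each peptide's log2 profile is regressed
on the parent protein's log2 profile and replaced by the OLS residuals.
Co-phosphorylation networks are then plain correlation networks over the
residual profiles of kinase/phosphatase peptides with a BH-controlled
correlation test per pair.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix
from .covariation import masked_pearson

__all__ = ["correct_phospho", "cophosphorylation_network"]


def correct_phospho(
    phospho: AbundanceMatrix,
    protein: AbundanceMatrix,
    phospho_map: pd.DataFrame,
    min_shared_samples: int = 10,
) -> AbundanceMatrix:
    """Residual (net) phosphorylation after removing parent-protein trends.

    Per peptide: OLS of log2 phosphopeptide on log2 parent protein across
    the samples where both are quantified; the output holds the mean-zero
    residuals. Peptides without a mapped/quantified parent, with too few
    shared samples or with a zero-variance parent are passed through
    mean-centered and flagged (``corrected = False`` in ``meta``).
    """
    parent_of = dict(zip(phospho_map["peptide"], phospho_map["parent"]))
    ph = np.log2(phospho.data.to_numpy() + 1.0)
    out = np.full_like(ph, np.nan)
    corrected_flags = []
    prot_log2 = np.log2(protein.data + 1.0)
    for i, pep in enumerate(phospho.feature_ids):
        y = ph[i]
        y_ok = np.isfinite(y)
        parent = parent_of.get(pep)
        x = None
        if parent is not None and parent in prot_log2.index:
            x = prot_log2.loc[parent].to_numpy()
        if x is not None:
            both = y_ok & np.isfinite(x)
            # the epsilon guards against float fuzz on constant parents
            if both.sum() >= min_shared_samples and np.nanstd(x[both]) > 1e-12:
                xs, ys = x[both], y[both]
                slope, intercept = np.polyfit(xs, ys, 1)
                out[i, both] = ys - (slope * xs + intercept)
                corrected_flags.append(True)
                continue
        out[i, y_ok] = y[y_ok] - y[y_ok].mean()
        corrected_flags.append(False)
    meta = phospho.meta.copy()
    meta["parent"] = [parent_of.get(p, "") for p in phospho.feature_ids]
    meta["corrected"] = corrected_flags
    data = pd.DataFrame(out, index=phospho.data.index.copy(), columns=phospho.data.columns)
    return AbundanceMatrix(data, meta)


def cophosphorylation_network(
    residuals: AbundanceMatrix,
    enzyme_peptides: list[str],
    fdr: float = 0.1,
    min_shared_samples: int = 10,
) -> pd.DataFrame:
    """Signed co-phosphorylation edges among kinase/phosphatase peptides.

    All pairwise Pearson correlations of the residual profiles, two-sided
    correlation-test p values (t transform of r with n-2 df), BH correction
    across the full pair list; rows carry a positive/negative sign label and
    a significance flag at ``fdr``.
    """
    present = [p for p in enzyme_peptides if p in residuals.data.index]
    if len(present) < 2:
        raise ValueError("need at least 2 quantified enzyme peptides")
    values = residuals.data.loc[present].to_numpy()
    r, n = masked_pearson(values, min_shared=min_shared_samples)
    iu = np.triu_indices(len(present), k=1)
    rr, nn = r[iu], n[iu]
    ok = np.isfinite(rr) & (nn > 2)
    feats = np.asarray(present)
    rr, nn = rr[ok], nn[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt((nn - 2) / np.clip(1.0 - rr**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), nn - 2)
    edges = pd.DataFrame(
        {
            "peptide_a": feats[iu[0][ok]],
            "peptide_b": feats[iu[1][ok]],
            "pearson_r": rr,
            "n_shared": nn,
            "p": p,
        }
    )
    if len(edges):
        edges["q"] = multipletests(edges["p"], method="fdr_bh")[1]
        edges["sign"] = np.where(edges["pearson_r"] > 0, "positive", "negative")
        edges["significant"] = edges["q"] < fdr
        edges = edges.sort_values("q", kind="stable").reset_index(drop=True)
    return edges
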