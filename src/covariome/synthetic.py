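"""Synthetic multi-omic cohort generator with a planted ground-truth ledger.

Emulates a 50-sample cancer cell-line panel profiled at the protein, mRNA
and phosphopeptide level, with the statistical structure the pipeline is
designed to detect:

* protein complexes as shared latent factors (pairwise co-variation within
  a complex, target Pearson r configurable; occasional outlier subunits
  with strongly reduced loading),
* gene-wise mRNA-protein coupling with a per-gene target correlation,
* zygosity-dependent loss-of-function (LoF) mutation effects on the mutated
  gene's protein and mRNA, propagating to complex partners at the protein
  level only (post-transcriptional propagation),
* stabilizing missense mutations (TP53-like protein gain with quiet mRNA),
* binary copy-number alterations with log2 dosage effects on both layers,
* discrete proteomic subtypes as mean shifts on disjoint protein blocks
  (subtype 1 doubles as the MSI-high group),
* phosphopeptides riding on their parent protein plus shared kinase latents,
* drug IC50 profiles driven by an efflux-transporter pair, by secondary
  genomic markers masked by efflux, by plain protein markers, or by nothing.

Everything is emitted both as analysis-ready containers and as a
:class:`GroundTruth` record so recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, AnnotationCatalog, MutationTable

__all__ = ["CohortSpec", "GroundTruth", "SyntheticCohort", "generate_cohort", "null_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters; the defaults are the study conditions.

    Effect sizes (``delta_het``, ``delta_hom``, ``subtype_shift``,
    ``stabilizing_effect``) are in units of the feature's own log2 noise SD;
    ``cna_dosage`` is an absolute log2 shift (one copy ~ +/-0.5).
    """

    n_samples: int = 50
    n_proteins: int = 2000
    n_complexes: int = 40
    complex_size_range: tuple[int, int] = (3, 20)
    within_complex_r: float = 0.6
    loading_jitter: float = 0.05
    outlier_every: int = 5
    mrna_coupling_mean: float = 0.5
    mrna_coupling_sd: float = 0.15
    n_lof_genes: int = 20
    n_missense_genes: int = 12
    n_stabilizing_genes: int = 2
    delta_het: float = 1.0
    delta_hom: float = 2.0
    stabilizing_effect: float = 1.5
    mutated_range: tuple[int, int] = (8, 16)
    marker_mutated_range: tuple[int, int] = (15, 25)
    position_attenuation: float = 0.0
    propagation_fraction: float = 0.5
    n_cna_regions: int = 10
    cna_genes_per_region: int = 4
    cna_dosage: float = 0.5
    cna_samples_range: tuple[int, int] = (5, 12)
    n_subtypes: int = 5
    subtype_block_size: int = 50
    subtype_shift: float = 2.0
    n_phospho: int = 400
    phospho_alpha: float = 1.0
    n_kinase_groups: int = 8
    peptides_per_kinase: int = 5
    kinase_beta: float = 0.85
    n_drugs: int = 40
    n_efflux_drugs: int = 10
    n_secondary_drugs: int = 6
    n_protein_marker_drugs: int = 6
    efflux_r: float = 0.92
    efflux_share: float = 0.7
    secondary_efflux_share: float = 0.65
    secondary_marker_share: float = 0.13
    protein_marker_share: float = 0.5
    feature_sd_range: tuple[float, float] = (0.4, 1.0)
    missing_feature_fraction: float = 0.15
    missing_cell_rate: float = 1.0 / 3.0
    n_replicate_lines: int = 6
    replicate_noise_sd: float = 0.15
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_proteins, self.n_complexes) <= 0:
            raise ValueError("sizes must be positive")
        if not (self.delta_hom >= self.delta_het >= 0):
            raise ValueError("need delta_hom >= delta_het >= 0")
        if not 0 <= self.propagation_fraction <= 1:
            raise ValueError("propagation_fraction must be in [0, 1]")
        if not -1 < self.mrna_coupling_mean < 1:
            raise ValueError("mrna_coupling_mean must be in (-1, 1)")
        if not 0 <= self.within_complex_r < 1:
            raise ValueError("within_complex_r must be in [0, 1)")
        lo, hi = self.complex_size_range
        if lo < 2 or hi < lo:
            raise ValueError("invalid complex_size_range")

    def replace(self, **kwargs) -> "CohortSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted structure, recorded so downstream recovery can be scored."""

    complexes: dict[str, list[str]] = field(default_factory=dict)
    outlier_subunits: dict[str, str] = field(default_factory=dict)
    mrna_coupling: pd.Series | None = None
    lof_genes: list[str] = field(default_factory=list)
    missense_genes: list[str] = field(default_factory=list)
    stabilizing_genes: list[str] = field(default_factory=list)
    marker_genes: list[str] = field(default_factory=list)
    mutation_effects: pd.DataFrame | None = None
    propagated_partners: dict[str, list[str]] = field(default_factory=dict)
    cna_regions: dict[str, dict] = field(default_factory=dict)
    subtype_labels: pd.Series | None = None
    subtype_signature: dict[int, list[str]] = field(default_factory=dict)
    msi_labels: pd.Series | None = None
    efflux_genes: list[str] = field(default_factory=list)
    drug_truth: pd.DataFrame | None = None
    kinase_groups: dict[str, list[str]] = field(default_factory=dict)
    anti_regulated_pair: tuple[str, str] | None = None


@dataclass
class SyntheticCohort:
    """Bundle of emitted matrices, annotations and the ground truth."""

    spec: CohortSpec
    protein: AbundanceMatrix
    mrna: AbundanceMatrix
    phospho: AbundanceMatrix
    phospho_map: pd.DataFrame
    enzymes: list[str]
    mutations: MutationTable
    cna: pd.DataFrame
    ic50: pd.DataFrame
    annotations: AnnotationCatalog
    replicate_protein: AbundanceMatrix
    replicate_groups: dict[str, str]
    truth: GroundTruth

    def genomic_layer(self) -> pd.DataFrame:
        """Binary variant x sample feature matrix (driver mutations + CNAs)."""
        samples = self.protein.sample_ids
        rows: dict[str, np.ndarray] = {}
        drivers = self.mutations.drivers()
        for gene, muts in sorted(drivers.mutated_samples().items()):
            vec = np.array([1.0 if s in muts else 0.0 for s in samples])
            rows[f"mut:{gene}"] = vec
        for region in self.cna.index:
            rows[f"cna:{region}"] = self.cna.loc[region].to_numpy(dtype=float)
        return pd.DataFrame(rows, index=samples).T


def _scale_rows_to_100(log2_values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """2**log2 intensities, missing applied, each row's non-missing mean 100."""
    intensities = np.power(2.0, log2_values)
    intensities[mask] = np.nan
    row_mean = np.nanmean(intensities, axis=1, keepdims=True)
    return intensities * (100.0 / row_mean)


def generate_cohort(spec: CohortSpec | None = None) -> SyntheticCohort:
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_proteins
    samples = [f"S{i + 1:03d}" for i in range(n)]
    genes = [f"G{i + 1:05d}" for i in range(p)]
    truth = GroundTruth()

    # ---- lay out the feature blocks ------------------------------------
    lo, hi = spec.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_complexes)
    cursor = 0
    complex_members: list[list[int]] = []
    for size in sizes:
        complex_members.append(list(range(cursor, cursor + int(size))))
        cursor += int(size)
    n_subtype_block = spec.n_subtypes * spec.subtype_block_size
    reserved = (
        cursor
        + n_subtype_block
        + 2  # efflux pair
        + spec.n_protein_marker_drugs
        + spec.n_cna_regions * spec.cna_genes_per_region
        + spec.n_kinase_groups
        + spec.n_missense_genes
    )
    if reserved > p:
        raise ValueError(
            f"infeasible spec: planted structure needs {reserved} proteins,"
            f" only {p} available"
        )
    subtype_blocks = [
        list(range(cursor + k * spec.subtype_block_size, cursor + (k + 1) * spec.subtype_block_size))
        for k in range(spec.n_subtypes)
    ]
    cursor += n_subtype_block
    efflux_idx = [cursor, cursor + 1]
    cursor += 2
    protein_marker_idx = list(range(cursor, cursor + spec.n_protein_marker_drugs))
    cursor += spec.n_protein_marker_drugs
    cna_gene_idx = [
        list(range(cursor + r * spec.cna_genes_per_region, cursor + (r + 1) * spec.cna_genes_per_region))
        for r in range(spec.n_cna_regions)
    ]
    cursor += spec.n_cna_regions * spec.cna_genes_per_region
    kinase_idx = list(range(cursor, cursor + spec.n_kinase_groups))
    cursor += spec.n_kinase_groups
    missense_idx = list(range(cursor, cursor + spec.n_missense_genes))
    cursor += spec.n_missense_genes

    # ---- latent random structure ---------------------------------------
    sd_lo, sd_hi = spec.feature_sd_range
    sd_g = rng.uniform(sd_lo, sd_hi, size=p)
    core = rng.standard_normal((p, n))  # unit-variance idiosyncratic noise
    loading_base = np.sqrt(spec.within_complex_r) if spec.within_complex_r > 0 else 0.0
    for ci, members in enumerate(complex_members):
        factor = rng.standard_normal(n)
        loadings = loading_base * (
            1.0 + rng.uniform(-spec.loading_jitter, spec.loading_jitter, size=len(members))
        )
        if spec.outlier_every and (ci + 1) % spec.outlier_every == 0:
            # planted outlier subunit: a halved loading would put its mean
            # correlation exactly at the 50%-of-complex-average outlier
            # boundary (r scales with the loading), so plant it clearly below;
            # the last member is used so it never doubles as the LoF hub
            loadings[-1] *= 0.3
            truth.outlier_subunits[f"CPX{ci + 1:03d}"] = genes[members[-1]]
        loadings = np.clip(loadings, 0.0, 0.999)
        for g, lam in zip(members, loadings):
            core[g] = lam * factor + np.sqrt(1.0 - lam**2) * core[g]
    # efflux transporter pair: shared latent, pairwise r ~ efflux_r
    efflux_latent = rng.standard_normal(n)
    lam_e = np.sqrt(spec.efflux_r)
    for g in efflux_idx:
        core[g] = lam_e * efflux_latent + np.sqrt(1.0 - lam_e**2) * core[g]
    truth.efflux_genes = [genes[g] for g in efflux_idx]
    truth.complexes = {
        f"CPX{ci + 1:03d}": [genes[g] for g in members]
        for ci, members in enumerate(complex_members)
    }

    # ---- subtypes (protein-level mean shifts on disjoint blocks) -------
    subtype_labels = np.arange(n) % spec.n_subtypes + 1  # balanced classes
    subtype_labels = rng.permutation(subtype_labels)
    shift_units = np.zeros((p, n))
    for k, block in enumerate(subtype_blocks, start=1):
        in_subtype = subtype_labels == k
        for g in block:
            shift_units[g, in_subtype] += spec.subtype_shift
            # subtype markers are highly variable proteins by construction;
            # that is what makes top-variance feature selection retrieve them
            sd_g[g] = rng.uniform(0.5 * (sd_lo + sd_hi), sd_hi)
        truth.subtype_signature[k] = [genes[g] for g in block]
    truth.subtype_labels = pd.Series(subtype_labels, index=samples, name="subtype")
    truth.msi_labels = pd.Series(
        np.where(subtype_labels == 1, "MSI-H", "MSS"), index=samples, name="msi"
    )

    # ---- mutations -----------------------------------------------------
    lof_idx = [members[0] for members in complex_members[: spec.n_lof_genes]]
    if len(lof_idx) < spec.n_lof_genes:
        raise ValueError("infeasible spec: fewer complexes than requested LoF genes")
    stabilizing_idx = missense_idx[: spec.n_stabilizing_genes]
    plain_missense_idx = missense_idx[spec.n_stabilizing_genes :]
    marker_idx = plain_missense_idx[: spec.n_secondary_drugs]

    mut_records: list[dict] = []
    effect_records: list[dict] = []
    lof_classes = ["frameshift", "nonsense", "inframe", "splice_site", "startstop_loss"]
    mrna_shift_units = np.zeros((p, n))

    def _plant_mutation(gidx: int, variant_class: str, n_mut_range: tuple[int, int],
                        effect_units: float, is_driver: bool, affects_mrna: bool,
                        propagate_from: list[int] | None = None) -> None:
        gene = genes[gidx]
        n_mut = int(rng.integers(n_mut_range[0], n_mut_range[1] + 1))
        mut_samples = rng.choice(n, size=n_mut, replace=False)
        for s in mut_samples:
            zyg = "hom" if rng.random() < 0.5 else "het"
            rel_pos = float(rng.uniform(0, 1))
            if effect_units < 0:
                scale = spec.delta_hom if zyg == "hom" else spec.delta_het
                eff = -scale * (1.0 - spec.position_attenuation * rel_pos)
            else:
                eff = effect_units
            shift_units[gidx, s] += eff
            if affects_mrna:
                mrna_shift_units[gidx, s] += eff
            if propagate_from is not None:
                for partner in propagate_from:
                    shift_units[partner, s] += eff * spec.propagation_fraction
            mut_records.append(
                dict(gene=gene, sample=samples[s],
                     variant_class=variant_class if variant_class != "lof"
                     else lof_classes[int(rng.integers(len(lof_classes)))],
                     zygosity=zyg, rel_position=rel_pos, is_driver=is_driver)
            )
            effect_records.append(
                dict(gene=gene, sample=samples[s], zygosity=zyg, effect_sd=eff)
            )

    for ci, gidx in enumerate(lof_idx):
        partners = [g for g in complex_members[ci] if g != gidx]
        _plant_mutation(gidx, "lof", spec.mutated_range, -1.0, True, True, partners)
        truth.propagated_partners[genes[gidx]] = [genes[g] for g in partners]
    for gidx in stabilizing_idx:
        _plant_mutation(gidx, "missense", spec.mutated_range, spec.stabilizing_effect, True, False)
    for gidx in marker_idx:
        _plant_mutation(gidx, "missense", spec.marker_mutated_range, 0.0, True, False)
    for gidx in plain_missense_idx[spec.n_secondary_drugs :]:
        _plant_mutation(gidx, "missense", spec.mutated_range, 0.0, False, False)
    truth.lof_genes = [genes[g] for g in lof_idx]
    truth.stabilizing_genes = [genes[g] for g in stabilizing_idx]
    truth.marker_genes = [genes[g] for g in marker_idx]
    truth.missense_genes = [genes[g] for g in plain_missense_idx]
    truth.mutation_effects = pd.DataFrame(effect_records)
    mutations = MutationTable(pd.DataFrame(mut_records))

    # ---- copy-number alterations ---------------------------------------
    cna_rows = []
    cna_log2 = np.zeros((p, n))
    for r, gene_block in enumerate(cna_gene_idx):
        region = f"REG{r + 1:02d}"
        kind = "amp" if r % 2 == 0 else "loss"
        n_alt = int(rng.integers(spec.cna_samples_range[0], spec.cna_samples_range[1] + 1))
        altered = rng.choice(n, size=n_alt, replace=False)
        indicator = np.zeros(n)
        indicator[altered] = 1.0
        dosage = spec.cna_dosage if kind == "amp" else -spec.cna_dosage
        for g in gene_block:
            cna_log2[g, altered] += dosage
        cna_rows.append(pd.Series(indicator, index=samples, name=region))
        truth.cna_regions[region] = dict(
            genes=[genes[g] for g in gene_block], kind=kind,
            samples=[samples[s] for s in altered], dosage=dosage,
        )
    cna = pd.DataFrame(cna_rows)

    # ---- assemble protein / mRNA log2 matrices -------------------------
    protein_log2 = sd_g[:, None] * (core + shift_units) + cna_log2
    coupling = np.clip(
        rng.normal(spec.mrna_coupling_mean, spec.mrna_coupling_sd, size=p), -0.95, 0.95
    )
    truth.mrna_coupling = pd.Series(coupling, index=genes, name="target_r")
    mrna_noise = rng.standard_normal((p, n))
    mrna_units = coupling[:, None] * core + np.sqrt(1.0 - coupling[:, None] ** 2) * mrna_noise
    # variable mRNAs tend to encode variable proteins: couple the per-gene
    # dispersion of the two layers, with independent jitter
    sd_m = 0.7 * sd_g + 0.3 * rng.uniform(sd_lo, sd_hi, size=p)
    mrna_log2 = sd_m[:, None] * (mrna_units + mrna_shift_units) + cna_log2

    # ---- phosphopeptides -----------------------------------------------
    n_enzyme_peps = spec.n_kinase_groups * spec.peptides_per_kinase
    if spec.n_phospho < n_enzyme_peps:
        raise ValueError("infeasible spec: n_phospho below enzyme peptide count")
    pep_parent_idx = list(
        np.repeat(kinase_idx, spec.peptides_per_kinase)
    ) + list(rng.integers(0, p, size=spec.n_phospho - n_enzyme_peps))
    residues = rng.choice(["S", "T", "Y"], size=spec.n_phospho, p=[0.86, 0.13, 0.01])
    pep_ids, map_rows = [], []
    for j, parent in enumerate(pep_parent_idx):
        pos = int(rng.integers(1, 600))
        pid = f"{genes[parent]}_p{residues[j]}{pos}_{j + 1}"
        pep_ids.append(pid)
        map_rows.append(dict(peptide=pid, parent=genes[parent], residue=residues[j], position=str(pos)))
    phospho_map = pd.DataFrame(map_rows)
    kin_latents = rng.standard_normal((spec.n_kinase_groups, n))
    pep_resid = rng.standard_normal((spec.n_phospho, n))
    beta = spec.kinase_beta
    for grp in range(spec.n_kinase_groups):
        name = f"KINGRP{grp + 1:02d}"
        members = list(range(grp * spec.peptides_per_kinase, (grp + 1) * spec.peptides_per_kinase))
        signs = np.ones(len(members))
        if grp == 0 and len(members) >= 2 and beta > 0:
            signs[-1] = -1.0  # planted anti-regulated peptide
            truth.anti_regulated_pair = (pep_ids[members[0]], pep_ids[members[-1]])
        for m, sign in zip(members, signs):
            pep_resid[m] = sign * beta * kin_latents[grp] + np.sqrt(1.0 - beta**2) * pep_resid[m]
        truth.kinase_groups[name] = [pep_ids[m] for m in members]
    enzymes = [pid for peps in truth.kinase_groups.values() for pid in peps]
    pep_sd = rng.uniform(sd_lo, sd_hi, size=spec.n_phospho)
    phospho_log2 = (
        spec.phospho_alpha * protein_log2[pep_parent_idx, :]
        + pep_sd[:, None] * pep_resid
    )

    # ---- drug response --------------------------------------------------
    def _std(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std()

    efflux_cov = _std(core[efflux_idx[0]] + core[efflux_idx[1]])
    drugs = [f"DRUG{j + 1:03d}" for j in range(spec.n_drugs)]
    ic50 = np.zeros((spec.n_drugs, n))
    drug_rows = []
    n_e, n_s, n_pm = spec.n_efflux_drugs, spec.n_secondary_drugs, spec.n_protein_marker_drugs
    if n_e + n_s + n_pm > spec.n_drugs:
        raise ValueError("infeasible spec: drug type counts exceed n_drugs")
    for j in range(spec.n_drugs):
        noise = rng.standard_normal(n)
        if j < n_e:
            kind, marker, layer = "efflux", "", ""
            a = np.sqrt(spec.efflux_share)
            y = a * efflux_cov + np.sqrt(max(1 - spec.efflux_share, 0)) * noise
        elif j < n_e + n_s:
            kind, layer = "secondary", "genomic"
            gidx = marker_idx[j - n_e]
            marker = genes[gidx]
            muts = {r["sample"] for r in mut_records if r["gene"] == marker}
            ind = _std(np.array([1.0 if s in muts else 0.0 for s in samples]))
            a = np.sqrt(spec.secondary_efflux_share)
            b = np.sqrt(spec.secondary_marker_share)
            resid = max(1.0 - spec.secondary_efflux_share - spec.secondary_marker_share, 0)
            y = a * efflux_cov + b * ind + np.sqrt(resid) * noise
        elif j < n_e + n_s + n_pm:
            kind, layer = "protein_marker", "protein"
            gidx = protein_marker_idx[j - n_e - n_s]
            marker = genes[gidx]
            a = np.sqrt(spec.protein_marker_share)
            y = a * _std(core[gidx]) + np.sqrt(max(1 - spec.protein_marker_share, 0)) * noise
        else:
            kind, marker, layer = "null", "", ""
            y = noise
        ic50[j] = y
        drug_rows.append(dict(drug=drugs[j], kind=kind, marker=marker, marker_layer=layer))
    truth.drug_truth = pd.DataFrame(drug_rows).set_index("drug")
    ic50_df = pd.DataFrame(ic50, index=drugs, columns=samples)

    # ---- missingness + scaling to the 0-1000 intensity convention ------
    def _mask(shape: tuple[int, int]) -> np.ndarray:
        sporadic = rng.random(shape[0]) < spec.missing_feature_fraction
        cells = rng.random(shape) < spec.missing_cell_rate
        return sporadic[:, None] & cells

    protein_mask = _mask(protein_log2.shape)
    phospho_mask = _mask(phospho_log2.shape)
    protein_scaled = _scale_rows_to_100(protein_log2, protein_mask)
    phospho_scaled = _scale_rows_to_100(phospho_log2, phospho_mask)
    mrna_scaled = _scale_rows_to_100(mrna_log2, np.zeros_like(mrna_log2, dtype=bool))

    meta = pd.DataFrame({"Description": genes}, index=pd.Index(genes, name="id"))
    protein = AbundanceMatrix(
        pd.DataFrame(protein_scaled, index=pd.Index(genes, name="id"), columns=samples),
        meta.copy(),
    )
    mrna = AbundanceMatrix(
        pd.DataFrame(mrna_scaled, index=pd.Index(genes, name="id"), columns=samples),
        meta.copy(),
    )
    phospho = AbundanceMatrix(
        pd.DataFrame(phospho_scaled, index=pd.Index(pep_ids, name="id"), columns=samples),
        pd.DataFrame(
            {"Description": phospho_map["parent"].to_numpy()},
            index=pd.Index(pep_ids, name="id"),
        ),
    )

    # ---- replicate measurements for the CV report ----------------------
    n_rep = min(spec.n_replicate_lines, n)
    rep_cols, rep_vals, rep_groups = [], [], {}
    for s in range(n_rep):
        for r in (1, 2):
            col = f"{samples[s]}_rep{r}"
            rep_cols.append(col)
            rep_groups[col] = samples[s]
            rep_vals.append(
                protein_log2[:, s] + spec.replicate_noise_sd * sd_g * rng.standard_normal(p)
            )
    rep_log2 = np.array(rep_vals).T
    rep_scaled = _scale_rows_to_100(rep_log2, np.zeros_like(rep_log2, dtype=bool))
    replicate_protein = AbundanceMatrix(
        pd.DataFrame(rep_scaled, index=pd.Index(genes, name="id"), columns=rep_cols),
        meta.copy(),
    )

    # ---- annotations: planted complexes as GMT sets and known pairs ----
    pairs = []
    for name, members in truth.complexes.items():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                pairs.append((a, b, "planted"))
    annotations = AnnotationCatalog(sets={k: list(v) for k, v in truth.complexes.items()}, pairs=pairs)

    return SyntheticCohort(
        spec=spec, protein=protein, mrna=mrna, phospho=phospho,
        phospho_map=phospho_map, enzymes=enzymes, mutations=mutations,
        cna=cna, ic50=ic50_df, annotations=annotations,
        replicate_protein=replicate_protein, replicate_groups=rep_groups,
        truth=truth,
    )


def null_cohort(spec: CohortSpec | None = None) -> SyntheticCohort:
    """Same bundle with every planted effect zeroed (global null).

    Mutations, CNA calls, annotation sets and drug/sample layout are still
    emitted so scans run on realistic inputs, but carry no signal.
    """
    spec = spec or CohortSpec()
    nulled = spec.replace(
        within_complex_r=0.0,
        loading_jitter=0.0,
        outlier_every=0,
        mrna_coupling_mean=0.0,
        mrna_coupling_sd=0.0,
        delta_het=0.0,
        delta_hom=0.0,
        stabilizing_effect=0.0,
        propagation_fraction=0.0,
        cna_dosage=0.0,
        subtype_shift=0.0,
        kinase_beta=0.0,
        efflux_r=0.0,
        efflux_share=0.0,
        secondary_efflux_share=0.0,
        secondary_marker_share=0.0,
        protein_marker_share=0.0,
    )
    return generate_cohort(nulled)
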