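"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`AbundanceMatrix`, a feature x sample numeric
matrix (proteins, phosphopeptides or mRNA) with optional per-feature
annotations. Gene-set / interaction annotations live in
:class:`AnnotationCatalog`, somatic variants in :class:`MutationTable`, and
run-wide thresholds in :class:`PipelineConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "AnnotationCatalog",
    "MutationTable",
    "PipelineConfig",
    "VARIANT_CLASSES",
    "LOF_CLASSES",
    "ZYGOSITIES",
    "canonical_pair",
]

#: Closed vocabulary of somatic variant classes.
VARIANT_CLASSES = frozenset(
    {"missense", "frameshift", "nonsense", "inframe", "splice_site", "startstop_loss"}
)

#: Loss-of-function classes: frameshift, nonsense, in-frame, splice site and
#: start/stop-codon loss variants, all expected to disrupt the protein product.
LOF_CLASSES = frozenset(
    {"frameshift", "nonsense", "inframe", "splice_site", "startstop_loss"}
)

ZYGOSITIES = frozenset({"het", "hom", "unknown"})


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return an undirected gene pair in canonical (lexicographic) order.

    Raises ``ValueError`` for self-pairs; pair identity is order-insensitive.
    """
    if a == b:
        raise ValueError(f"self-pair not allowed: ({a!r}, {b!r})")
    return (a, b) if a < b else (b, a)


@dataclass
class AbundanceMatrix:
    """Feature x sample abundance matrix with missing values allowed.

    Parameters
    ----------
    data : pandas.DataFrame
        Numeric matrix; index = unique feature ids, columns = unique sample
        ids. Missing measurements are ``NaN``; all present values are finite.
    meta : pandas.DataFrame, optional
        Per-feature annotations aligned to ``data.index`` (gene symbol,
        phosphosite tag, ...). A ``Description`` column is created when
        absent so GCT round-trips are lossless.
    """

    data: pd.DataFrame
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("data must be a pandas DataFrame")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate feature ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups}")
        self.data = self.data.astype(float)
        vals = self.data.to_numpy()
        if np.isinf(vals).any():
            raise ValueError("abundance values must be finite or missing")
        if self.meta is None:
            self.meta = pd.DataFrame(
                {"Description": ["na"] * len(idx)}, index=idx.copy()
            )
        else:
            if not self.meta.index.equals(idx):
                self.meta = self.meta.reindex(idx)
            if "Description" not in self.meta.columns:
                self.meta.insert(0, "Description", "na")

    # -- basic introspection -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.meta.copy())

    def subset(
        self,
        features: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "AbundanceMatrix":
        data = self.data
        meta = self.meta
        if features is not None:
            data = data.loc[list(features)]
            meta = meta.loc[list(features)]
        if samples is not None:
            data = data[list(samples)]
        return AbundanceMatrix(data.copy(), meta.copy())

    def log2(self, pseudocount: float = 1.0) -> "AbundanceMatrix":
        """log2(x + pseudocount) transform used for all correlation work."""
        return AbundanceMatrix(np.log2(self.data + pseudocount), self.meta.copy())

    def equals(self, other: "AbundanceMatrix") -> bool:
        return self.data.equals(other.data) and self.meta.equals(other.meta)


@dataclass
class AnnotationCatalog:
    """Named gene sets plus undirected known-interaction pairs.

    ``sets`` maps set name -> deduplicated member list; ``pairs`` holds
    ``(gene_a, gene_b, confidence_label)`` with canonical (lexicographic)
    gene order and no self-pairs.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            seen: dict[str, None] = {}
            for m in members:
                seen.setdefault(m, None)
            self.sets[name] = list(seen)
        canon = []
        for rec in self.pairs:
            a, b = rec[0], rec[1]
            label = rec[2] if len(rec) > 2 else ""
            canon.append((*canonical_pair(a, b), label))
        self.pairs = canon

    def pair_keys(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.pairs}

    def set_pairs(self, name: str) -> set[tuple[str, str]]:
        """All within-set member pairs of one gene set, canonical order."""
        members = self.sets[name]
        out: set[tuple[str, str]] = set()
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                out.add(canonical_pair(a, b))
        return out

    def all_set_pairs(self) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for name in self.sets:
            out |= self.set_pairs(name)
        return out


@dataclass
class MutationTable:
    """Per-(gene, sample) somatic variant records.

    Columns: gene, sample, variant_class (closed vocabulary), zygosity
    (het/hom/unknown), rel_position (relative position of the variant along
    the protein, 0 = N terminus, 1 = C terminus; NaN when unknown) and
    is_driver flag.
    """

    records: pd.DataFrame

    COLUMNS = ("gene", "sample", "variant_class", "zygosity", "rel_position", "is_driver")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"mutation table missing columns: {missing}")
        bad = set(df["variant_class"]) - VARIANT_CLASSES
        if bad:
            raise ValueError(f"unknown variant_class values: {sorted(bad)}")
        bad = set(df["zygosity"]) - ZYGOSITIES
        if bad:
            raise ValueError(f"unknown zygosity values: {sorted(bad)}")
        pos = pd.to_numeric(df["rel_position"], errors="coerce")
        present = pos.notna()
        if ((pos[present] < 0) | (pos[present] > 1)).any():
            raise ValueError("rel_position must lie in [0, 1] when present")
        df["rel_position"] = pos
        df["is_driver"] = df["is_driver"].astype(bool)
        self.records = df.reset_index(drop=True)[list(self.COLUMNS)]

    def __len__(self) -> int:
        return len(self.records)

    def filter_classes(self, classes: Iterable[str]) -> "MutationTable":
        classes = set(classes)
        return MutationTable(self.records[self.records["variant_class"].isin(classes)])

    def lof(self) -> "MutationTable":
        return self.filter_classes(LOF_CLASSES)

    def missense(self) -> "MutationTable":
        return self.filter_classes({"missense"})

    def drivers(self) -> "MutationTable":
        return MutationTable(self.records[self.records["is_driver"]])

    def mutated_samples(self) -> dict[str, set[str]]:
        """gene -> set of mutated sample ids."""
        out: dict[str, set[str]] = {}
        for gene, sub in self.records.groupby("gene", sort=True):
            out[gene] = set(sub["sample"])
        return out


@dataclass
class PipelineConfig:
    """Run-wide thresholds, sizes and seeds.

    All FDR levels are in (0, 1]; the network weight cutoff is the exported
    TOM weight floor; ``min_mutated`` / ``min_shared_samples`` are group-size
    floors for association tests and pairwise correlations.
    """

    seed: int = 0
    fdr_mutation: float = 0.1
    fdr_enrichment: float = 0.05
    fdr_cophospho: float = 0.1
    fdr_drug_efflux: float = 0.05
    fdr_qtl_discovery: float = 0.1
    fdr_qtl_replication: float = 0.3
    weight_cutoff: float = 0.02
    min_mutated: int = 3
    min_mutated_driver: int = 5
    min_shared_samples: int = 10
    min_fraction_quantified: float = 0.8
    min_module_size: int = 3
    cut_height_fraction: float = 0.995
    soft_power_default: int = 6
    n_permutations: int = 1000
    consensus_reps: int = 250
    consensus_subsample: float = 0.8
    consensus_k_range: tuple[int, int] = (2, 8)
    predictive_r_threshold: float = 0.4
    elastic_net_l1_ratio: tuple[float, ...] = (0.5,)
    elastic_net_n_alphas: int = 20
    top_variable_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise ValueError("seed must be an integer")
        for name in (
            "fdr_mutation",
            "fdr_enrichment",
            "fdr_cophospho",
            "fdr_drug_efflux",
            "fdr_qtl_discovery",
            "fdr_qtl_replication",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.weight_cutoff < 0:
            raise ValueError("weight_cutoff must be >= 0")
        for name in ("min_mutated", "min_mutated_driver", "min_shared_samples", "min_module_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.min_fraction_quantified <= 1:
            raise ValueError("min_fraction_quantified must be in (0, 1]")
        if not 0 < self.cut_height_fraction <= 1:
            raise ValueError("cut_height_fraction must be in (0, 1]")
        if not 0 < self.consensus_subsample <= 1:
            raise ValueError("consensus_subsample must be in (0, 1]")
        if not 0 < self.top_variable_fraction <= 1:
            raise ValueError("top_variable_fraction must be in (0, 1]")
        lo, hi = self.consensus_k_range
        if lo < 2 or hi < lo:
            raise ValueError("consensus_k_range must satisfy 2 <= lo <= hi")
        if self.n_permutations < 1 or self.consensus_reps < 1:
            raise ValueError("n_permutations and consensus_reps must be >= 1")

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("consensus_k_range", "elastic_net_l1_ratio"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
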