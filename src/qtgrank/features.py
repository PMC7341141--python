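"""Per-gene feature construction.

Builds the gene x feature matrix consumed by the ranking model from
annotated variant calls, conserved non-coding elements (CE / TFBS),
gene presence/absence matrices, GO annotations aggregated through a
GO-slim, and orthogroup membership (paralog copy number).

Coordinates are 0-based half-open internally.  GFF3 input (1-based
inclusive) is converted on ingest by the readers in :mod:`qtgrank.io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "AnnotatedVariant",
    "ConservedElement",
    "EffectRule",
    "FeatureTable",
    "DEFAULT_EFFECT_SCHEMA",
    "encode_variant_features",
    "count_cns_polymorphisms",
    "compute_percent_absence",
    "aggregate_go_features",
    "attach_paralog_counts",
    "merge_feature_fragments",
]

FEATURE_KINDS = ("binary", "count", "fraction")


@dataclass(frozen=True)
class GeneModel:
    """A gene locus; ``start < end``, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )


@dataclass(frozen=True)
class AnnotatedVariant:
    """A single-alternate variant with effect annotation.

    ``variant_class`` is derived from ref/alt lengths (both length 1 ->
    SNP, otherwise indel); multi-allelic records are split upstream so
    each carries one alternate allele.  ``deleterious_flag`` carries a
    SIFT-style pathogenicity call when present; ``None`` means no call
    was made and the variant can never satisfy a rule that requires
    deleteriousness.
    """

    chrom: str
    pos: int
    variant_class: str  # "SNP" | "indel"
    gene_id: str | None = None
    effect_terms: frozenset[str] = frozenset()
    deleterious_flag: bool | None = None

    @staticmethod
    def classify(ref: str, alt: str) -> str:
        return "SNP" if len(ref) == 1 and len(alt) == 1 else "indel"


@dataclass(frozen=True)
class ConservedElement:
    """A conserved non-coding interval, kind ``CE`` or ``TFBS``."""

    element_id: str
    chrom: str
    start: int
    end: int
    element_kind: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"element {self.element_id}: start ({self.start}) "
                f"must be < end ({self.end})"
            )
        if self.element_kind not in ("CE", "TFBS"):
            raise ValueError(f"unknown element_kind {self.element_kind!r}")


@dataclass(frozen=True)
class EffectRule:
    """Maps a set of annotation effect terms onto one binary feature.

    A variant sets the feature when any of its effect terms is in
    ``terms`` and, if ``require_deleterious``, its deleterious flag is
    True.
    """

    terms: frozenset[str]
    require_deleterious: bool = False


# Reconstruction of the standard per-gene polymorphism flags used by
# SnpEff/SIFT-style annotation pipelines.  Term spellings follow the
# Sequence Ontology dialect SnpEff emits; the schema is configurable
# because annotation dialects vary.
DEFAULT_EFFECT_SCHEMA: dict[str, EffectRule] = {
    "is_nonsyn_deleterious": EffectRule(
        frozenset({"missense_variant", "missense"}), require_deleterious=True
    ),
    "is_nonsyn": EffectRule(frozenset({"missense_variant", "missense"})),
    "is_synonymous": EffectRule(
        frozenset({"synonymous_variant", "synonymous"})
    ),
    "is_frameshift": EffectRule(
        frozenset({"frameshift_variant", "frameshift"})
    ),
    "is_stop_gained": EffectRule(frozenset({"stop_gained"})),
    "is_stop_lost": EffectRule(frozenset({"stop_lost"})),
    "is_splice": EffectRule(
        frozenset(
            {
                "splice_acceptor_variant",
                "splice_donor_variant",
                "splice_region_variant",
                "splice",
            }
        )
    ),
    "is_utr": EffectRule(
        frozenset(
            {"5_prime_UTR_variant", "3_prime_UTR_variant", "UTR"}
        )
    ),
    "is_intron": EffectRule(frozenset({"intron_variant", "intron"})),
    "is_upstream": EffectRule(frozenset({"upstream_gene_variant", "upstream"})),
    "is_downstream": EffectRule(
        frozenset({"downstream_gene_variant", "downstream"})
    ),
}


@dataclass
class FeatureTable:
    """Gene x feature numeric matrix with per-feature kind metadata.

    ``values`` is indexed by gene_id with one column per feature;
    ``kinds`` maps each feature name to ``binary``, ``count`` or
    ``fraction``.  Construction validates ranges: binary in {0,1},
    counts non-negative integers, fractions in [0,1].
    """

    values: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene_ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        missing = set(self.values.columns) - set(self.kinds)
        if missing:
            raise ValueError(f"features without a declared kind: {sorted(missing)}")
        for name in self.values.columns:
            kind = self.kinds[name]
            col = self.values[name]
            if col.isna().any():
                raise ValueError(f"feature {name!r} has missing values")
            if kind == "binary":
                if not col.isin([0, 1]).all():
                    raise ValueError(f"binary feature {name!r} has values outside {{0,1}}")
            elif kind == "count":
                if (col < 0).any() or not np.allclose(col, np.round(col)):
                    raise ValueError(
                        f"count feature {name!r} must hold non-negative integers"
                    )
            elif kind == "fraction":
                if (col < 0).any() or (col > 1).any():
                    raise ValueError(f"fraction feature {name!r} outside [0,1]")
            else:
                raise ValueError(f"unknown feature kind {kind!r} for {name!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def matrix(self, gene_ids=None, feature_names=None) -> np.ndarray:
        df = self.values
        if feature_names is not None:
            df = df[list(feature_names)]
        if gene_ids is not None:
            df = df.loc[list(gene_ids)]
        return df.to_numpy(dtype=float)


def encode_variant_features(
    variants: list[AnnotatedVariant],
    genes: list[GeneModel],
    feature_schema: dict[str, EffectRule] | None = None,
) -> FeatureTable:
    """Binary per-gene polymorphism flags.

    A feature is 1 for a gene iff at least one variant assigned to the
    gene matches the feature's effect rule.  Genes with no variants get
    all-zero rows.  Effect terms not covered by any rule are counted and
    reported with a single warning (a signal of schema/annotation-dialect
    mismatch), never an error.
    """
    schema = DEFAULT_EFFECT_SCHEMA if feature_schema is None else feature_schema
    gene_ids = [g.gene_id for g in genes]
    known = set(gene_ids)

    unknown_genes = sorted(
        {v.gene_id for v in variants if v.gene_id is not None and v.gene_id not in known}
    )
    if unknown_genes:
        raise KeyError(f"variants reference unknown gene IDs: {unknown_genes}")

    covered_terms = set().union(*(rule.terms for rule in schema.values())) if schema else set()
    mat = pd.DataFrame(0, index=pd.Index(gene_ids, name="gene_id"), columns=list(schema))
    unmatched = 0
    for v in variants:
        if v.gene_id is None:
            continue
        if v.effect_terms and not (v.effect_terms & covered_terms):
            unmatched += 1
            continue
        for fname, rule in schema.items():
            if not (v.effect_terms & rule.terms):
                continue
            if rule.require_deleterious and v.deleterious_flag is not True:
                continue
            mat.at[v.gene_id, fname] = 1
    if unmatched:
        warnings.warn(
            f"{unmatched} variant(s) carried effect terms not covered by the "
            "feature schema and were skipped",
            stacklevel=2,
        )
    return FeatureTable(mat, {name: "binary" for name in schema})


def count_cns_polymorphisms(
    variants: list[AnnotatedVariant],
    elements: list[ConservedElement],
    genes: list[GeneModel],
    window: int = 1000,
) -> FeatureTable:
    """CE_snp / TFBS_snp / CE_indel / TFBS_indel counts.

    An element is assigned to every gene whose interval, extended by
    ``window`` bp on both flanks, it overlaps; the assignment is
    strand-agnostic.  Each feature counts the variants of the matching
    class (SNP or indel) that fall inside any assigned element of the
    matching kind.  A variant inside an element assigned to two genes
    counts for both genes; a variant inside two overlapping elements of
    the same kind assigned to one gene counts once per gene per kind.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    features = ["CE_snp", "TFBS_snp", "CE_indel", "TFBS_indel"]
    gene_ids = [g.gene_id for g in genes]
    mat = pd.DataFrame(0, index=pd.Index(gene_ids, name="gene_id"), columns=features)

    # gene trees on the window-extended intervals, per chromosome
    gene_trees: dict[str, IntervalTree] = {}
    for g in genes:
        gene_trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, g.start - window), g.end + window, g.gene_id
        )

    # element -> genes assignment
    elem_genes: dict[str, list[str]] = {}
    elem_trees: dict[tuple[str, str], IntervalTree] = {}
    for e in elements:
        tree = gene_trees.get(e.chrom)
        hits = [iv.data for iv in tree.overlap(e.start, e.end)] if tree else []
        elem_genes[e.element_id] = hits
        if hits:
            elem_trees.setdefault((e.chrom, e.element_kind), IntervalTree()).addi(
                e.start, e.end, e.element_id
            )

    cls_to_suffix = {"SNP": "snp", "indel": "indel"}
    # (gene, feature) -> set of variant keys so overlapping same-kind
    # elements never double-count one variant
    seen: set[tuple[str, str, str, int]] = set()
    for i, v in enumerate(variants):
        suffix = cls_to_suffix.get(v.variant_class)
        if suffix is None:
            raise ValueError(f"unknown variant_class {v.variant_class!r}")
        for kind in ("CE", "TFBS"):
            tree = elem_trees.get((v.chrom, kind))
            if tree is None:
                continue
            fname = f"{kind}_{suffix}"
            for iv in tree.overlap(v.pos, v.pos + 1):
                for gid in elem_genes[iv.data]:
                    key = (gid, fname, v.chrom, i)
                    if key not in seen:
                        seen.add(key)
                        mat.at[gid, fname] += 1
    return FeatureTable(mat, {name: "count" for name in features})


def compute_percent_absence(pav: pd.DataFrame) -> FeatureTable:
    """Fraction of accessions in which each gene is absent.

    ``pav`` is a gene x accession matrix with entries in {0,1} (or
    {"present","absent"}), 1/"absent" meaning the gene is missing from
    that accession.
    """
    if pav.shape[1] < 1:
        raise ValueError("presence/absence matrix needs at least one accession column")
    df = pav.replace({"present": 0, "absent": 1})
    arr = df.to_numpy()
    bad = ~np.isin(arr, [0, 1])
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary presence/absence cell at gene {df.index[r]!r}, "
            f"accession {df.columns[c]!r}: {arr[r, c]!r}"
        )
    frac = df.mean(axis=1).astype(float)
    mat = frac.to_frame("percent_absence")
    mat.index.name = "gene_id"
    return FeatureTable(mat, {"percent_absence": "fraction"})


def aggregate_go_features(
    annotations: dict[str, set[str]],
    slim_map: dict[str, set[str]],
    slim_feature_schema: dict[str, str],
    diagnostics: dict | None = None,
) -> FeatureTable:
    """Binary function flags from GO terms rolled up through a GO-slim.

    ``slim_feature_schema`` maps a slim term to its feature name, e.g.
    ``{"GO:0005215": "is_transporter"}``.  A gene's feature is 1 iff any
    of its annotated terms is the slim term itself or has it among its
    slim ancestors.  Terms missing from ``slim_map`` are counted in
    ``diagnostics['unmapped_terms']`` when a dict is supplied.
    """
    feature_names = list(slim_feature_schema.values())
    gene_ids = sorted(annotations)
    mat = pd.DataFrame(0, index=pd.Index(gene_ids, name="gene_id"), columns=feature_names)
    unmapped: set[str] = set()
    for gid, terms in annotations.items():
        for term in terms:
            ancestors = slim_map.get(term)
            if ancestors is None:
                unmapped.add(term)
                ancestors = set()
            reachable = {term} | ancestors
            for slim_term, fname in slim_feature_schema.items():
                if slim_term in reachable:
                    mat.at[gid, fname] = 1
    if diagnostics is not None:
        diagnostics["unmapped_terms"] = sorted(unmapped)
    return FeatureTable(mat, {name: "binary" for name in feature_names})


def attach_paralog_counts(
    gene_to_group: dict[str, str],
    group_species_counts: dict[str, dict[str, int]],
    target_species: str,
    gene_ids: list[str],
) -> FeatureTable:
    """Paralog copy number: same-species member count of a gene's orthogroup.

    Genes belonging to no orthogroup are singletons and get copy
    number 1 (every gene has at least itself).
    """
    counts = []
    for gid in gene_ids:
        group = gene_to_group.get(gid)
        if group is None:
            counts.append(1)
        else:
            counts.append(group_species_counts.get(group, {}).get(target_species, 1))
    mat = pd.DataFrame(
        {"paralog_copy_number": counts}, index=pd.Index(gene_ids, name="gene_id")
    )
    return FeatureTable(mat, {"paralog_copy_number": "count"})


#: per-feature value used when a gene is absent from a fragment
IMPUTATION_DEFAULTS = {"paralog_copy_number": 1}


def merge_feature_fragments(
    fragments: list[FeatureTable], universe: list[str]
) -> FeatureTable:
    """Column-wise union of fragments over a common gene universe.

    Genes missing from a fragment receive that fragment's imputation
    default: binary and count features 0, paralog copy number 1 (a gene
    is always its own paralog).  Duplicate feature names across
    fragments are an error; fragment genes outside the universe are an
    error.
    """
    if len(set(universe)) != len(universe):
        raise ValueError("universe contains duplicate gene IDs")
    uni = pd.Index(universe, name="gene_id")
    seen_features: set[str] = set()
    cols = []
    kinds: dict[str, str] = {}
    for frag in fragments:
        overlap = seen_features & set(frag.feature_names)
        if overlap:
            raise ValueError(f"duplicate feature names across fragments: {sorted(overlap)}")
        seen_features |= set(frag.feature_names)
        stray = set(frag.gene_ids) - set(universe)
        if stray:
            raise ValueError(f"fragment genes outside universe: {sorted(stray)}")
        block = frag.values.reindex(uni)
        for name in frag.feature_names:
            default = IMPUTATION_DEFAULTS.get(name, 0)
            block[name] = block[name].fillna(default)
        cols.append(block)
        kinds.update({n: frag.kinds[n] for n in frag.feature_names})
    merged = pd.concat(cols, axis=1) if cols else pd.DataFrame(index=uni)
    return FeatureTable(merged, kinds)
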