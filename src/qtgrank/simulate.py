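"""Synthetic species generator.

Emits everything the pipeline ingests — gene models, annotated
variants, conserved elements, a presence/absence matrix, GO
annotations, orthogroup membership — for an artificial genome in which
a chosen subset of genes ("causal") is drawn from shifted feature
distributions.  The planted effects mirror what is observed for real
causal genes: more SNPs and indels in nearby conserved elements,
higher percent absence across accessions, and enrichment of
deleterious non-synonymous polymorphism.

The generator is deliberately marginal: each feature is drawn
independently per gene (binary via Bernoulli with an odds-multiplier
effect, counts via Poisson with a shifted mean, fractions via a Beta
on the per-accession absence probability).  There is no linkage,
population structure or genuine ortholog evolution — only the
signal/noise structure the classifier consumes.

Round-trip contract: the raw files written by :func:`write_raw`, run
through :mod:`qtgrank.features` extraction, reproduce the generated
feature table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import (
    AnnotatedVariant,
    ConservedElement,
    EffectRule,
    FeatureTable,
    GeneModel,
)
from .orthology import CausalGeneRecord, OrthologMap
from .validation import QTLRegion

__all__ = [
    "FeatureSpecEntry",
    "FixtureSpec",
    "SpeciesFixture",
    "OrthologPairFixture",
    "default_feature_spec",
    "single_informative_feature_spec",
    "generate_species",
    "generate_ortholog_pair",
]

DEFAULT_SEED = 20200518

_GENE_SPACING = 5000
_GENE_LENGTH = 2000


@dataclass(frozen=True)
class FeatureSpecEntry:
    """One feature's generative law.

    ``null`` parameterizes the genome-wide distribution, ``causal`` the
    causal-gene distribution (``None`` means no effect).  ``source``
    decides which raw file realizes the value: ``variant`` (a binary
    effect-annotated SNP/indel inside the gene), ``cns`` (variant
    counts inside a flanking conserved element), ``pav`` (absence
    fraction across accessions), ``go`` (a GO term rolled up to a slim
    feature) or ``orthogroup`` (same-species orthogroup size).
    """

    kind: str
    source: str
    null: dict
    causal: dict | None = None
    term: str | None = None
    deleterious: bool = False
    element_kind: str | None = None
    variant_class: str | None = None

    def null_p(self) -> float:
        return float(self.null["p"])

    def causal_p(self) -> float:
        if self.causal is None:
            return self.null_p()
        if "p" in self.causal:
            p = float(self.causal["p"])
        else:
            m = float(self.causal["odds_multiplier"])
            if m <= 0:
                raise ValueError("odds_multiplier must be positive")
            p0 = self.null_p()
            odds = p0 / (1.0 - p0) * m
            p = odds / (1.0 + odds)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"causal probability {p} outside [0, 1]")
        return p


def default_feature_spec() -> dict[str, FeatureSpecEntry]:
    """Default planted-effect feature set.

    Causal genes get a 4x odds of deleterious non-synonymous SNPs, a
    conserved-element SNP mean shifted from 0.5 to 1.5 (indels 0.2 to
    0.6), and mean percent absence shifted from 0.02 to 0.10; TFBS
    polymorphism, GO flags and paralog copy number carry no signal.
    """
    return {
        "is_nonsyn_deleterious": FeatureSpecEntry(
            "binary", "variant", {"p": 0.10}, {"odds_multiplier": 4.0},
            term="missense_variant", deleterious=True,
        ),
        "is_synonymous": FeatureSpecEntry(
            "binary", "variant", {"p": 0.50}, term="synonymous_variant"
        ),
        "is_frameshift": FeatureSpecEntry(
            "binary", "variant", {"p": 0.05}, term="frameshift_variant"
        ),
        "CE_snp": FeatureSpecEntry(
            "count", "cns", {"mean": 0.5}, {"mean": 1.5},
            element_kind="CE", variant_class="SNP",
        ),
        "CE_indel": FeatureSpecEntry(
            "count", "cns", {"mean": 0.2}, {"mean": 0.6},
            element_kind="CE", variant_class="indel",
        ),
        "TFBS_snp": FeatureSpecEntry(
            "count", "cns", {"mean": 0.5}, element_kind="TFBS", variant_class="SNP"
        ),
        "TFBS_indel": FeatureSpecEntry(
            "count", "cns", {"mean": 0.2}, element_kind="TFBS", variant_class="indel"
        ),
        "percent_absence": FeatureSpecEntry(
            "fraction", "pav",
            {"mean": 0.02, "concentration": 25.0},
            {"mean": 0.10, "concentration": 25.0},
        ),
        "is_transporter": FeatureSpecEntry(
            "binary", "go", {"p": 0.05}, term="GO:0005215"
        ),
        "is_transcription_factor": FeatureSpecEntry(
            "binary", "go", {"p": 0.08}, term="GO:0003700"
        ),
        "paralog_copy_number": FeatureSpecEntry(
            "count", "orthogroup", {"mean": 1.0}
        ),
    }


def single_informative_feature_spec() -> dict[str, FeatureSpecEntry]:
    """A reduced feature set in which exactly one feature (CE_snp)
    carries signal; used for planted-signal recovery studies of the
    leave-one-out importance analysis."""
    return {
        "is_nonsyn_deleterious": FeatureSpecEntry(
            "binary", "variant", {"p": 0.10},
            term="missense_variant", deleterious=True,
        ),
        "is_synonymous": FeatureSpecEntry(
            "binary", "variant", {"p": 0.50}, term="synonymous_variant"
        ),
        "CE_snp": FeatureSpecEntry(
            "count", "cns", {"mean": 0.5}, {"mean": 2.5},
            element_kind="CE", variant_class="SNP",
        ),
        "TFBS_snp": FeatureSpecEntry(
            "count", "cns", {"mean": 0.5}, element_kind="TFBS", variant_class="SNP"
        ),
        "percent_absence": FeatureSpecEntry(
            "fraction", "pav", {"mean": 0.02, "concentration": 25.0}
        ),
        "paralog_copy_number": FeatureSpecEntry(
            "count", "orthogroup", {"mean": 1.0}
        ),
    }


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic species."""

    n_genes: int = 2000
    n_causal: int = 200
    features: dict[str, FeatureSpecEntry] = field(default_factory=default_feature_spec)
    n_qtls: int = 10
    qtl_size_range: tuple[int, int] = (20, 700)
    n_accessions: int = 80
    species: str = "synspecies_A"
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not 0 < self.n_causal < self.n_genes:
            raise ValueError("need 0 < n_causal < n_genes")
        if self.qtl_size_range[0] < 1 or self.qtl_size_range[0] > self.qtl_size_range[1]:
            raise ValueError("invalid qtl_size_range")
        for name, entry in self.features.items():
            if entry.kind == "binary":
                entry.causal_p()  # validates feasibility
            elif entry.kind == "count":
                if entry.null["mean"] < 0 or (
                    entry.causal is not None and entry.causal["mean"] < 0
                ):
                    raise ValueError(f"{name}: Poisson mean must be >= 0")
            elif entry.kind == "fraction":
                for params in (entry.null, entry.causal or entry.null):
                    if not 0 < params["mean"] < 1 or params["concentration"] <= 0:
                        raise ValueError(f"{name}: invalid Beta parameters")
            else:
                raise ValueError(f"{name}: unknown kind {entry.kind!r}")


@dataclass
class SpeciesFixture:
    """One synthetic species with every raw input held in memory."""

    spec: FixtureSpec
    genes: list[GeneModel]
    feature_table: FeatureTable
    causal_genes: list[str]
    qtls: list[QTLRegion]
    variants: list[AnnotatedVariant]
    elements: list[ConservedElement]
    pav: pd.DataFrame
    go_annotations: dict[str, set[str]]
    slim_map: dict[str, set[str]]
    slim_feature_schema: dict[str, str]
    effect_schema: dict[str, EffectRule]
    gene_to_group: dict[str, str]
    group_species_counts: dict[str, dict[str, int]]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


# child GO terms the generator annotates with, mapping up to the slim
_GO_CHILDREN = {"GO:0005215": "GO:0022857", "GO:0003700": "GO:0000981"}


def generate_species(spec: FixtureSpec) -> SpeciesFixture:
    """Draw one synthetic species; same spec (and seed) -> identical output."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    prefix = spec.species
    gene_ids = [f"{prefix}.G{i:05d}" for i in range(n)]
    genes = [
        GeneModel(
            gene_ids[i], "chr1",
            i * _GENE_SPACING + 1000, i * _GENE_SPACING + 1000 + _GENE_LENGTH, "+",
        )
        for i in range(n)
    ]

    causal_idx = np.sort(rng.choice(n, size=spec.n_causal, replace=False))
    causal_mask = np.zeros(n, dtype=bool)
    causal_mask[causal_idx] = True
    causal_genes = [gene_ids[i] for i in causal_idx]

    # draw all feature values (spec order fixed -> reproducible)
    values: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for name, entry in spec.features.items():
        kinds[name] = entry.kind
        if entry.kind == "binary":
            p = np.where(causal_mask, entry.causal_p(), entry.null_p())
            values[name] = (rng.random(n) < p).astype(int)
        elif entry.source == "orthogroup":
            values[name] = 1 + rng.poisson(entry.null["mean"], size=n)
        elif entry.kind == "count":
            mean1 = (entry.causal or entry.null)["mean"]
            lam = np.where(causal_mask, mean1, entry.null["mean"])
            values[name] = rng.poisson(lam)
        else:  # fraction (pav): Beta -> Binomial over accessions
            par0, par1 = entry.null, entry.causal or entry.null
            def ab(par):
                return par["mean"] * par["concentration"], (1 - par["mean"]) * par["concentration"]
            a0, b0 = ab(par0)
            a1, b1 = ab(par1)
            p_gene = np.where(causal_mask, rng.beta(a1, b1, size=n), rng.beta(a0, b0, size=n))
            absent = rng.binomial(spec.n_accessions, p_gene)
            values[name] = absent

    # realize raw objects
    variants: list[AnnotatedVariant] = []
    elements: list[ConservedElement] = []
    go_annotations: dict[str, set[str]] = {}
    gene_to_group: dict[str, str] = {}
    group_species_counts: dict[str, dict[str, int]] = {}
    effect_schema: dict[str, EffectRule] = {}
    slim_feature_schema: dict[str, str] = {}
    slim_map = {child: {slim} for slim, child in _GO_CHILDREN.items()}
    pav_mat = np.zeros((n, spec.n_accessions), dtype=int)
    frac_values: dict[str, np.ndarray] = {}

    for name, entry in spec.features.items():
        if entry.source == "variant":
            effect_schema[name] = EffectRule(
                frozenset({entry.term}), require_deleterious=entry.deleterious
            )
        elif entry.source == "go":
            slim_feature_schema[entry.term] = name

    for i, g in enumerate(genes):
        var_offset = 10
        for name, entry in spec.features.items():
            v = values[name][i]
            if entry.source == "variant":
                if v:
                    variants.append(
                        AnnotatedVariant(
                            g.chrom, g.start + var_offset, "SNP", g.gene_id,
                            frozenset({entry.term}),
                            True if entry.deleterious else None,
                        )
                    )
                var_offset += 10
            elif entry.source == "go":
                if v:
                    go_annotations.setdefault(g.gene_id, set()).add(
                        _GO_CHILDREN[entry.term]
                    )
            elif entry.source == "orthogroup":
                if v > 1:
                    group = f"OG_{prefix}_{i:05d}"
                    gene_to_group[g.gene_id] = group
                    group_species_counts[group] = {prefix: int(v)}
            elif entry.source == "pav":
                absent = int(v)
                cols = rng.choice(spec.n_accessions, size=absent, replace=False)
                pav_mat[i, cols] = 1
                frac_values[name] = frac_values.get(
                    name, np.zeros(n, dtype=float)
                )
                frac_values[name][i] = absent / spec.n_accessions

        # conserved elements flank every gene; CNS variant counts
        ce = ConservedElement(f"CE_{i:05d}", g.chrom, g.start - 900, g.start - 300, "CE")
        tfbs = ConservedElement(
            f"TFBS_{i:05d}", g.chrom, g.end + 300, g.end + 900, "TFBS"
        )
        elements.extend([ce, tfbs])
        anchors = {("CE", "SNP"): ce.start, ("CE", "indel"): ce.start + 300,
                   ("TFBS", "SNP"): tfbs.start, ("TFBS", "indel"): tfbs.start + 300}
        for name, entry in spec.features.items():
            if entry.source != "cns":
                continue
            count = int(values[name][i])
            if count > 250:
                raise ValueError(f"{name}: count {count} exceeds element capacity")
            base = anchors[(entry.element_kind, entry.variant_class)]
            for j in range(count):
                variants.append(
                    AnnotatedVariant(g.chrom, base + j, entry.variant_class, None)
                )

    # assemble the canonical feature table
    table = {}
    for name, entry in spec.features.items():
        if entry.kind == "fraction":
            table[name] = frac_values[name]
        else:
            table[name] = values[name]
    feature_table = FeatureTable(
        pd.DataFrame(table, index=pd.Index(gene_ids, name="gene_id")), kinds
    )

    pav = pd.DataFrame(
        pav_mat,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"acc{j:03d}" for j in range(spec.n_accessions)],
    )

    # QTLs: contiguous blocks of the gene order, one planted causal gene
    qtls = []
    lo, hi = spec.qtl_size_range
    hi = min(hi, n)
    for q in range(spec.n_qtls):
        anchor = int(rng.choice(causal_idx))
        size = int(rng.integers(lo, hi + 1))
        start_min = max(0, anchor - size + 1)
        start_max = min(anchor, n - size)
        start = int(rng.integers(start_min, start_max + 1))
        qtls.append(
            QTLRegion(
                qtl_id=f"QTL_{prefix}_{q:02d}",
                gene_ids=gene_ids[start : start + size],
                trait=f"synthetic_trait_{q}",
                causal_gene=gene_ids[anchor],
            )
        )

    return SpeciesFixture(
        spec=spec,
        genes=genes,
        feature_table=feature_table,
        causal_genes=causal_genes,
        qtls=qtls,
        variants=variants,
        elements=elements,
        pav=pav,
        go_annotations=go_annotations,
        slim_map=slim_map,
        slim_feature_schema=slim_feature_schema,
        effect_schema=effect_schema,
        gene_to_group=gene_to_group,
        group_species_counts=group_species_counts,
    )


@dataclass
class OrthologPairFixture:
    """Two synthetic species tied by a fine-grained ortholog map.

    ``species_b.causal_genes`` lists B's own known causal genes;
    ``linked_targets`` are the B genes reachable as orthologs of A's
    causal genes.  With ``ortholog_overlap`` = 1 every linked target is
    drawn from the causal feature distribution; with 0, from the null.
    """

    species_a: SpeciesFixture
    species_b: SpeciesFixture
    omap: OrthologMap
    causal_records: list[CausalGeneRecord]
    known_b: list[str]
    linked_targets: list[str]


def generate_ortholog_pair(
    spec_a: FixtureSpec,
    spec_b: FixtureSpec,
    ortholog_overlap: float = 1.0,
) -> OrthologPairFixture:
    """Generate a donor species A and a target species B whose
    ortholog-linked genes carry causal-like features for a fraction
    ``ortholog_overlap`` of A's causal genes."""
    if not 0.0 <= ortholog_overlap <= 1.0:
        raise ValueError("ortholog_overlap must be in [0, 1]")
    if spec_a.species == spec_b.species:
        raise ValueError("species names must differ")
    fixture_a = generate_species(spec_a)
    n_linked = round(ortholog_overlap * spec_a.n_causal)

    spec_b_grown = replace(spec_b, n_causal=spec_b.n_causal + n_linked)
    fixture_b = generate_species(spec_b_grown)
    causal_like = list(fixture_b.causal_genes)
    rng = np.random.default_rng(np.random.SeedSequence([spec_a.seed, spec_b.seed, 7]))
    rng.shuffle(causal_like)
    known_b = causal_like[: spec_b.n_causal]
    linked_causal_like = causal_like[spec_b.n_causal :]

    null_pool = sorted(set(fixture_b.gene_ids) - set(fixture_b.causal_genes))
    n_null_links = spec_a.n_causal - n_linked
    null_links = list(rng.choice(null_pool, size=n_null_links, replace=False))

    omap = OrthologMap()
    targets = linked_causal_like + null_links
    linked_targets = []
    for a_gene, b_gene in zip(fixture_a.causal_genes, targets):
        omap.add(a_gene, spec_a.species, b_gene, spec_b.species, "fine_grained")
        linked_targets.append(b_gene)

    fixture_b.causal_genes = known_b
    records = [
        CausalGeneRecord(g, spec_a.species, source="synthetic")
        for g in fixture_a.causal_genes
    ] + [CausalGeneRecord(g, spec_b.species, source="synthetic") for g in known_b]
    return OrthologPairFixture(
        species_a=fixture_a,
        species_b=fixture_b,
        omap=omap,
        causal_records=records,
        known_b=known_b,
        linked_targets=linked_targets[:n_linked],
    )
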