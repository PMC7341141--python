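"""File formats.

TSV (tab-delimited, ``#``-prefixed comment/provenance lines) is the
interchange dialect for tables; gene models travel as GFF3 (1-based
inclusive on disk, converted to 0-based half-open on ingest), variants
as VCF with SnpEff-style ``ANN=`` and a SIFT-style ``SIFT=`` INFO
field, conserved elements as BED-like 5-column files.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

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
    "read_table",
    "write_table",
    "read_gff3",
    "write_gff3",
    "read_vcf",
    "write_vcf",
    "read_bed_elements",
    "write_bed_elements",
    "read_pav_matrix",
    "write_pav_matrix",
    "read_gene_term_table",
    "write_gene_term_table",
    "read_slim_map",
    "write_slim_map",
    "read_orthogroups",
    "write_orthogroups",
    "read_effect_schema",
    "write_effect_schema",
    "read_feature_table",
    "write_feature_table",
    "read_causal_genes",
    "read_ortholog_map",
    "read_lineage_table",
    "read_qtls",
    "read_id_map",
]


# ---------------------------------------------------------------- tables

def write_table(
    df: pd.DataFrame, path, provenance: dict | None = None, index: bool = False
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _require_numeric(df: pd.DataFrame, columns: list[str], path) -> None:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"{path}: malformed numeric cell at row {row}, column {col!r}: "
                f"{df[col].iloc[row]!r}"
            )
        df[col] = coerced


# ---------------------------------------------------------------- GFF3

def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tqtgrank\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand if g.strand in '+-' else '.'}\t.\tID={g.gene_id}\n"
            )


def read_gff3(path) -> list[GeneModel]:
    """Gene models from GFF3; converts to 0-based half-open."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        genes.append(
            GeneModel(
                feat.id, feat.seqid, feat.start - 1, feat.end,
                feat.strand if feat.strand in "+-" else "unknown",
            )
        )
    return genes


# ---------------------------------------------------------------- VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: 'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID'">
##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT-style pathogenicity call">
##contig=<ID={chrom},length={length}>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(variants: list[AnnotatedVariant], path) -> None:
    """Minimal single-sample-free VCF with SnpEff-style ANN entries.

    SNPs are written as A>C, indels as AT>A; what matters downstream is
    only the ref/alt length relation, positions and annotations.
    """
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos))
    chrom = variants[0].chrom if variants else "chr1"
    length = max((v.pos for v in variants), default=0) + 10_000
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=chrom, length=length))
        for v in variants:
            ref, alt = ("A", "C") if v.variant_class == "SNP" else ("AT", "A")
            info = []
            if v.effect_terms or v.gene_id:
                terms = "&".join(sorted(v.effect_terms)) or "intergenic_region"
                gid = v.gene_id or ""
                info.append(f"ANN={alt}|{terms}|MODIFIER|{gid}|{gid}")
            if v.deleterious_flag is not None:
                info.append(f"SIFT={'deleterious' if v.deleterious_flag else 'tolerated'}")
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{ref}\t{alt}\t.\t.\t"
                f"{';'.join(info) or '.'}\n"
            )


def read_vcf(path) -> list[AnnotatedVariant]:
    """Annotated variants from a VCF with ANN/SIFT INFO fields.

    Multi-allelic records are split per alternate allele; the variant
    class is derived from ref/alt lengths.  A missing SIFT field leaves
    the deleterious flag unset (``None``), never imputed.
    """
    out = []
    for rec in VCF(str(path)):
        ann_raw = rec.INFO.get("ANN")
        sift_raw = rec.INFO.get("SIFT")
        deleterious = None
        if sift_raw is not None:
            deleterious = "deleterious" in str(sift_raw).lower()
        ann_by_allele: dict[str, tuple[str | None, frozenset[str]]] = {}
        if ann_raw:
            for entry in str(ann_raw).split(","):
                fields = entry.split("|")
                allele = fields[0]
                terms = frozenset(
                    t for t in fields[1].split("&") if t and t != "intergenic_region"
                )
                gene_id = fields[4] if len(fields) > 4 and fields[4] else None
                ann_by_allele[allele] = (gene_id, terms)
        for alt in rec.ALT:
            gene_id, terms = ann_by_allele.get(alt, (None, frozenset()))
            out.append(
                AnnotatedVariant(
                    rec.CHROM,
                    rec.start,
                    AnnotatedVariant.classify(rec.REF, alt),
                    gene_id,
                    terms,
                    deleterious,
                )
            )
    return out


# ---------------------------------------------------------------- BED-like

def write_bed_elements(elements: list[ConservedElement], path) -> None:
    rows = [
        (e.chrom, e.start, e.end, e.element_id, e.element_kind) for e in elements
    ]
    pd.DataFrame(
        rows, columns=["chrom", "start", "end", "element_id", "element_kind"]
    ).to_csv(path, sep="\t", index=False, header=False)


def read_bed_elements(path, element_kind: str | None = None) -> list[ConservedElement]:
    """BED-like file: chrom, start, end, element_id[, kind].

    ``element_kind`` overrides (or supplies) the 5th column; elements
    with start >= end are rejected at parse time.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "element_id", "element_kind"],
    )
    out = []
    for row in df.itertuples(index=False):
        kind = element_kind or row.element_kind
        out.append(
            ConservedElement(str(row.element_id), row.chrom, int(row.start), int(row.end), kind)
        )
    return out


# ---------------------------------------------------------------- matrices

def write_pav_matrix(pav: pd.DataFrame, path) -> None:
    pav.to_csv(path, sep="\t", index=True, index_label="gene_id")


def read_pav_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")


# ---------------------------------------------------------------- GO / slim

def write_gene_term_table(annotations: dict[str, set[str]], path) -> None:
    rows = [
        (g, t) for g in sorted(annotations) for t in sorted(annotations[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "go_term"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_term_table(path) -> dict[str, set[str]]:
    df = read_table(path, required=["gene_id", "go_term"])
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.gene_id), set()).add(str(row.go_term))
    return out


def write_slim_map(slim_map: dict[str, set[str]], path) -> None:
    rows = [(t, s) for t in sorted(slim_map) for s in sorted(slim_map[t])]
    pd.DataFrame(rows, columns=["go_term", "slim_term"]).to_csv(
        path, sep="\t", index=False
    )


def read_slim_map(path) -> dict[str, set[str]]:
    df = read_table(path, required=["go_term", "slim_term"])
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.go_term), set()).add(str(row.slim_term))
    return out


# ---------------------------------------------------------------- orthogroups

def write_orthogroups(
    gene_to_group: dict[str, str],
    group_species_counts: dict[str, dict[str, int]],
    species: str,
    path,
) -> None:
    """Long-format orthogroup membership: orthogroup, species, gene_id.

    Same-species members beyond the focal gene are written as derived
    placeholder IDs so that per-species counts round-trip.
    """
    rows = []
    for gid in sorted(gene_to_group):
        group = gene_to_group[gid]
        rows.append((group, species, gid))
        counts = group_species_counts.get(group, {})
        for sp in sorted(counts):
            extra = counts[sp] - (1 if sp == species else 0)
            for j in range(extra):
                rows.append((group, sp, f"{gid}.paralog{j + 1}"))
    pd.DataFrame(rows, columns=["orthogroup", "species", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_orthogroups(
    path, universe: set[str] | None = None
) -> tuple[dict[str, str], dict[str, dict[str, int]]]:
    """Returns (gene -> orthogroup for genes in ``universe``,
    orthogroup -> per-species member counts)."""
    df = read_table(path, required=["orthogroup", "species", "gene_id"])
    gene_to_group: dict[str, str] = {}
    counts: dict[str, dict[str, int]] = {}
    for row in df.itertuples(index=False):
        group, sp, gid = str(row.orthogroup), str(row.species), str(row.gene_id)
        counts.setdefault(group, {})
        counts[group][sp] = counts[group].get(sp, 0) + 1
        if universe is None or gid in universe:
            if gid in gene_to_group and gene_to_group[gid] != group:
                raise ValueError(f"gene {gid} assigned to two orthogroups")
            gene_to_group[gid] = group
    return gene_to_group, counts


# ---------------------------------------------------------------- schema

def write_effect_schema(schema: dict[str, EffectRule], path) -> None:
    data = {
        name: {
            "terms": sorted(rule.terms),
            "require_deleterious": rule.require_deleterious,
        }
        for name, rule in schema.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_effect_schema(path) -> dict[str, EffectRule]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return {
        name: EffectRule(
            frozenset(entry["terms"]), bool(entry.get("require_deleterious", False))
        )
        for name, entry in data.items()
    }


# ---------------------------------------------------------------- feature table

def write_feature_table(table: FeatureTable, path, provenance: dict | None = None) -> None:
    """TSV with gene_id index plus a ``<path>.kinds.tsv`` sidecar that
    records each feature's declared kind."""
    path = Path(path)
    write_table(table.values.reset_index(), path, provenance=provenance)
    kinds = pd.DataFrame(
        sorted(table.kinds.items()), columns=["feature", "kind"]
    )
    kinds.to_csv(path.with_suffix(path.suffix + ".kinds.tsv"), sep="\t", index=False)


def read_feature_table(path) -> FeatureTable:
    path = Path(path)
    df = read_table(path, required=["gene_id"]).set_index("gene_id")
    _require_numeric(df, list(df.columns), path)
    kinds_path = path.with_suffix(path.suffix + ".kinds.tsv")
    kinds_df = pd.read_csv(kinds_path, sep="\t")
    kinds = dict(zip(kinds_df["feature"], kinds_df["kind"]))
    return FeatureTable(df, kinds)


# ---------------------------------------------------------------- curated lists

def read_causal_genes(path) -> list[CausalGeneRecord]:
    df = read_table(path, required=["gene_id", "species"])
    return [
        CausalGeneRecord(
            str(r.gene_id), str(r.species),
            str(getattr(r, "trait", "") or ""), str(getattr(r, "source", "") or ""),
        )
        for r in df.itertuples(index=False)
    ]


def read_ortholog_map(path) -> OrthologMap:
    df = read_table(
        path,
        required=["causal_id", "causal_species", "ortholog_id", "ortholog_species", "kind"],
    )
    omap = OrthologMap()
    for r in df.itertuples(index=False):
        omap.add(
            str(r.causal_id), str(r.causal_species),
            str(r.ortholog_id), str(r.ortholog_species), str(r.kind),
        )
    return omap


def read_lineage_table(path) -> dict[str, str]:
    df = read_table(path, required=["species", "lineage"])
    return {str(r.species): str(r.lineage) for r in df.itertuples(index=False)}


def read_id_map(path) -> dict[str, str]:
    df = read_table(path, required=["source_id", "target_id"])
    return {str(r.source_id): str(r.target_id) for r in df.itertuples(index=False)}


def read_qtls(path) -> list[QTLRegion]:
    """QTL definitions as a TSV with one row per (qtl_id, gene_id);
    optional ``trait`` and ``causal`` (0/1 flag on the causal row)."""
    df = read_table(path, required=["qtl_id", "gene_id"])
    qtls = []
    for qtl_id, grp in df.groupby("qtl_id", sort=False):
        trait = str(grp["trait"].iloc[0]) if "trait" in grp.columns else ""
        causal = None
        if "causal" in grp.columns:
            flagged = grp.loc[grp["causal"].astype(int) == 1, "gene_id"]
            if len(flagged) > 1:
                raise ValueError(f"QTL {qtl_id}: multiple causal flags")
            if len(flagged) == 1:
                causal = str(flagged.iloc[0])
        qtls.append(
            QTLRegion(str(qtl_id), [str(g) for g in grp["gene_id"]], trait, causal)
        )
    return qtls
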