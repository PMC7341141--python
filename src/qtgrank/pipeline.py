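"""End-to-end plumbing: raw files -> feature table -> training set ->
ensemble -> per-QTL ranking -> validation report.

Each stage is a thin composition of the library modules; the CLI maps
one subcommand onto each function here.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import io as qio
from .features import (
    FeatureTable,
    aggregate_go_features,
    attach_paralog_counts,
    compute_percent_absence,
    count_cns_polymorphisms,
    encode_variant_features,
    merge_feature_fragments,
)
from .model import ModelConfig, score_genes, train_ensemble
from .orthology import expand_training_set
from .simulate import SpeciesFixture
from .validation import ValidationSummary, rank_qtl, validate

__all__ = [
    "build_feature_table_from_files",
    "write_fixture_raw",
    "rank_qtls_with_model",
    "run_pipeline",
]


def build_feature_table_from_files(
    vcf_path,
    gff_path,
    ce_path,
    tfbs_path,
    pav_path,
    go_path,
    slim_map_path,
    orthogroups_path,
    species: str,
    slim_feature_schema: dict[str, str],
    effect_schema=None,
    window: int = 1000,
) -> FeatureTable:
    """Assemble the full per-gene feature table from raw inputs.

    Fragments are merged over the GFF3 gene universe with the standard
    imputation (binary/count 0, paralog copy number 1).
    """
    genes = qio.read_gff3(gff_path)
    gene_ids = [g.gene_id for g in genes]
    variants = qio.read_vcf(vcf_path)
    elements = qio.read_bed_elements(ce_path, element_kind="CE") + qio.read_bed_elements(
        tfbs_path, element_kind="TFBS"
    )
    frag_poly = encode_variant_features(variants, genes, effect_schema)
    frag_cns = count_cns_polymorphisms(variants, elements, genes, window=window)
    frag_pav = compute_percent_absence(qio.read_pav_matrix(pav_path))
    frag_go = aggregate_go_features(
        qio.read_gene_term_table(go_path),
        qio.read_slim_map(slim_map_path),
        slim_feature_schema,
    )
    gene_to_group, counts = qio.read_orthogroups(orthogroups_path, universe=set(gene_ids))
    frag_paralog = attach_paralog_counts(gene_to_group, counts, species, gene_ids)
    return merge_feature_fragments(
        [frag_poly, frag_cns, frag_pav, frag_go, frag_paralog], gene_ids
    )


def write_fixture_raw(fixture: SpeciesFixture, out_dir) -> dict[str, Path]:
    """Write a synthetic species' raw files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff": out / "genes.gff3",
        "vcf": out / "variants.vcf",
        "ce": out / "conserved_elements.bed",
        "tfbs": out / "tfbs.bed",
        "pav": out / "presence_absence.tsv",
        "go": out / "go_annotations.tsv",
        "slim_map": out / "go_slim_map.tsv",
        "orthogroups": out / "orthogroups.tsv",
        "effect_schema": out / "effect_schema.yaml",
        "causal": out / "causal_genes.tsv",
        "qtls": out / "qtls.tsv",
        "features": out / "features.tsv",
    }
    qio.write_gff3(fixture.genes, paths["gff"])
    qio.write_vcf(fixture.variants, paths["vcf"])
    qio.write_bed_elements(
        [e for e in fixture.elements if e.element_kind == "CE"], paths["ce"]
    )
    qio.write_bed_elements(
        [e for e in fixture.elements if e.element_kind == "TFBS"], paths["tfbs"]
    )
    qio.write_pav_matrix(fixture.pav, paths["pav"])
    qio.write_gene_term_table(fixture.go_annotations, paths["go"])
    qio.write_slim_map(fixture.slim_map, paths["slim_map"])
    qio.write_orthogroups(
        fixture.gene_to_group,
        fixture.group_species_counts,
        fixture.spec.species,
        paths["orthogroups"],
    )
    qio.write_effect_schema(fixture.effect_schema, paths["effect_schema"])
    qio.write_table(
        pd.DataFrame(
            {
                "gene_id": fixture.causal_genes,
                "species": fixture.spec.species,
                "trait": "synthetic",
                "source": "simulated",
            }
        ),
        paths["causal"],
    )
    qtl_rows = [
        {
            "qtl_id": q.qtl_id,
            "gene_id": g,
            "trait": q.trait,
            "causal": int(g == q.causal_gene),
        }
        for q in fixture.qtls
        for g in q.gene_ids
    ]
    qio.write_table(pd.DataFrame(qtl_rows), paths["qtls"])
    qio.write_feature_table(
        fixture.feature_table,
        paths["features"],
        provenance={"seed": fixture.spec.seed, "species": fixture.spec.species},
    )
    return paths


def rebuild_feature_table(fixture_dir, species: str, slim_feature_schema=None) -> FeatureTable:
    """Run feature extraction over a fixture directory's raw files."""
    d = Path(fixture_dir)
    if slim_feature_schema is None:
        slim_feature_schema = {
            "GO:0005215": "is_transporter",
            "GO:0003700": "is_transcription_factor",
        }
    return build_feature_table_from_files(
        d / "variants.vcf",
        d / "genes.gff3",
        d / "conserved_elements.bed",
        d / "tfbs.bed",
        d / "presence_absence.tsv",
        d / "go_annotations.tsv",
        d / "go_slim_map.tsv",
        d / "orthogroups.tsv",
        species,
        slim_feature_schema,
        effect_schema=qio.read_effect_schema(d / "effect_schema.yaml"),
    )


def rank_qtls_with_model(
    features: FeatureTable,
    positives: list[str],
    qtls,
    config: ModelConfig,
    aggregation: str = "votes",
) -> list[tuple]:
    """Train the ensemble once and rank every QTL with it."""
    ensemble = train_ensemble(features, positives, config)
    scores = score_genes(ensemble, features, features.gene_ids, aggregation=aggregation)
    return [(qtl, rank_qtl(scores, qtl)) for qtl in qtls]


def run_pipeline(
    fixture_dir,
    out_dir,
    species: str,
    config: ModelConfig,
    cutoffs=(5, 10, 20),
) -> ValidationSummary:
    """features -> trainset -> train -> rank -> validate over a fixture
    directory; writes ranked TSVs and a JSON validation report."""
    fixture_dir, out = Path(fixture_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    features = rebuild_feature_table(fixture_dir, species)
    causal = qio.read_causal_genes(fixture_dir / "causal_genes.tsv")
    from .orthology import OrthologMap

    positives = expand_training_set(
        causal, OrthologMap(), species, mode="known_only"
    )
    qtls = qio.read_qtls(fixture_dir / "qtls.tsv")
    ranked = rank_qtls_with_model(features, list(positives), qtls, config)

    provenance = {"seed": config.seed, "species": species}
    rank_rows = []
    for qtl, res in ranked:
        for gid in res.gene_ids:
            rank_rows.append(
                {
                    "qtl_id": qtl.qtl_id,
                    "gene_id": gid,
                    "score": res.scores[gid],
                    "rank": res.ranks[gid],
                    "percent_rank": res.percent_ranks[gid],
                }
            )
    qio.write_table(pd.DataFrame(rank_rows), out / "ranked_genes.tsv", provenance)

    summary = validate(ranked, cutoffs=list(cutoffs))
    report = {
        "cutoffs": summary.cutoffs,
        "recall_at_cutoff": {str(k): v for k, v in summary.recall_at_cutoff.items()},
        "avg_precision_at_cutoff": {
            str(k): v for k, v in summary.avg_precision_at_cutoff.items()
        },
        "theoretical_background": {
            str(k): v for k, v in summary.theoretical_background.items()
        },
        "per_qtl": summary.per_qtl,
        "provenance": provenance,
    }
    with open(out / "validation_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    qio.write_table(pd.DataFrame(summary.per_qtl), out / "validation_per_qtl.tsv", provenance)
    return summary
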