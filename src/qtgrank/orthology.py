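"""Training-set construction from known causal genes and their orthologs.

A model for a target species can be trained on (i) causal genes cloned
in that species, (ii) target-species orthologs of causal genes cloned
in *other* species, or (iii) both.  Orthology calls carry a kind:
``fine_grained`` (pairwise phylogenetic call), ``group_member``
(whole-orthogroup fallback) or ``collinear`` (synteny-mapped).  For
each causal gene, fine-grained orthologs are preferred; only when none
exist do all group members stand in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CausalGeneRecord",
    "OrthologEntry",
    "OrthologMap",
    "TrainingSet",
    "apply_fine_grained_preference",
    "expand_training_set",
    "remap_gene_ids",
]

ORTHOLOGY_KINDS = ("fine_grained", "group_member", "collinear")
MODES = ("known_only", "orthologs_only", "combined")


@dataclass(frozen=True)
class CausalGeneRecord:
    """A literature-curated causal gene; (gene_id, species) is unique."""

    gene_id: str
    species: str
    trait: str = ""
    source: str = ""


@dataclass(frozen=True)
class OrthologEntry:
    target_gene_id: str
    target_species: str
    orthology_kind: str

    def __post_init__(self) -> None:
        if self.orthology_kind not in ORTHOLOGY_KINDS:
            raise ValueError(f"unknown orthology_kind {self.orthology_kind!r}")


@dataclass
class OrthologMap:
    """causal (gene_id, species) -> ortholog entries in other species."""

    entries: dict[tuple[str, str], list[OrthologEntry]] = field(default_factory=dict)

    def add(
        self,
        causal_id: str,
        causal_species: str,
        target_gene_id: str,
        target_species: str,
        kind: str,
    ) -> None:
        self.entries.setdefault((causal_id, causal_species), []).append(
            OrthologEntry(target_gene_id, target_species, kind)
        )


@dataclass
class TrainingSet:
    """Labelled positives plus the negative-sampling specification.

    ``positives`` maps gene_id -> provenance ("known_causal" or
    "ortholog"); ``negative_pool`` is the set negatives are drawn from
    (disjoint from positives); ``exclusions`` are genes barred from the
    positives (e.g. an external validation set).
    """

    positives: dict[str, str]
    negative_pool: list[str] = field(default_factory=list)
    ratio: float = 1.0
    exclusions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = set(self.positives) & self.exclusions
        if bad:
            raise ValueError(f"positives overlap exclusions: {sorted(bad)}")
        bad = set(self.positives) & set(self.negative_pool)
        if bad:
            raise ValueError(f"negative pool overlaps positives: {sorted(bad)}")

    @property
    def positive_ids(self) -> list[str]:
        return list(self.positives)


def apply_fine_grained_preference(
    entries: list[OrthologEntry], target_species: str
) -> list[OrthologEntry]:
    """Select one causal gene's orthologs in the target species.

    If any fine-grained call exists for the target species, only those
    are returned; otherwise all group-member (or collinear-mapped)
    entries for the target species.
    """
    in_target = [e for e in entries if e.target_species == target_species]
    fine = [e for e in in_target if e.orthology_kind == "fine_grained"]
    return fine if fine else in_target


def expand_training_set(
    causal: list[CausalGeneRecord],
    omap: OrthologMap,
    target_species: str,
    mode: str = "combined",
    lineage_constraint: str = "none",
    lineage_table: dict[str, str] | None = None,
    exclusions: set[str] | None = None,
) -> dict[str, str]:
    """Positive training genes for ``target_species`` with provenance.

    ``known_only`` takes causal genes cloned in the target species;
    ``orthologs_only`` takes target-species orthologs of causal genes
    from *other* species (fine-grained preferred per causal gene);
    ``combined`` is their union, with provenance ``known_causal``
    winning on overlap.  Under ``lineage_constraint='same_lineage'``
    only orthologs of causal genes from the target's own lineage
    (monocot or eudicot) are transferred; species absent from the
    lineage table fail closed.  ``exclusions`` are removed last.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if lineage_constraint not in ("none", "same_lineage"):
        raise ValueError(f"unknown lineage_constraint {lineage_constraint!r}")
    exclusions = exclusions or set()

    seen: set[tuple[str, str]] = set()
    for rec in causal:
        key = (rec.gene_id, rec.species)
        if key in seen:
            raise ValueError(f"duplicate causal gene record: {key}")
        seen.add(key)

    if lineage_constraint == "same_lineage":
        if lineage_table is None or target_species not in lineage_table:
            raise ValueError(
                f"target species {target_species!r} missing from lineage table"
            )
        target_lineage = lineage_table[target_species]

    positives: dict[str, str] = {}

    if mode in ("orthologs_only", "combined"):
        for rec in causal:
            if rec.species == target_species:
                continue  # only cross-species transfer
            if lineage_constraint == "same_lineage":
                if lineage_table.get(rec.species) != target_lineage:
                    continue
            entries = omap.entries.get((rec.gene_id, rec.species), [])
            for e in apply_fine_grained_preference(entries, target_species):
                positives.setdefault(e.target_gene_id, "ortholog")

    if mode in ("known_only", "combined"):
        for rec in causal:
            if rec.species == target_species:
                positives[rec.gene_id] = "known_causal"

    for gid in exclusions:
        positives.pop(gid, None)

    if not positives:
        raise ValueError(
            f"empty positive set for target {target_species!r} in mode {mode!r}; "
            "check the species label and training mode"
        )
    return positives


def remap_gene_ids(
    positives: dict[str, str],
    id_map: dict[str, str],
    dropped: list[str] | None = None,
) -> dict[str, str]:
    """Substitute gene IDs through an injective map (e.g. collinearity
    between a domesticated species and its wild ancestor).

    IDs absent from the map are dropped and reported through
    ``dropped`` when a list is supplied.
    """
    targets = list(id_map.values())
    if len(set(targets)) != len(targets):
        raise ValueError("id_map is not injective")
    out: dict[str, str] = {}
    for gid, provenance in positives.items():
        if gid in id_map:
            out[id_map[gid]] = provenance
        elif dropped is not None:
            dropped.append(gid)
    return out
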