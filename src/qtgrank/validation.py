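"""QTL gene ranking and external-validation arithmetic.

Genes inside a QTL interval are ordered by ensemble score; a gene's
percent rank is ``ceil(100 * rank / N)`` so the top gene of a 144-gene
QTL sits at 1% and the top 20% of a 335-gene interval holds exactly
ceil(0.2 * 335) = 67 genes.  Validation summarizes, over a set of QTLs
with cloned causal genes, the recall and average per-QTL precision of
the causal gene at top-k% cutoffs, against a theoretical background of
k/100 (the chance of catching the causal gene by picking k% of the
interval at random).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "QTLRegion",
    "RankResult",
    "ValidationSummary",
    "rank_qtl",
    "top_fraction_count",
    "recall_at_cutoffs",
    "average_precision_at_cutoffs",
    "theoretical_background",
    "summary_from_percent_ranks",
    "validate",
    "fisher_compare",
    "enrichment_test",
    "expression_overlap_filter",
]


@dataclass
class QTLRegion:
    """A QTL as its member gene list, optionally tagged with the cloned
    causal gene for validation."""

    qtl_id: str
    gene_ids: list[str]
    trait: str = ""
    causal_gene: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"QTL {self.qtl_id}: empty gene list")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"QTL {self.qtl_id}: duplicate gene IDs")
        if self.causal_gene is not None and self.causal_gene not in self.gene_ids:
            raise ValueError(
                f"QTL {self.qtl_id}: causal gene {self.causal_gene!r} not in interval"
            )


@dataclass
class RankResult:
    """Per-gene score, rank (1 = best, ties get the mean of the tied
    span) and percent rank within one QTL."""

    qtl_id: str
    gene_ids: list[str]
    scores: dict[str, float]
    ranks: dict[str, float]
    percent_ranks: dict[str, int]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class ValidationSummary:
    cutoffs: list[float]
    recall_at_cutoff: dict[float, float]
    avg_precision_at_cutoff: dict[float, float]
    theoretical_background: dict[float, float]
    per_qtl: list[dict] = field(default_factory=list)


def rank_qtl(scores: dict[str, float], qtl: QTLRegion) -> RankResult:
    """Rank a QTL's genes by descending ensemble score.

    Tied scores receive the mean of the tied rank span; percent rank is
    ``ceil(100 * rank / N)``.
    """
    missing = [g for g in qtl.gene_ids if g not in scores]
    if missing:
        raise KeyError(f"QTL {qtl.qtl_id}: no score for genes {missing}")
    vals = np.array([scores[g] for g in qtl.gene_ids], dtype=float)
    ranks = stats.rankdata(-vals, method="average")
    n = len(qtl.gene_ids)
    rank_map = {g: float(r) for g, r in zip(qtl.gene_ids, ranks)}
    pct = {g: math.ceil(100.0 * r / n) for g, r in rank_map.items()}
    return RankResult(
        qtl_id=qtl.qtl_id,
        gene_ids=sorted(qtl.gene_ids, key=lambda g: rank_map[g]),
        scores={g: float(scores[g]) for g in qtl.gene_ids},
        ranks=rank_map,
        percent_ranks=pct,
    )


def top_fraction_count(n_genes: int, cutoff_percent: float) -> int:
    """Number of genes prioritized at a top-k% cutoff: ceil(k/100 * N)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 < cutoff_percent <= 100:
        raise ValueError("cutoff must be in (0, 100]")
    return math.ceil(cutoff_percent / 100.0 * n_genes)


def _causal_percent_rank(qtl: QTLRegion, result: RankResult) -> int:
    if qtl.causal_gene is None:
        raise ValueError(f"QTL {qtl.qtl_id} has no causal gene tag")
    return result.percent_ranks[qtl.causal_gene]


def recall_at_cutoffs(
    validation: list[tuple[QTLRegion, RankResult]],
    cutoffs: list[float] = (5, 10, 20),
) -> dict[float, float]:
    """Fraction of QTLs whose causal gene has percent rank <= cutoff.

    A causal gene sitting exactly on the cutoff counts as recalled.
    """
    if not validation:
        raise ValueError("no validation QTLs")
    out = {}
    for f in cutoffs:
        hits = sum(
            1 for qtl, res in validation if _causal_percent_rank(qtl, res) <= f
        )
        out[f] = hits / len(validation)
    return out


def average_precision_at_cutoffs(
    validation: list[tuple[QTLRegion, RankResult]],
    cutoffs: list[float] = (5, 10, 20),
) -> dict[float, float]:
    """Mean per-QTL precision of the prioritized gene set.

    For a QTL with N genes, the prioritized set at cutoff k holds
    ceil(k/100 * N) genes and contains at most one causal gene, so the
    QTL's precision is 1/ceil(k/100 * N) when the causal gene is
    recalled and 0 otherwise; the summary averages over QTLs.
    """
    if not validation:
        raise ValueError("no validation QTLs")
    out = {}
    for f in cutoffs:
        precisions = []
        for qtl, res in validation:
            prioritized = top_fraction_count(res.n_genes, f)
            recalled = _causal_percent_rank(qtl, res) <= f
            precisions.append((1.0 if recalled else 0.0) / prioritized)
        out[f] = float(np.mean(precisions))
    return out


def theoretical_background(cutoff_percent: float) -> float:
    """Chance of including the causal gene when k% of a QTL's genes are
    picked at random: k/100."""
    if not 0 < cutoff_percent <= 100:
        raise ValueError("cutoff must be in (0, 100]")
    return cutoff_percent / 100.0


def validate(
    validation: list[tuple[QTLRegion, RankResult]],
    cutoffs: list[float] = (5, 10, 20),
) -> ValidationSummary:
    """Full external-validation summary over QTLs with known causal genes."""
    cutoffs = list(cutoffs)
    per_qtl = [
        {
            "qtl_id": qtl.qtl_id,
            "trait": qtl.trait,
            "causal_gene": qtl.causal_gene,
            "genes_in_qtl": res.n_genes,
            "causal_percent_rank": _causal_percent_rank(qtl, res),
        }
        for qtl, res in validation
    ]
    return ValidationSummary(
        cutoffs=cutoffs,
        recall_at_cutoff=recall_at_cutoffs(validation, cutoffs),
        avg_precision_at_cutoff=average_precision_at_cutoffs(validation, cutoffs),
        theoretical_background={f: theoretical_background(f) for f in cutoffs},
        per_qtl=per_qtl,
    )


def summary_from_percent_ranks(
    genes_in_qtl: list[int],
    percent_ranks: list[float],
    cutoffs: list[float] = (5, 10, 20),
) -> ValidationSummary:
    """Validation arithmetic from printed per-QTL results.

    Curated validation tables report, per QTL, only the interval's
    gene count and the causal gene's percent rank; recall and average
    precision at each cutoff follow directly (the prioritized set at
    cutoff k holds ceil(k/100 * N) genes, at most one of them causal).
    """
    if len(genes_in_qtl) != len(percent_ranks) or not genes_in_qtl:
        raise ValueError("need equal-length, non-empty size and rank lists")
    cutoffs = list(cutoffs)
    recall, precision = {}, {}
    for f in cutoffs:
        hits = [pr <= f for pr in percent_ranks]
        recall[f] = sum(hits) / len(hits)
        precision[f] = float(
            np.mean(
                [
                    (1.0 if hit else 0.0) / top_fraction_count(n, f)
                    for n, hit in zip(genes_in_qtl, hits)
                ]
            )
        )
    per_qtl = [
        {"genes_in_qtl": n, "causal_percent_rank": pr}
        for n, pr in zip(genes_in_qtl, percent_ranks)
    ]
    return ValidationSummary(
        cutoffs=cutoffs,
        recall_at_cutoff=recall,
        avg_precision_at_cutoff=precision,
        theoretical_background={f: theoretical_background(f) for f in cutoffs},
        per_qtl=per_qtl,
    )


def fisher_compare(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> float:
    """Two-sided Fisher's exact p-value comparing two models' recalled /
    not-recalled counts.

    Degenerate tables (a zero margin) carry no information and return
    p = 1 with a warning.
    """
    table = np.array([counts_a, counts_b])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def enrichment_test(
    causal_values: list[float], genome_values: list[float]
) -> tuple[float, float]:
    """Mann-Whitney U comparison of a feature between causal genes and
    genome genes; returns (U, two-sided p).

    Small samples get an exact permutation p-value (valid with ties,
    two-sided via the distance of U from its null mean, matching the
    point-probability convention used for Fisher's test); larger
    samples use the tie-corrected normal approximation.
    """
    if not len(causal_values) or not len(genome_values):
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(causal_values), len(genome_values)
    pooled = np.asarray(list(causal_values) + list(genome_values), dtype=float)
    if len(set(pooled.tolist())) == 1:
        return n1 * n2 / 2.0, 1.0
    u_obs = float(
        stats.mannwhitneyu(
            causal_values, genome_values, alternative="two-sided", method="asymptotic"
        ).statistic
    )
    if math.comb(n1 + n2, n1) <= 5000:
        # exact null distribution of U over all group assignments
        mid = (pooled[:, None] > pooled[None, :]).astype(float)
        mid += 0.5 * (pooled[:, None] == pooled[None, :])
        np.fill_diagonal(mid, 0.0)
        mu = n1 * n2 / 2.0
        hits = total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            rest = [i for i in range(n1 + n2) if i not in set(idx)]
            u = mid[np.ix_(list(idx), rest)].sum()
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
                hits += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(
        causal_values, genome_values, alternative="two-sided", method="asymptotic"
    )
    return u_obs, float(res.pvalue)


def expression_overlap_filter(
    rank_result: RankResult,
    fold_changes: dict[str, tuple[float, float]],
    cutoff_percent: float = 20,
    fc_threshold: float = 2.0,
    excluded: list[str] | None = None,
) -> list[str]:
    """Intersect the top-ranked genes with expression evidence.

    Keeps genes with percent rank <= cutoff that are up-regulated more
    than ``fc_threshold``-fold in either of two tissue contrasts (e.g.
    internode meristem or elongation zone vs maturation zone).  Genes
    absent from the expression table are excluded, not imputed, and
    reported through ``excluded`` when a list is supplied.
    """
    out = []
    for gid in rank_result.gene_ids:  # already best-to-worst
        if rank_result.percent_ranks[gid] > cutoff_percent:
            continue
        if gid not in fold_changes:
            if excluded is not None:
                excluded.append(gid)
            continue
        fc_a, fc_b = fold_changes[gid]
        if fc_a > fc_threshold or fc_b > fc_threshold:
            out.append(gid)
    return out
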