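# Methods

## Problem setting and model

A QTL interval from linkage mapping contains N genes, one of which is
causal for the mapped trait. `qtgrank` treats causal-gene
identification as a positive-unlabelled classification problem: a
small positive set P (genes cloned as causal, or target-species
orthologs of genes cloned as causal elsewhere) against a genome of
unlabelled genes, almost all of which are non-causal.

The classifier is a negative-resampling random-forest ensemble. For
each of K iterations, a "negative" set N_i of size r·|P| is drawn
uniformly without replacement from the genome excluding P, and a
random forest is fitted on P ∪ N_i. A gene's ensemble score is the
fraction of the K forests that classify it positive (each forest
voting by its own tree majority). Resampling the negatives averages
out the mislabelled causal genes that any single draw contains, and
the vote fraction is a selection frequency, not a calibrated
probability — only its within-QTL ordering is used. Mean positive-class
probability is available as an alternative aggregation
(`aggregation="probability"`).

## Features

Per gene, from standard annotation resources:

| feature | kind | source |
|---|---|---|
| `is_nonsyn_deleterious`, `is_synonymous`, `is_frameshift`, … | binary | SnpEff/SIFT-style variant effects |
| `CE_snp`, `CE_indel`, `TFBS_snp`, `TFBS_indel` | count | variants inside conserved elements near the gene |
| `percent_absence` | fraction | presence/absence across re-sequenced accessions |
| `is_transporter`, `is_transcription_factor` | binary | GO terms rolled up through a GO-slim |
| `paralog_copy_number` | count | same-species orthogroup size |

Conventions that matter:

- Coordinates are 0-based half-open internally; GFF3 (1-based
  inclusive) is converted on ingest. A conserved element is assigned
  to every gene whose interval extended by the flank window (default
  1000 bp, strand-agnostic) it overlaps; a variant in an element
  shared by two genes counts for both, and overlapping same-kind
  elements never double-count a variant for one gene.
- The effect-term → feature schema is a YAML configuration
  (`qtgrank/data/effect_schema.yaml`); annotation dialects vary, so
  unknown effect terms are counted and warned about, never fatal.
  Variants with no SIFT-style call cannot set
  `is_nonsyn_deleterious` (pathogenicity is not imputed). Multi-allelic
  records are split per alternate allele; SNP vs indel follows
  ref/alt lengths.
- Missing data at merge time: binary and count features impute 0,
  paralog copy number imputes 1 (a gene is always its own paralog).

## Training sets from orthology

`expand_training_set` supports three modes: `known_only` (causal
genes cloned in the target species), `orthologs_only` (target-species
orthologs of causal genes cloned in *other* species; self-species
transfer is excluded), and `combined` (their union, provenance
`known_causal` winning). Per causal gene, fine-grained (pairwise
phylogenetic) ortholog calls are preferred; only when none exist are
all orthogroup members (or synteny-mapped IDs) used, each with equal
weight. An optional lineage constraint restricts transfer to donors
in the target's lineage (monocot/eudicot); species missing from the
lineage table fail closed. Genes reserved for external validation are
removed from the positives last, so exclusion always wins.

## Model evaluation

- **Cross-validation**: per repeat (default 50), a fresh negative
  draw, stratified 5-fold splitting (equal class ratio per fold, which
  also prevents positive-free folds), one forest per training fold;
  the held-out probabilities are pooled into one AUC-ROC per repeat.
  F1/precision/recall are reported at a 0.5 probability threshold —
  the threshold is an implementation choice, documented rather than
  inherited.
- **Hyperparameters**: exhaustive grid search on mean CV AUC; ties
  break toward smaller `n_trees`, then smaller `neg_pos_ratio`, so
  the argmax is deterministic.
- **Feature importance**: leave-one-out ΔAUC = mean CV AUC with all
  features − mean CV AUC with the feature removed, both runs under
  identical seeds so the difference isolates the feature.

Defaults (all overridable): 200 trees, `max_features = sqrt(p)`,
`min_samples_split = 2`, negatives-per-positive ratio 1 with a
suggested tuning grid {1, 3, 5, 10}, K = 200 ensemble iterations
(vote fractions then resolve to ~0.005; tests use K = 3–10 and 25–50
trees). All randomness flows from one integer seed; per-iteration
seeds derive from `numpy.random.SeedSequence(seed, iteration)`, so
the train → score path is bit-reproducible.

## Ranking and validation arithmetic

Within a QTL, genes sort by descending score; tied scores share the
mean of their rank span. Percent rank is ⌈100·k/N⌉ and the top-f% set
holds ⌈f·N/100⌉ genes. These ceiling conventions are asserted
deliberately: they make the best gene of a 144-gene interval sit at
1% and the top 20% of 335 genes count 67, and they reproduce the
curated sorghum panel's printed average precisions
(0.065/0.041/0.044) exactly under rational arithmetic. Published
percent ranks are consumed as printed — some printed values (e.g. 3%
in a 27-gene interval) are not expressible as ⌈100·k/N⌉ for any
integer k, so no convention can regenerate every printed value from
an integer rank; the arithmetic therefore operates on the printed
numbers, not on reconstructed ranks. One boundary subtlety follows
from the pair of conventions: with distinct scores, exactly
⌊f·N/100⌋ genes sit at percent rank ≤ f, one fewer than the
prioritized-set size ⌈f·N/100⌉ whenever f·N/100 is fractional (they
coincide when it is integral, as for 20% of 335). Recall uses the
percent-rank criterion and precision divides by the prioritized-set
size — the combination that reproduces the published numbers.

- Recall at cutoff f: fraction of validation QTLs whose causal gene
  has percent rank ≤ f (a gene exactly on the boundary counts).
- Average precision at f: mean over QTLs of
  [causal recalled] / ⌈f·N/100⌉.
- Theoretical background: f/100, the chance of catching the causal
  gene when f% of the interval is picked at random.
- Model comparison: two-sided Fisher's exact test on
  recalled/not-recalled counts (point-probability method; degenerate
  margins return p = 1 with a warning).
- Feature enrichment: Mann-Whitney U, exact by permutation
  enumeration for small samples (two-sided via distance of U from its
  null mean, valid under ties and consistent with the Fisher
  convention), tie-corrected normal approximation otherwise.
- Candidate filtering: the expression-overlap filter intersects the
  top-f% genes with genes up-regulated more than a fold-change
  threshold (default 2) in either of two tissue contrasts; genes
  absent from the expression table are excluded and reported, never
  imputed.

## Synthetic species

The generator emits a complete set of raw inputs (GFF3, VCF with
ANN/SIFT fields, CE/TFBS BED, presence/absence matrix, GO and
orthogroup tables) for an artificial genome, with a chosen causal
subset drawn from shifted distributions. Distribution families are
the simplest per feature kind: Bernoulli for binary flags (causal
effect as an odds multiplier), Poisson for counts (shifted mean),
Beta-Binomial for percent absence, 1 + Poisson for paralog copy
number. Default effects follow the direction observed for real causal
genes: 4× odds of a deleterious non-synonymous SNP, CE SNP mean
0.5 → 1.5 (indels 0.2 → 0.6), mean percent absence 0.02 → 0.10 over
80 accessions; TFBS polymorphism, GO flags and paralog copy number
carry no planted signal. This default regime yields cross-validation
AUC around 0.85–0.9, the regime of published per-species models
(0.77–0.86).

QTLs are contiguous blocks of the synthetic gene order (sizes uniform
in 20–700, spanning the curated panel's 22–706) with one planted
causal gene. Ortholog pairs link a configurable fraction of a donor
species' causal genes to target-species genes drawn from the causal
distribution (`fine_grained` calls); the remainder link to null genes,
so overlap 1 → full signal transfer, overlap 0 → none.

Deliberate non-goals of the generator: no linkage disequilibrium, no
population structure, no correlated features, no genuine sequence
evolution. Tests passing on these fixtures therefore demonstrate that
the machinery (feature extraction, transfer logic, ensemble, ranking
arithmetic) behaves correctly under the assumed marginal structure —
not that real genomes satisfy that structure, nor that real-data
performance will match the synthetic AUCs. The generator's round-trip
contract (raw files re-extracted equal the emitted feature table
bit-exactly) is what ties the file-level pipeline to the in-memory
path.

## Problem sizes used in the shipped analyses

The test suite and `scripts/acceptance.py` run the stochastic checks
at reduced sizes chosen as the package's own defaults for desk-scale
verification: synthetic genomes of 400–1000 genes with 10–20% causal,
forests of 25–50 trees, 3–50 CV repeats, 10⁴ simulated QTLs for the
background check, and 20–50 replicates for the planted-feature
recovery study. Larger settings only narrow the error bars; the
qualitative conclusions (chance-level nulls, transfer of ortholog
signal, recovery of the planted feature) are stable across seeds at
these sizes.

## Known limitations

- The exact historical list of binary polymorphism features varies by
  annotation pipeline; the shipped schema is a documented
  reconstruction and should be adapted to the local SnpEff/SIFT
  dialect.
- Vote-fraction scores are granular at 1/K; ties are common at small
  K and are handled by mean-rank averaging.
- The CV classification metrics (F1/precision/recall) depend strongly
  on the operating threshold and the negative ratio; AUC is the
  primary comparison metric.
- `percent_absence` treats accessions as exchangeable; population
  structure in real panels violates this.
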