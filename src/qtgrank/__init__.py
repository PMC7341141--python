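"""qtgrank: prioritize candidate causal genes in plant QTL intervals.

A QTL interval from linkage mapping typically holds tens to hundreds
of genes; cloning the causal one is the bottleneck.  qtgrank ranks the
interval's genes with an ensemble of random forests trained on known
causal genes — and, for species with few or none, on orthologs of
causal genes cloned in other species — over per-gene features built
from variant-effect annotations, polymorphism in flanking conserved
non-coding elements, gene presence/absence variation, GO-slim function
flags and paralog copy number.
"""

from importlib import resources

import pandas as pd

from .features import FeatureTable  # noqa: F401
from .model import ModelConfig  # noqa: F401
from .validation import QTLRegion, RankResult  # noqa: F401

__version__ = "0.1.0"


def load_sorghum_validation() -> pd.DataFrame:
    """The curated sorghum external-validation set: ten QTLs with cloned
    causal genes, each QTL's gene count and the percent rank the
    published ortholog-trained sorghum model assigned to its causal
    gene."""
    ref = resources.files("qtgrank").joinpath("data/sorghum_qtl_validation.tsv")
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_lineage_table() -> dict[str, str]:
    """Monocot/eudicot lineage assignment for the species panel."""
    ref = resources.files("qtgrank").joinpath("data/lineages.tsv")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return dict(zip(df["species"], df["lineage"]))
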