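"""Per-gene histone-mark presence calls and categorization.

A gene carries a mark iff at least one replicate-concordant ("real")
peak overlaps the first 1 kb of its gene body by >= 1 bp. Presence of
H2Aub1 and H3K27me3 partitions genes into four mutually exclusive
categories; H3K27me3-marked genes are further split by whether their
H3K27me3 depends on PRC1 (lost in a PRC1 mutant's first 1 kb) or not.
Classification is strictly binary — enrichment magnitude never enters.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .errors import UsageError
from .intervals import GeneModel, GenomicInterval, RegionKind, annotate_peaks_to_genes

__all__ = [
    "call_mark_presence",
    "categorize",
    "classify_prc1_dependency",
    "category_fraction",
    "CATEGORIES",
]

CATEGORIES = ("not_marked", "h2aub_only", "both", "k27_only")


def call_mark_presence(
    real_peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
) -> dict[str, bool]:
    """True iff >= 1 real peak overlaps the gene's first 1 kb."""
    mapping = annotate_peaks_to_genes(real_peaks, genes, RegionKind.first_1kb)
    return {g: bool(p) for g, p in mapping.items()}


def _category(h2aub: bool, k27: bool) -> str:
    if h2aub and k27:
        return "both"
    if h2aub:
        return "h2aub_only"
    if k27:
        return "k27_only"
    return "not_marked"


def categorize(
    h2aub: Mapping[str, bool], k27: Mapping[str, bool]
) -> pd.DataFrame:
    """Four-way gene table from the two presence maps.

    Returns a DataFrame indexed by gene_id with boolean ``h2aub``/``k27``
    columns and a ``category`` column over
    {not_marked, h2aub_only, both, k27_only}.
    """
    if set(h2aub) != set(k27):
        raise UsageError("h2aub and k27 presence maps cover different gene universes")
    genes = sorted(h2aub)
    df = pd.DataFrame(
        {
            "h2aub": [bool(h2aub[g]) for g in genes],
            "k27": [bool(k27[g]) for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    df["category"] = [_category(h, k) for h, k in zip(df["h2aub"], df["k27"])]
    return df


def classify_prc1_dependency(
    k27_presence: Mapping[str, bool],
    decreased_k27_peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
) -> dict[str, str]:
    """PRC1 dependency of H3K27me3 per gene.

    ``prc1_dep``: K27-marked and the first 1 kb overlaps a peak of
    decreased H3K27me3 in the PRC1 mutant; ``prc1_indep``: K27-marked
    otherwise; ``non_k27``: everything else (peaks at unmarked genes are
    ignored).
    """
    down = call_mark_presence(decreased_k27_peaks, genes)
    out = {}
    for gene in genes:
        g = gene.gene_id
        if not k27_presence.get(g, False):
            out[g] = "non_k27"
        elif down.get(g, False):
            out[g] = "prc1_dep"
        else:
            out[g] = "prc1_indep"
    return out


def category_fraction(
    set_a: set[str], table: pd.DataFrame, field: str
) -> float:
    """Fraction of genes in ``set_a`` for which ``table[field]`` is true."""
    if not set_a:
        raise UsageError("cannot compute a fraction over an empty gene set")
    missing = set_a - set(table.index)
    if missing:
        raise UsageError(f"genes not in table, e.g. {sorted(missing)[:3]}")
    return float(table.loc[sorted(set_a), field].astype(bool).mean())
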