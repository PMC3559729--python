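"""Gene annotation of CNVRs and functional-category enrichment.

Gene spans include introns (full transcript extent).  A CNVR is annotated
with every gene it overlaps by at least 1 bp; a CNVR in a gene desert is
annotated with the single nearest gene by edge distance (ties to the
smaller start) and marked "proximal".

Enrichment is a one-sided hypergeometric over-representation test of the
CNVR gene lists against a background gene set (the genes covered by the
array), with Benjamini-Hochberg correction across categories.  To stop a
single locus spanning a clustered gene family from driving a category,
each locus contributes at most one gene to a category's hit count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cnvr_segmentation import Cnvr
from .exceptions import ValidationError
from .io_formats import IntervalTrack


@dataclass
class EnrichmentResult:
    category: str
    hits_in_list: int          # loci contributing a gene of the category
    list_size: int             # number of loci tested
    hits_in_background: int    # background genes in the category
    background_size: int
    p_raw: float
    p_bh: float = float("nan")


def annotate_genes(cnvr: Cnvr, genes: IntervalTrack) -> tuple[list[str], str]:
    """Genes overlapping a CNVR, or the nearest gene when none overlap.

    Returns ``(gene_names, mode)`` with mode ``"overlap"`` or
    ``"proximal"``; the CNVR's ``genes`` list is updated in place.
    Partial overlap counts — complete coverage of the gene is not required.
    """
    hits = genes.overlapping(cnvr.chrom, cnvr.start_pos, cnvr.end_pos)
    if hits:
        names = [iv.name for iv in hits]
        cnvr.genes = names
        return names, "overlap"
    same_chrom = [iv for iv in genes.intervals if iv.chrom == cnvr.chrom]
    if not same_chrom:
        cnvr.genes = []
        return [], "proximal"
    def edge_distance(iv):
        if iv.end < cnvr.start_pos:
            return cnvr.start_pos - iv.end
        return iv.start - cnvr.end_pos
    nearest = min(same_chrom, key=lambda iv: (edge_distance(iv), iv.start))
    cnvr.genes = [nearest.name]
    return [nearest.name], "proximal"


def _categories_as_mapping(categories) -> dict[str, set[str]]:
    """Accept a DataFrame with (gene, category) columns or a mapping
    category -> iterable of genes."""
    if isinstance(categories, pd.DataFrame):
        out: dict[str, set[str]] = {}
        for gene, cat in zip(categories.iloc[:, 0], categories.iloc[:, 1]):
            out.setdefault(str(cat), set()).add(str(gene))
        return out
    return {str(k): set(v) for k, v in categories.items()}


def enrichment_test(locus_gene_lists: Sequence[Sequence[str]],
                    categories, background: set[str]
                    ) -> list[EnrichmentResult]:
    """Hypergeometric over-representation per category, one gene per locus.

    ``locus_gene_lists`` holds one gene list per associated locus;
    ``categories`` maps categories to gene sets (or is a two-column
    gene/category table); ``background`` is the universe of genes covered
    by the array and must contain every listed gene.
    """
    cats = _categories_as_mapping(categories)
    background = set(background)
    for genes in locus_gene_lists:
        for g in genes:
            if g not in background:
                raise ValidationError(
                    f"gene {g!r} in a locus list is absent from the background")
    m = len(background)
    n_loci = len(locus_gene_lists)
    results = []
    for cat in sorted(cats):
        members = cats[cat] & background
        # one-per-locus rule: a locus is a hit if any of its genes (hence
        # its first in genomic order) belongs to the category
        hits = sum(1 for genes in locus_gene_lists
                   if any(g in members for g in genes))
        p_raw = float(stats.hypergeom.sf(hits - 1, m, len(members), n_loci))
        results.append(EnrichmentResult(
            category=cat, hits_in_list=hits, list_size=n_loci,
            hits_in_background=len(members), background_size=m,
            p_raw=min(1.0, p_raw)))
    p_adj = benjamini_hochberg([r.p_raw for r in results])
    for r, q in zip(results, p_adj):
        r.p_bh = q
    return results


def benjamini_hochberg(p_list: Sequence[float]) -> list[float]:
    """Step-up BH adjusted p-values, order preserved, capped at 1."""
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


def write_enrichment_table(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("category\thits_in_list\tlist_size\thits_in_background\t"
                 "background_size\tp_raw\tp_bh\n")
        for r in results:
            fh.write(f"{r.category}\t{r.hits_in_list}\t{r.list_size}\t"
                     f"{r.hits_in_background}\t{r.background_size}\t"
                     f"{r.p_raw!r}\t{r.p_bh!r}\n")
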