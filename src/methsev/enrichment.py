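"""Over-representation analysis of significant genes and sites.

Fisher's exact test (one-sided, over-representation) of significant genes
against user-supplied annotation categories, and of significant CpG sites
against fixed genomic windows.  The published linkage regions and 500 kb
GWAS-SNP windows relevant to Paget's disease ship as a packaged fixture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .site_ewas import adjust_fdr

__all__ = [
    "GenomicWindow",
    "LINKAGE_WINDOWS",
    "GWAS_SNP_WINDOWS",
    "map_sites_to_genes",
    "fisher_enrichment",
    "window_enrichment",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicWindow:
    """1-based inclusive genomic interval (GRCh37)."""

    label: str
    chr: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")


#: Linkage regions previously implicated in familial Paget's disease (GRCh37).
LINKAGE_WINDOWS = (
    GenomicWindow("2q36", "2", 221_500_001, 231_000_000),
    GenomicWindow("5q31", "5", 130_600_001, 144_500_000),
    GenomicWindow("5q35", "5", 168_500_001, 180_915_260),
    GenomicWindow("10p13", "10", 12_200_001, 17_300_000),
)

#: 500 kb windows around genome-wide-significant PDB susceptibility SNPs.
GWAS_SNP_WINDOWS = (
    GenomicWindow("rs10494112", "1", 110_102_477, 110_602_477),
    GenomicWindow("rs4294134", "7", 135_043_128, 135_543_128),
    GenomicWindow("rs2458413", "8", 105_109_432, 105_609_432),
    GenomicWindow("rs1561570", "10", 12_905_726, 13_405_726),
    GenomicWindow("rs10498635", "14", 92_853_309, 93_353_309),
    GenomicWindow("rs5742915", "15", 74_086_633, 74_586_633),
    GenomicWindow("rs3018362", "18", 59_832_033, 60_332_033),
)


def map_sites_to_genes(
    site_ids, manifest: pd.DataFrame
) -> tuple[set[str], int]:
    """Deduplicated gene labels of the given sites.

    Sites without a gene annotation are excluded; their count is returned
    alongside the gene set.
    """
    ann = manifest.set_index("probe_id")["gene"]
    genes: set[str] = set()
    unannotated = 0
    for sid in site_ids:
        g = ann.get(sid, "")
        if isinstance(g, str) and g:
            genes.add(g)
        else:
            unannotated += 1
    return genes, unannotated


def _fisher_row(a: int, b: int, c: int, d: int, two_sided: bool) -> tuple[float, float]:
    """One table's p and Haldane-corrected odds ratio."""
    alternative = "two-sided" if two_sided else "greater"
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if min(a, b, c, d) == 0:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = a * d / (b * c)
    return float(p), float(orr)


def fisher_enrichment(
    significant: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    two_sided: bool = False,
) -> pd.DataFrame:
    """Category over-representation of significant genes.

    2x2 table per category: (significant in category, significant outside,
    non-significant in category, non-significant outside) over the gene
    universe.  Significant genes outside the universe are dropped with a
    warning; empty categories (after intersecting the universe) are dropped.
    BH q-values across the tested categories.
    """
    if not universe:
        raise ValueError("empty gene universe")
    stray = significant - universe
    if stray:
        log.warning("%d significant genes not in universe; dropped", len(stray))
    sig = significant & universe
    rows = []
    for cat, members in sorted(gene_sets.items()):
        members = members & universe
        if not members:
            continue
        a = len(sig & members)
        b = len(sig - members)
        c = len(members - sig)
        d = len(universe) - a - b - c
        p, orr = _fisher_row(a, b, c, d, two_sided)
        rows.append(
            {"category": cat, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": orr, "p": p}
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = adjust_fdr(out["p"])
    return out


def window_enrichment(
    significant_sites,
    all_sites,
    windows,
    manifest: pd.DataFrame,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Over-representation of significant sites inside fixed genomic windows.

    Membership is 1-based inclusive on the window's chromosome.  The table
    contrasts significant vs non-significant sites, inside vs outside each
    window; windows holding no site give the degenerate table with p = 1.
    """
    pos = manifest.set_index("probe_id")[["chr", "pos"]]
    all_ids = [s for s in all_sites if s in pos.index]
    sig_ids = set(significant_sites) & set(all_ids)
    chrs = pos.loc[all_ids, "chr"].astype(str).to_numpy()
    positions = pos.loc[all_ids, "pos"].to_numpy()
    is_sig = np.array([s in sig_ids for s in all_ids])

    rows = []
    for w in windows:
        inside = (chrs == str(w.chr)) & (positions >= w.start) & (positions <= w.end)
        a = int(np.sum(inside & is_sig))
        b = int(np.sum(~inside & is_sig))
        c = int(np.sum(inside & ~is_sig))
        d = int(np.sum(~inside & ~is_sig))
        p, orr = _fisher_row(a, b, c, d, two_sided)
        rows.append(
            {"window": w.label, "chr": w.chr, "start": w.start, "end": w.end,
             "a": a, "b": b, "c": c, "d": d, "odds_ratio": orr, "p": p}
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = adjust_fdr(out["p"])
    return out
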