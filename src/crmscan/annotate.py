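"""Peak ranking, peak-to-gene assignment and gene-set term enrichment.

Peaks are ranked by the area under their signal contour. Each peak is
assigned from its summit (the point of maximal enrichment): a summit inside
an intron goes to the nested gene whose transcription start site is nearest
(key mesodermal enhancers often sit inside their target gene), otherwise the
peak goes to the gene with the nearest outer exon boundary — 5' or 3', in
either direction, because enhancers are also found downstream of their
targets. Summit positions are categorized with the precedence
exon > 5'UTR > promoter > intron > intergenic; the promoter is the
strand-aware 2 kb window upstream of the TSS. Term enrichment is a
hypergeometric upper tail with Benjamini-Hochberg FDR across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .seqio import GenomicInterval

logger = logging.getLogger(__name__)

CATEGORIES = ("exon", "5utr", "promoter", "intron", "intergenic")


@dataclass
class PeakCall:
    """A binding peak with its summit and the area under its signal contour."""

    interval: GenomicInterval
    summit: int
    area: float
    id: str

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(f"summit {self.summit} outside peak {self.id}")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


@dataclass
class GeneModel:
    """A gene as ordered non-overlapping exons with a strand-aware TSS.

    `cds_start` (genomic coordinate of the translation start) is optional;
    without it the 5'UTR category collapses into exon.
    """

    id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_start: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("gene strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in gene {self.id}")

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """5' boundary of the gene (first exon start on +, last exon end on -)."""
        return self.start if self.strand == "+" else self.end

    def contains_in_intron(self, pos: int) -> bool:
        if not (self.start <= pos < self.end):
            return False
        return not any(e.start <= pos < e.end for e in self.exons)

    def in_exon(self, pos: int) -> bool:
        return any(e.start <= pos < e.end for e in self.exons)

    def in_5utr(self, pos: int) -> bool:
        """Exonic and 5' of the CDS start (requires an annotated CDS start)."""
        if self.cds_start is None or not self.in_exon(pos):
            return False
        return pos < self.cds_start if self.strand == "+" else pos >= self.cds_start

    def in_promoter(self, pos: int, span: int = 2000) -> bool:
        if self.strand == "+":
            return self.tss - span <= pos < self.tss
        return self.tss <= pos < self.tss + span


@dataclass
class PeakAnnotation:
    peak_id: str
    gene_id: Optional[str]
    category: str
    distance: int  # signed summit - boundary distance (0 when inside the gene)


def peak_area(signal: Sequence[float]) -> float:
    """Area under a per-position signal contour (trapezoidal rule)."""
    return float(np.trapezoid(np.asarray(signal, dtype=float)))


def rank_peaks(peaks: Sequence[PeakCall]) -> list[PeakCall]:
    """Descending by area; ties broken by summit coordinate, then id."""
    return sorted(peaks, key=lambda p: (-p.area, p.summit, p.id))


def assign_gene(peak: PeakCall, genes: Sequence[GeneModel],
                promoter_span: int = 2000) -> PeakAnnotation:
    """Assign a peak to a gene from its summit.

    Intronic summits go to the containing gene with the nearest TSS; all
    other summits go to the gene with the nearest outer exon boundary in
    either direction. Equidistant boundaries tie-break toward a TSS
    boundary, then the smaller gene id.
    """
    summit = peak.summit
    chrom_genes = [g for g in genes if g.chrom == peak.interval.chrom]
    category = categorize_peak(peak, genes, promoter_span=promoter_span)
    if not chrom_genes:
        logger.warning("no genes on %s; peak %s left unassigned", peak.interval.chrom, peak.id)
        return PeakAnnotation(peak.id, None, category, 0)

    nested = [g for g in chrom_genes if g.contains_in_intron(summit)]
    if nested:
        gene = min(nested, key=lambda g: (abs(summit - g.tss), g.id))
        return PeakAnnotation(peak.id, gene.id, category, 0)

    # nearest outer exon boundary (gene 5'/3' ends), searched in both directions
    best = None
    for g in chrom_genes:
        for boundary in (g.start, g.end):
            dist = abs(summit - boundary)
            is_tss = boundary == g.tss
            key = (dist, 0 if is_tss else 1, g.id)
            if best is None or key < best[0]:
                best = (key, g, summit - boundary)
    _, gene, signed = best
    distance = 0 if gene.start <= summit < gene.end else signed
    return PeakAnnotation(peak.id, gene.id, category, distance)


def categorize_peak(peak: PeakCall, genes: Sequence[GeneModel],
                    promoter_span: int = 2000) -> str:
    """Genomic category of the summit with precedence
    exon > 5'UTR > promoter > intron > intergenic.

    "exon" means an exonic position not in an annotated 5'UTR; genes lacking
    a CDS start contribute plain exon calls only.
    """
    summit = peak.summit
    chrom_genes = [g for g in genes if g.chrom == peak.interval.chrom]
    in_utr = any(g.in_5utr(summit) for g in chrom_genes)
    in_exon = any(g.in_exon(summit) and not g.in_5utr(summit) for g in chrom_genes)
    if in_exon:
        return "exon"
    if in_utr:
        return "5utr"
    if any(g.in_promoter(summit, promoter_span) for g in chrom_genes):
        return "promoter"
    if any(g.contains_in_intron(summit) for g in chrom_genes):
        return "intron"
    return "intergenic"


@dataclass
class OverlapSummary:
    a_overlapping: int
    b_overlapping: int
    a_only: int
    b_only: int


def overlap_peak_sets(a: Sequence[PeakCall], b: Sequence[PeakCall],
                      min_overlap: int = 1) -> OverlapSummary:
    """Count peaks in each set overlapping >= 1 peak of the other.

    Peak sets do not map one-to-one (one set may call two small peaks where
    the other calls one large one), so each side is counted independently:
    an a-peak overlapping two b-peaks still counts once on the a side.
    """
    def hits(xs, ys):
        return sum(
            1 for x in xs
            if any(x.interval.overlaps(y.interval) >= min_overlap for y in ys)
        )

    a_over = hits(a, b)
    b_over = hits(b, a)
    return OverlapSummary(a_over, b_over, len(a) - a_over, len(b) - b_over)


def term_enrichment(
    gene_set: set[str],
    universe: set[str],
    annotations: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of each term in `gene_set`.

    P(X >= k) for k annotated genes in the set, with term sizes restricted
    to the universe; Benjamini-Hochberg FDR across terms. Columns: term,
    n_annotated, n_overlap, pvalue, fdr.
    """
    extra = gene_set - universe
    if extra:
        raise ValueError(f"genes outside the universe: {sorted(extra)[:5]}")
    M, N = len(universe), len(gene_set)
    rows = []
    for term, members in annotations.items():
        members = members & universe
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), N))
        rows.append({"term": term, "n_annotated": len(members), "n_overlap": k, "pvalue": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        _, fdr, _, _ = multipletests(df["pvalue"], method="fdr_bh")
        df["fdr"] = fdr
        df = df.sort_values("pvalue", kind="stable").reset_index(drop=True)
    return df
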