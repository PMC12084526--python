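"""SNP-to-gene mapping: turn GWAS summary statistics into implicated genes.

A gene is implicated for a disorder when a genome-wide-significant (GWS)
SNP lies within the gene body extended by a flank (proximity), when a GWS
SNP is a cis-eQTL for the gene, or when a GWS SNP sits in one anchor of a
chromatin loop whose other anchor overlaps the gene's promoter window.

Linkage-disequilibrium pruning is approximated, reference-free, by greedy
distance clumping in ascending-p order: a GWS SNP within ``clump_window``
of an already-selected lead on the same chromosome is absorbed. Binary
gene implication uses all GWS SNPs; the per-gene annotation aggregates are
computed over clumped leads only, so one LD block cannot contribute many
correlated SNPs to a mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from intervaltree import IntervalTree

from .io import (
    REGULOME_CATEGORIES,
    EqtlRecord,
    GeneModel,
    LoopRecord,
    SummaryStatRecord,
)

#: Conventional genome-wide significance threshold.
GWS_ALPHA = 5e-8
#: Default greedy-clumping window, basepairs.
CLUMP_WINDOW = 250_000
#: Default gene-body flank for proximity matching, basepairs (±10 kbp).
PROXIMITY_FLANK = 10_000
#: Default promoter half-window around the gene start, basepairs.
PROMOTER_FLANK = 2_000

#: regulomeDB categories recoded to a numeric scale where higher = stronger
#: regulatory evidence: "1a" -> 7 descending in half-steps to "7" -> 0.
#: Any strictly monotone recoding would serve; this one is the default.
REGULOME_NUMERIC = {cat: 7.0 - 0.5 * i for i, cat in enumerate(REGULOME_CATEGORIES)}

AGG_FIELDS = (
    "max_abs_beta", "mean_abs_beta", "max_z", "mean_z",
    "max_cadd", "mean_cadd", "regulome_best", "pli", "any_exonic",
)


@dataclass
class LeadSnp:
    """An independent association signal after distance clumping."""

    record: SummaryStatRecord
    locus_rank: int  # 1 = smallest p


@dataclass
class GeneHit:
    """A gene implicated by the GWAS, with its supporting SNPs.

    ``sources`` is a subset of {"proximity", "eqtl", "chromatin"};
    ``snp_records`` maps variant id to the supporting summary-statistic
    record, over which the annotation aggregates are computed.
    """

    gene_id: str
    sources: set[str]
    snp_records: dict[str, SummaryStatRecord]
    pli: Optional[float] = None

    @property
    def snp_ids(self) -> frozenset[str]:
        return frozenset(self.snp_records)

    @property
    def lead_variant(self) -> str:
        """Supporting variant with the smallest p (ties: lexicographic id)."""
        return min(self.snp_records.values(), key=lambda r: (r.p, r.variant_id)).variant_id

    @property
    def agg(self) -> dict[str, float]:
        """Per-gene annotation aggregates over the supporting SNPs.

        Means are unweighted; z and beta are aggregated in absolute value;
        CADD and regulomeDB aggregate over the SNPs that carry them (0.0
        when none do); ``pli`` is the gene-level score (0.0 when missing);
        ``any_exonic`` is 1.0 iff some supporting SNP is exonic.
        """
        recs = list(self.snp_records.values())
        betas = [abs(r.beta) for r in recs]
        zs = [abs(r.z) for r in recs]
        cadds = [r.cadd for r in recs if r.cadd is not None]
        regs = [REGULOME_NUMERIC[r.regulome] for r in recs if r.regulome is not None]
        return {
            "max_abs_beta": max(betas),
            "mean_abs_beta": sum(betas) / len(betas),
            "max_z": max(zs),
            "mean_z": sum(zs) / len(zs),
            "max_cadd": max(cadds) if cadds else 0.0,
            "mean_cadd": sum(cadds) / len(cadds) if cadds else 0.0,
            "regulome_best": max(regs) if regs else 0.0,
            "pli": self.pli if self.pli is not None else 0.0,
            "any_exonic": 1.0 if any(r.exonic for r in recs) else 0.0,
        }


def filter_gws(records: Iterable[SummaryStatRecord],
               gws_alpha: float = GWS_ALPHA) -> list[SummaryStatRecord]:
    """Keep records with p <= ``gws_alpha`` (inclusive), order preserved."""
    if not (0.0 < gws_alpha < 1.0):
        raise ValueError(f"gws_alpha must be in (0, 1), got {gws_alpha}")
    return [r for r in records if r.p <= gws_alpha]


def clump_leads(gws: Sequence[SummaryStatRecord],
                clump_window: int = CLUMP_WINDOW) -> list[LeadSnp]:
    """Greedy distance clumping of GWS SNPs into independent leads.

    SNPs are visited in ascending p (ties broken by (chrom, pos)); a SNP
    closer than ``clump_window`` to an already-selected lead on the same
    chromosome is absorbed. Deterministic given the tie rule.
    """
    leads: list[LeadSnp] = []
    chosen: dict[str, list[int]] = {}
    for rec in sorted(gws, key=lambda r: (r.p, r.chrom, r.pos)):
        positions = chosen.setdefault(rec.chrom, [])
        if any(abs(rec.pos0 - q) < clump_window for q in positions):
            continue
        positions.append(rec.pos0)
        leads.append(LeadSnp(record=rec, locus_rank=len(leads) + 1))
    return leads


def _as_records(snps: Iterable[Union[SummaryStatRecord, LeadSnp]]) -> list[SummaryStatRecord]:
    return [s.record if isinstance(s, LeadSnp) else s for s in snps]


def map_proximity(snps: Iterable[Union[SummaryStatRecord, LeadSnp]],
                  genes: Sequence[GeneModel],
                  flank: int = PROXIMITY_FLANK) -> list[GeneHit]:
    """Proximity mapping: gene hit iff a SNP lies in [start-flank, end+flank).

    Positions are 0-based internally; the lower boundary is inclusive, the
    upper exclusive (BED half-open convention carried through the flank).
    One SNP may hit several overlapping genes.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start - flank, g.end + flank, g)
    hits: dict[str, GeneHit] = {}
    for rec in _as_records(snps):
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        for iv in tree[rec.pos0]:
            gene: GeneModel = iv.data
            hit = hits.get(gene.gene_id)
            if hit is None:
                hit = hits[gene.gene_id] = GeneHit(
                    gene_id=gene.gene_id, sources={"proximity"},
                    snp_records={}, pli=gene.pli)
            hit.snp_records[rec.variant_id] = rec
    return [hits[g] for g in sorted(hits)]


def map_eqtl(gws: Iterable[SummaryStatRecord],
             eqtls: Iterable[EqtlRecord],
             genes: Optional[Sequence[GeneModel]] = None) -> list[GeneHit]:
    """eQTL mapping: gene hit iff a GWS SNP is a cis-eQTL for it."""
    by_variant: dict[str, SummaryStatRecord] = {r.variant_id: r for r in gws}
    pli_of = {g.gene_id: g.pli for g in genes} if genes is not None else {}
    hits: dict[str, GeneHit] = {}
    for e in eqtls:
        rec = by_variant.get(e.variant_id)
        if rec is None:
            continue
        hit = hits.get(e.gene_id)
        if hit is None:
            hit = hits[e.gene_id] = GeneHit(
                gene_id=e.gene_id, sources={"eqtl"},
                snp_records={}, pli=pli_of.get(e.gene_id))
        hit.snp_records[rec.variant_id] = rec
    return [hits[g] for g in sorted(hits)]


def map_chromatin(gws: Sequence[SummaryStatRecord],
                  loops: Iterable[LoopRecord],
                  genes: Sequence[GeneModel],
                  promoter_flank: int = PROMOTER_FLANK) -> list[GeneHit]:
    """Chromatin-loop mapping: SNP in one anchor, gene promoter in the other.

    The promoter window is [start - promoter_flank, start + promoter_flank)
    on the stored orientation (gene models carry no strand). A SNP and
    promoter in the same anchor only do not constitute a contact.
    """
    promoters: dict[str, IntervalTree] = {}
    for g in genes:
        promoters.setdefault(g.chrom, IntervalTree()).addi(
            g.start - promoter_flank, g.start + promoter_flank, g)
    hits: dict[str, GeneHit] = {}

    def _contact(rec: SummaryStatRecord, chrom_snp, start_snp, end_snp,
                 chrom_gene, start_gene, end_gene) -> None:
        if rec.chrom != chrom_snp or not (start_snp <= rec.pos0 < end_snp):
            return
        tree = promoters.get(chrom_gene)
        if tree is None:
            return
        for iv in tree.overlap(start_gene, end_gene):
            gene: GeneModel = iv.data
            hit = hits.get(gene.gene_id)
            if hit is None:
                hit = hits[gene.gene_id] = GeneHit(
                    gene_id=gene.gene_id, sources={"chromatin"},
                    snp_records={}, pli=gene.pli)
            hit.snp_records[rec.variant_id] = rec

    for loop in loops:
        for rec in gws:
            _contact(rec, loop.chromA, loop.startA, loop.endA,
                     loop.chromB, loop.startB, loop.endB)
            _contact(rec, loop.chromB, loop.startB, loop.endB,
                     loop.chromA, loop.startA, loop.endA)
    return [hits[g] for g in sorted(hits)]


def merge_hits(*collections: Iterable[GeneHit]) -> list[GeneHit]:
    """Union hit collections by gene: sources and SNP sets union, aggregates
    recomputed over the unioned SNPs. Commutative, associative, idempotent."""
    merged: dict[str, GeneHit] = {}
    for coll in collections:
        for hit in coll:
            cur = merged.get(hit.gene_id)
            if cur is None:
                merged[hit.gene_id] = GeneHit(
                    gene_id=hit.gene_id, sources=set(hit.sources),
                    snp_records=dict(hit.snp_records), pli=hit.pli)
            else:
                cur.sources |= hit.sources
                cur.snp_records.update(hit.snp_records)
                if cur.pli is None:
                    cur.pli = hit.pli
    return [merged[g] for g in sorted(merged)]


def implicate_genes(records: Iterable[SummaryStatRecord],
                    genes: Sequence[GeneModel],
                    gws_alpha: float = GWS_ALPHA,
                    flank: int = PROXIMITY_FLANK,
                    clump_window: int = CLUMP_WINDOW,
                    eqtls: Optional[Iterable[EqtlRecord]] = None,
                    loops: Optional[Iterable[LoopRecord]] = None,
                    promoter_flank: int = PROMOTER_FLANK,
                    sources: Sequence[str] = ("proximity",),
                    aggregate_on_leads: bool = True) -> list[GeneHit]:
    """Full mapping step: GWS filter, clumping, then the enabled sources.

    Proximity membership is decided with all GWS SNPs; when
    ``aggregate_on_leads`` is true (default) the per-gene annotation
    aggregates are recomputed over clumped leads where a gene is hit by at
    least one lead, falling back to all hitting SNPs otherwise.
    """
    unknown = set(sources) - {"proximity", "eqtl", "chromatin"}
    if unknown:
        raise ValueError(f"unknown mapping sources: {sorted(unknown)}")
    gws = filter_gws(records, gws_alpha)
    pieces: list[list[GeneHit]] = []
    if "proximity" in sources:
        prox = map_proximity(gws, genes, flank)
        if aggregate_on_leads:
            leads = clump_leads(gws, clump_window)
            lead_hits = {h.gene_id: h for h in map_proximity(leads, genes, flank)}
            for hit in prox:
                lead_hit = lead_hits.get(hit.gene_id)
                if lead_hit is not None:
                    hit.snp_records = dict(lead_hit.snp_records)
        pieces.append(prox)
    if "eqtl" in sources and eqtls is not None:
        pieces.append(map_eqtl(gws, eqtls, genes))
    if "chromatin" in sources and loops is not None:
        pieces.append(map_chromatin(gws, loops, genes, promoter_flank))
    return merge_hits(*pieces)


def write_mapping_report(hits: Sequence[GeneHit], path, comment: Optional[str] = None) -> None:
    """Mapping report TSV: gene, sources, SNP count, lead SNP, aggregates."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("gene_id\tsources\tn_snps\tlead_snp\t" + "\t".join(AGG_FIELDS) + "\n")
        for h in hits:
            agg = h.agg
            fh.write(
                f"{h.gene_id}\t{','.join(sorted(h.sources))}\t{len(h.snp_records)}\t"
                f"{h.lead_variant}\t" + "\t".join(repr(agg[f]) for f in AGG_FIELDS) + "\n")
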