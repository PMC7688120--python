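"""Strand-aware gene-proximity annotation of SNPs and cluster/DE-gene overlap.

A SNP is annotated against every gene whose span lies within a window
(default 50 kb) of the SNP position.  Intergenic relations are ``upstream`` /
``downstream`` relative to the gene's transcription direction, with the
distance counted such that a SNP immediately adjacent to the gene boundary is
1 bp away.  Intragenic SNPs get ``exon k`` / ``intron k`` with k 1-based in
transcription order and distance 0.

Conventions (documented, since locus tables in the literature rarely state
theirs): the window is measured to the nearest gene-span boundary, not to the
TSS; a SNP may annotate to several genes — no best-gene selection is done.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .model import (
    ClassifiedSnp,
    DeGeneRecord,
    GeneModel,
    SnpCluster,
    SnpGeneAnnotation,
    SnpPanel,
    SnpRecord,
    ValidationError,
)

DEFAULT_WINDOW = 50_000


def _intragenic_relation(gene: GeneModel, p: int) -> str:
    """Relation of 0-based position ``p`` (inside the gene span) to its exons.

    Positions inside the span but outside the exon hull (possible when the
    annotated span exceeds the exons) are assigned to the nearest terminal
    exon.
    """
    exons = gene.exons  # transcription order
    for k, (s, e) in enumerate(exons, start=1):
        if s <= p < e:
            return f"exon {k}"
    # introns: gap between transcription-consecutive exons k and k+1
    for k in range(1, len(exons)):
        a, b = exons[k - 1], exons[k]
        lo, hi = (a[1], b[0]) if a[0] < b[0] else (b[1], a[0])
        if lo <= p < hi:
            return f"intron {k}"
    hull_start = min(s for s, _ in exons)
    if p < hull_start:
        return "exon 1" if gene.strand == "+" else f"exon {len(exons)}"
    return f"exon {len(exons)}" if gene.strand == "+" else "exon 1"


def annotate_snp(
    snp: SnpRecord,
    genes: Iterable[GeneModel],
    window: int = DEFAULT_WINDOW,
    allele_label: str | None = None,
) -> list[SnpGeneAnnotation]:
    """Annotate one SNP against all genes within ``window`` bp on its chromosome.

    Genes on other chromosomes are skipped.  Results are sorted by distance
    (then gene id for ties).  ``allele_label`` is carried through to the
    output rows (e.g. ``"C/A"``); it defaults to ``focal/other``.
    """
    if window < 0:
        raise ValidationError(f"window must be >= 0, got {window}")
    label = allele_label if allele_label is not None else f"{snp.focal_allele}/{snp.other_allele}"
    p = snp.pos - 1  # 0-based
    out: list[SnpGeneAnnotation] = []
    for gene in genes:
        if gene.chrom != snp.chrom:
            continue
        if gene.start <= p < gene.end:
            relation, dist = _intragenic_relation(gene, p), 0
        else:
            left = p < gene.start
            dist = gene.start - p if left else p - (gene.end - 1)
            if dist > window:
                continue
            if gene.strand == "+":
                relation = "upstream" if left else "downstream"
            else:
                relation = "downstream" if left else "upstream"
        out.append(
            SnpGeneAnnotation(
                snp_id=snp.snp_id,
                gene_id=gene.gene_id,
                relation=relation,
                distance_bp=dist,
                chrom=snp.chrom,
                pos=snp.pos,
                gene_strand=gene.strand,
                allele_label=label,
            )
        )
    out.sort(key=lambda a: (a.distance_bp, a.gene_id))
    return out


def _oriented_label(c: ClassifiedSnp) -> str:
    """Allele label oriented as selected-line allele / control-line allele."""
    snp = c.snp
    if not c.is_all_or_none:
        return f"{snp.focal_allele}/{snp.other_allele}"
    fixed = c.fixed_base
    other = snp.other_allele if fixed == snp.focal_allele else snp.focal_allele
    if c.fixed_linetype == "selected":
        return f"{fixed}/{other}"
    return f"{other}/{fixed}"


def annotate_panel(
    panel: SnpPanel,
    genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
    classified: Sequence[ClassifiedSnp] | None = None,
) -> list[SnpGeneAnnotation]:
    """Annotate every panel SNP; stable order (SNP position, then distance).

    When ``classified`` results are supplied, allele labels are oriented as
    selected-allele/control-allele for all-or-none SNPs (the ``HR / Cont``
    style of a locus table); otherwise labels are focal/other.
    """
    labels: dict[str, str] = {}
    if classified is not None:
        labels = {c.snp.snp_id: _oriented_label(c) for c in classified}
    out: list[SnpGeneAnnotation] = []
    for rec in panel.records:
        out.extend(annotate_snp(rec, genes, window=window, allele_label=labels.get(rec.snp_id)))
    return out


def overlap_de_with_clusters(
    clusters: Sequence[SnpCluster],
    de_genes: Sequence[DeGeneRecord],
    genes: Sequence[GeneModel],
) -> tuple[pd.DataFrame, dict]:
    """Count DE genes (q < 0.05) whose span intersects each padded cluster.

    Returns a per-cluster table with counts split by receptor family plus a
    totals dict (genome-wide DE count, DE-in-cluster count, and any DE gene
    ids missing from the gene models, which are warned about and flagged).
    """
    by_id = {g.gene_id: g for g in genes}
    trees: dict[str, IntervalTree] = {}
    for c in clusters:
        # cluster [start, end] 1-based inclusive -> half-open [start, end+1)
        trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end + 1, c.cluster_id)

    de_set = [d for d in de_genes if d.is_de]
    missing = sorted(d.gene_id for d in de_set if d.gene_id not in by_id)
    if missing:
        warnings.warn(f"DE gene ids absent from gene models: {missing}", stacklevel=2)

    hits: dict[str, list[DeGeneRecord]] = {c.cluster_id: [] for c in clusters}
    n_in_any = 0
    for d in de_set:
        gene = by_id.get(d.gene_id)
        if gene is None:
            continue
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        # gene [start, end) 0-based -> 1-based half-open [start+1, end+1)
        found = tree.overlap(gene.start + 1, gene.end + 1)
        if found:
            n_in_any += 1
        for iv in found:
            hits[iv.data].append(d)

    rows = []
    for c in clusters:
        in_c = sorted(hits[c.cluster_id], key=lambda d: d.gene_id)
        row = {
            "cluster_id": c.cluster_id,
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "n_de": len(in_c),
            "de_ids": ",".join(d.gene_id for d in in_c),
        }
        for fam in ("Vmn1r", "Vmn2r", "Fpr", "other"):
            row[f"n_de_{fam}"] = sum(d.family == fam for d in in_c)
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "chrom", "start", "end", "n_de",
            "n_de_Vmn1r", "n_de_Vmn2r", "n_de_Fpr", "n_de_other", "de_ids",
        ],
    )
    totals = {
        "n_de_total": len(de_set),
        "n_de_in_clusters": n_in_any,
        "missing_gene_ids": missing,
    }
    return df, totals
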