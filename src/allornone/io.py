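"""Readers and writers for panels, gene models, DE tables and pipeline outputs.

Formats
-------
* allele-frequency panel: TSV with ``snp_id  chrom  pos  focal_allele
  other_allele`` then one frequency column per line id;
* line design: TSV ``line_id  linetype`` with ``#ne=`` / ``#generations=``
  header comments;
* gene models: GFF3 (1-based inclusive; canonical, carries the receptor
  family as an attribute) or BED12 (0-based half-open; family encoded in the
  itemRgb column via a fixed family-color map);
* clusters: BED6 export (name = cluster id, score = member count) and a
  full-fidelity TSV that also stores the member list;
* DE tables, classified SNPs, annotation tables: TSV.

All tables are written sorted with a fixed column order, and floats with
shortest round-trip representation, so outputs are byte-stable and every
``read(write(x))`` returns ``x``.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import gffutils
import pandas as pd

from .model import (
    ClassifiedSnp,
    DeGeneRecord,
    DesignMismatchError,
    FormatError,
    GeneModel,
    LineDesign,
    SnpCluster,
    SnpGeneAnnotation,
    SnpPanel,
    SnpRecord,
    ValidationError,
)

PANEL_FIXED_COLUMNS = ["snp_id", "chrom", "pos", "focal_allele", "other_allele"]

FAMILY_RGB = {"Vmn1r": "255,0,0", "Vmn2r": "0,0,255", "Fpr": "0,128,0", "other": "0,0,0"}
_RGB_FAMILY = {v: k for k, v in FAMILY_RGB.items()}


def _write_lines(path: str | os.PathLike, lines: Iterable[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# line design

def read_design(path: str | os.PathLike) -> LineDesign:
    """Read a line-design TSV (line_id, linetype; ``#ne=``/``#generations=``
    comments override the defaults 35 and 88)."""
    ne, generations = 35, 88
    lines: list[tuple[str, str]] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw:
                continue
            if raw.startswith("#"):
                body = raw[1:].strip()
                if body.startswith("ne="):
                    ne = int(body[3:])
                elif body.startswith("generations="):
                    generations = int(body[len("generations="):])
                continue
            parts = raw.split("\t")
            if not header_seen:
                if parts[:2] != ["line_id", "linetype"]:
                    raise FormatError(
                        f"{path}: design header must be 'line_id\\tlinetype', got {parts[:2]}"
                    )
                header_seen = True
                continue
            if len(parts) < 2:
                raise FormatError(f"{path}: malformed design row {raw!r}")
            lines.append((parts[0], parts[1]))
    if not header_seen:
        raise FormatError(f"{path}: empty design file")
    return LineDesign(lines=lines, ne=ne, generations=generations)


def write_design(design: LineDesign, path: str | os.PathLike) -> None:
    out = [f"#ne={design.ne}", f"#generations={design.generations}", "line_id\tlinetype"]
    out += [f"{lid}\t{lt}" for lid, lt in design.lines]
    _write_lines(path, out)


# ---------------------------------------------------------------------------
# SNP panel

def read_snp_panel(path: str | os.PathLike, design_path: str | os.PathLike) -> SnpPanel:
    """Read a frequency panel TSV against its companion design file.

    Raises :class:`FormatError` for a missing fixed or design column,
    :class:`ValidationError` (naming the SNP) for out-of-range values, and
    :class:`DesignMismatchError` for frequency columns not in the design.
    """
    design = read_design(design_path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in PANEL_FIXED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    freq_cols = [c for c in df.columns if c not in PANEL_FIXED_COLUMNS]
    unknown = [c for c in freq_cols if c not in design.line_ids]
    if unknown:
        raise DesignMismatchError(f"{path}: frequency column(s) {unknown} not in design")
    missing = [lid for lid in design.line_ids if lid not in freq_cols]
    if missing:
        raise FormatError(f"{path}: missing frequency column(s) {missing}")

    records: list[SnpRecord] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        snp_id = d["snp_id"]
        try:
            pos = int(d["pos"])
        except ValueError as exc:
            raise ValidationError(f"{snp_id}: non-integer position {d['pos']!r}") from exc
        freqs: dict[str, float] = {}
        for lid in design.line_ids:
            try:
                freqs[lid] = float(d[lid])
            except ValueError as exc:
                raise ValidationError(
                    f"{snp_id}: non-numeric frequency {d[lid]!r} for line {lid}"
                ) from exc
        records.append(
            SnpRecord(
                snp_id=snp_id,
                chrom=d["chrom"],
                pos=pos,
                focal_allele=d["focal_allele"],
                other_allele=d["other_allele"],
                freqs=freqs,
            )
        )
    return SnpPanel(design=design, records=records)


def write_snp_panel(
    panel: SnpPanel, path: str | os.PathLike, design_path: str | os.PathLike | None = None
) -> None:
    line_ids = panel.design.line_ids
    out = ["\t".join(PANEL_FIXED_COLUMNS + line_ids)]
    for r in panel.records:
        fields = [r.snp_id, r.chrom, str(r.pos), r.focal_allele, r.other_allele]
        fields += [repr(float(r.freqs[lid])) for lid in line_ids]
        out.append("\t".join(fields))
    _write_lines(path, out)
    if design_path is not None:
        write_design(panel.design, design_path)


# ---------------------------------------------------------------------------
# gene models

def _sniff_gene_format(path: str | os.PathLike, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    return "bed12" if ext == ".bed" else "gff3"


def read_gene_models(path: str | os.PathLike, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/exon features) or BED12.

    A GFF3 gene with no exon children is treated as single-exon.  Exons
    outside the gene span or unknown strand symbols raise
    :class:`ValidationError`.
    """
    fmt = _sniff_gene_format(path, fmt)
    if fmt == "gff3":
        return _read_gff3(path)
    if fmt == "bed12":
        return _read_bed12(path)
    raise FormatError(f"unknown gene-model format {fmt!r}")


def _read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        family = feat.attributes.get("family", ["other"])[0]
        if feat.strand not in ("+", "-"):
            raise ValidationError(f"{gene_id}: unknown strand {feat.strand!r}")
        start, end = feat.start - 1, feat.end  # 1-based inclusive -> 0-based half-open
        exons = [
            (ex.start - 1, ex.end)
            for ex in db.children(feat, featuretype="exon", order_by="start")
        ]
        if not exons:
            exons = [(start, end)]
        if feat.strand == "-":
            exons = exons[::-1]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                strand=feat.strand,
                start=start,
                end=end,
                exons=exons,
                family=family,
            )
        )
    return genes


def _read_bed12(path: str | os.PathLike) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            f = raw.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}: BED12 requires 12 columns, got {len(f)}")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            rgb = f[8]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}: blockCount mismatch for {name}")
            exons = [(start + off, start + off + size) for off, size in zip(offsets, sizes)]
            if strand == "-":
                exons = exons[::-1]
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    family=_RGB_FAMILY.get(rgb, "other"),
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gene_models(
    genes: Sequence[GeneModel], path: str | os.PathLike, fmt: str | None = None
) -> None:
    fmt = _sniff_gene_format(path, fmt)
    ordered = sorted(genes, key=lambda g: (g.chrom, g.start))
    if fmt == "gff3":
        out = ["##gff-version 3"]
        for g in ordered:
            out.append(
                "\t".join(
                    [g.chrom, "allornone", "gene", str(g.start + 1), str(g.end),
                     ".", g.strand, ".", f"ID={g.gene_id};family={g.family}"]
                )
            )
            for k, (s, e) in enumerate(g.genomic_exons(), start=1):
                out.append(
                    "\t".join(
                        [g.chrom, "allornone", "exon", str(s + 1), str(e),
                         ".", g.strand, ".", f"ID={g.gene_id}.exon{k};Parent={g.gene_id}"]
                    )
                )
        _write_lines(path, out)
    elif fmt == "bed12":
        out = []
        for g in ordered:
            blocks = g.genomic_exons()
            sizes = ",".join(str(e - s) for s, e in blocks)
            offsets = ",".join(str(s - g.start) for s, _ in blocks)
            out.append(
                "\t".join(
                    [g.chrom, str(g.start), str(g.end), g.gene_id, "0", g.strand,
                     str(g.start), str(g.end), FAMILY_RGB[g.family],
                     str(len(blocks)), sizes, offsets]
                )
            )
        _write_lines(path, out)
    else:
        raise FormatError(f"unknown gene-model format {fmt!r}")


# ---------------------------------------------------------------------------
# DE tables

def read_de_table(path: str | os.PathLike) -> list[DeGeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "family": str})
    for col in ("gene_id", "log2fc", "qvalue"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    fam = df["family"] if "family" in df.columns else ["other"] * len(df)
    return [
        DeGeneRecord(gene_id=g, log2fc=float(l), qvalue=float(q), family=f)
        for g, l, q, f in zip(df["gene_id"], df["log2fc"], df["qvalue"], fam)
    ]


def write_de_table(records: Sequence[DeGeneRecord], path: str | os.PathLike) -> None:
    out = ["gene_id\tlog2fc\tqvalue\tfamily"]
    for r in sorted(records, key=lambda r: r.gene_id):
        out.append(f"{r.gene_id}\t{float(r.log2fc)!r}\t{float(r.qvalue)!r}\t{r.family}")
    _write_lines(path, out)


# ---------------------------------------------------------------------------
# classified SNPs

def write_classified_table(classified: Sequence[ClassifiedSnp], path: str | os.PathLike) -> None:
    out = ["snp_id\tchrom\tpos\tfocal_allele\tother_allele\tis_all_or_none\t"
           "fixed_linetype\tfixed_allele\tfixed_base"]
    for c in classified:
        s = c.snp
        out.append(
            f"{s.snp_id}\t{s.chrom}\t{s.pos}\t{s.focal_allele}\t{s.other_allele}\t"
            f"{int(c.is_all_or_none)}\t{c.fixed_linetype}\t{c.fixed_allele}\t{c.fixed_base}"
        )
    _write_lines(path, out)


def read_classified_sites(path: str | os.PathLike) -> tuple[list[tuple[str, int, str]], list[str]]:
    """(chrom, pos, snp_id) sites of a classified table plus the all-or-none ids."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "snp_id": str})
    sites = [(c, int(p), s) for c, p, s in zip(df["chrom"], df["pos"], df["snp_id"])]
    aon = [s for s, flag in zip(df["snp_id"], df["is_all_or_none"]) if int(flag) == 1]
    return sites, aon


# ---------------------------------------------------------------------------
# clusters

def write_clusters_bed(clusters: Sequence[SnpCluster], path: str | os.PathLike) -> None:
    """BED6 export: 0-based half-open interval, name = id, score = size."""
    out = []
    for c in sorted(clusters, key=lambda c: (c.chrom, c.start)):
        out.append(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.cluster_id}\t{c.size}\t.")
    _write_lines(path, out)


def read_clusters_bed(path: str | os.PathLike) -> list[SnpCluster]:
    clusters: list[SnpCluster] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw or raw.startswith(("#", "track")):
                continue
            f = raw.split("\t")
            if len(f) < 5:
                raise FormatError(f"{path}: BED cluster rows need >= 5 columns")
            clusters.append(
                SnpCluster(
                    cluster_id=f[3], chrom=f[0], start=int(f[1]) + 1, end=int(f[2]),
                    members=[], size=int(f[4]),
                )
            )
    return clusters


def write_clusters_tsv(clusters: Sequence[SnpCluster], path: str | os.PathLike) -> None:
    """Full-fidelity cluster table including the member snp ids."""
    out = ["cluster_id\tchrom\tstart\tend\tsize\tmembers"]
    for c in sorted(clusters, key=lambda c: (c.chrom, c.start)):
        out.append(
            f"{c.cluster_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.size}\t{','.join(c.members)}"
        )
    _write_lines(path, out)


def read_clusters_tsv(path: str | os.PathLike) -> list[SnpCluster]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cluster_id", "chrom", "start", "end", "size", "members"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        members = row.members.split(",") if isinstance(row.members, str) and row.members else []
        out.append(
            SnpCluster(
                cluster_id=row.cluster_id, chrom=row.chrom, start=int(row.start),
                end=int(row.end), members=members, size=int(row.size),
            )
        )
    return out


# ---------------------------------------------------------------------------
# annotation table

def write_annotation_table(
    annotations: Sequence[SnpGeneAnnotation], path: str | os.PathLike
) -> None:
    """Locus-table-style TSV: one row per (SNP, gene) pair.

    Columns: snp_id, snp_location, alleles (selected/control when the
    annotator was given classifications), gene, strand, relation,
    distance_bp.  Rows are written in the annotator's stable order.
    """
    out = ["snp_id\tsnp_location\talleles\tgene\tstrand\trelation\tdistance_bp"]
    for a in annotations:
        out.append(
            f"{a.snp_id}\t{a.chrom}:{a.pos}\t{a.allele_label}\t{a.gene_id}\t"
            f"{a.gene_strand}\t{a.relation}\t{a.distance_bp}"
        )
    _write_lines(path, out)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write any summary DataFrame as a plain TSV (fixed column order)."""
    df.to_csv(path, sep="\t", index=False)
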