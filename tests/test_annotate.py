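"""Gene-proximity annotation: strand conventions, distances, DE overlap."""

import warnings

import numpy as np
import pytest

from allornone import (
    DeGeneRecord,
    GeneModel,
    SnpCluster,
    annotate_panel,
    annotate_snp,
    overlap_de_with_clusters,
)

from conftest import make_panel, make_snp


def gene(gene_id="g1", strand="+", start=5000, end=8000, exons=None,
         chrom="chr1", family="other"):
    # start/end given 0-based half-open (1-based span start+1..end)
    if exons is None:
        exons = [(start, end)]
    if strand == "-":
        exons = sorted(exons, reverse=True)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     start=start, end=end, exons=exons, family=family)


def snp_at(pos, chrom="chr1"):
    return make_snp("s1", [1, 1, 1, 1], [0, 0, 0, 0], chrom=chrom, pos=pos)


# gene spanning 1-based 5,001..8,000 -> internal [5000, 8000)
PLUS = gene(strand="+")
MINUS = gene(strand="-")


def test_plus_strand_upstream_distance():
    anns = annotate_snp(snp_at(4501), [PLUS])
    assert len(anns) == 1
    assert (anns[0].relation, anns[0].distance_bp) == ("upstream", 500)


def test_minus_strand_downstream_distance():
    anns = annotate_snp(snp_at(4477), [MINUS])
    assert (anns[0].relation, anns[0].distance_bp) == ("downstream", 524)


def test_adjacent_base_is_one_bp_away():
    assert annotate_snp(snp_at(5000), [PLUS])[0].distance_bp == 1
    assert annotate_snp(snp_at(8001), [PLUS])[0].distance_bp == 1


def test_right_side_relations_follow_strand():
    assert annotate_snp(snp_at(8501), [PLUS])[0].relation == "downstream"
    assert annotate_snp(snp_at(8501), [MINUS])[0].relation == "upstream"


def test_gene_beyond_window_not_reported():
    far = gene(start=70_000, end=75_000)
    assert annotate_snp(snp_at(1000), [far], window=50_000) == []
    assert annotate_snp(snp_at(1000), [gene(chrom="chr9")]) == []


def test_intron_of_minus_strand_two_exon_gene():
    # exons 1-based 5,001-5,500 and 7,001-8,000; SNP between them
    g = gene(strand="-", exons=[(5000, 5500), (7000, 8000)])
    anns = annotate_snp(snp_at(6000), [g])
    assert (anns[0].relation, anns[0].distance_bp) == ("intron 1", 0)


def test_exon_numbering_in_transcription_order():
    exons = [(5000, 5500), (6000, 6500), (7000, 8000)]
    plus = gene(strand="+", exons=exons)
    minus = gene(strand="-", exons=exons)
    assert annotate_snp(snp_at(5100), [plus])[0].relation == "exon 1"
    assert annotate_snp(snp_at(5100), [minus])[0].relation == "exon 3"
    assert annotate_snp(snp_at(6200), [minus])[0].relation == "exon 2"
    assert annotate_snp(snp_at(5700), [plus])[0].relation == "intron 1"
    assert annotate_snp(snp_at(5700), [minus])[0].relation == "intron 2"


def random_gene(rng, gene_id, chrom="chr1"):
    start = int(rng.integers(1000, 2_000_000))
    n_exons = int(rng.integers(1, 5))
    cuts = np.sort(rng.choice(np.arange(1, 40), size=2 * n_exons - 1, replace=False))
    bounds = start + np.concatenate([[0], np.cumsum(cuts)]) * 100
    exons = [(int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_exons)]
    strand = rng.choice(["+", "-"])
    if strand == "-":
        exons = exons[::-1]
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     start=int(bounds[0]), end=int(bounds[-1]), exons=exons)


def flip_strand(g):
    return GeneModel(gene_id=g.gene_id, chrom=g.chrom,
                     strand="-" if g.strand == "+" else "+",
                     start=g.start, end=g.end, exons=g.exons[::-1], family=g.family)


def test_strand_flip_swaps_relations_and_renumbers():
    rng = np.random.default_rng(5)
    for i in range(40):
        g = random_gene(rng, f"g{i}")
        flipped = flip_strand(g)
        pos = int(rng.integers(max(1, g.start - 40_000), g.end + 40_000))
        a1 = annotate_snp(snp_at(pos), [g])
        a2 = annotate_snp(snp_at(pos), [flipped])
        assert len(a1) == len(a2)
        if not a1:
            continue
        r1, r2 = a1[0].relation, a2[0].relation
        assert a1[0].distance_bp == a2[0].distance_bp
        if r1 in ("upstream", "downstream"):
            assert {r1, r2} == {"upstream", "downstream"}
        else:
            kind, k = r1.split()
            k = int(k)
            total = g.n_exons if kind == "exon" else g.n_exons - 1
            assert r2 == f"{kind} {total + 1 - k}"


def test_shifting_intergenic_snp_shifts_distance_linearly():
    base = annotate_snp(snp_at(4900), [PLUS])[0].distance_bp
    for k in (1, 10, 500):
        assert annotate_snp(snp_at(4900 - k), [PLUS])[0].distance_bp == base + k


def test_all_distances_within_window():
    rng = np.random.default_rng(9)
    genes = [random_gene(rng, f"g{i}") for i in range(30)]
    for pos in rng.integers(1, 2_500_000, size=60):
        for a in annotate_snp(snp_at(int(pos)), genes, window=50_000):
            assert a.distance_bp <= 50_000


def test_panel_annotation_is_union_of_per_snp(design8):
    rng = np.random.default_rng(3)
    genes = [random_gene(rng, f"g{i}") for i in range(10)]
    positions = [("chr1", int(p)) for p in rng.integers(1, 2_000_000, size=8)]
    panel = make_panel(design8, rng.uniform(size=(8, 8)), positions=positions)
    whole = annotate_panel(panel, genes)
    union = []
    for rec in panel.records:
        union.extend(annotate_snp(rec, genes))
    assert whole == union


# ---------------------------------------------------------------------------
# DE-gene / cluster overlap

def make_cluster(cid, chrom, start, end):
    return SnpCluster(cluster_id=cid, chrom=chrom, start=start, end=end,
                      members=["x"], size=1)


def test_no_de_genes_gives_zeros():
    clusters = [make_cluster("c1", "chr1", 1000, 5000)]
    genes = [gene()]
    df, totals = overlap_de_with_clusters(clusters, [], genes)
    assert df["n_de"].tolist() == [0]
    assert totals["n_de_total"] == 0


def test_single_de_gene_inside_cluster():
    clusters = [make_cluster("c1", "chr1", 1000, 10_000)]
    g = gene(family="Vmn2r")
    de = [DeGeneRecord(gene_id="g1", log2fc=1.5, qvalue=0.01, family="Vmn2r")]
    df, totals = overlap_de_with_clusters(clusters, de, [g])
    assert df.loc[0, "n_de"] == 1
    assert df.loc[0, "n_de_Vmn2r"] == 1
    assert totals["n_de_in_clusters"] == 1


def test_non_de_gene_not_counted():
    clusters = [make_cluster("c1", "chr1", 1000, 10_000)]
    de = [DeGeneRecord(gene_id="g1", log2fc=0.1, qvalue=0.5)]
    df, _ = overlap_de_with_clusters(clusters, de, [gene()])
    assert df.loc[0, "n_de"] == 0


def test_missing_de_gene_id_warns_and_is_flagged():
    clusters = [make_cluster("c1", "chr1", 1000, 10_000)]
    de = [DeGeneRecord(gene_id="ghost", log2fc=1.0, qvalue=0.01)]
    with pytest.warns(UserWarning, match="ghost"):
        _, totals = overlap_de_with_clusters(clusters, de, [gene()])
    assert totals["missing_gene_ids"] == ["ghost"]


def test_overlap_counts_match_brute_force():
    rng = np.random.default_rng(21)
    genes, de = [], []
    for i in range(60):
        g = random_gene(rng, f"g{i}", chrom=f"chr{rng.integers(1, 3)}")
        genes.append(g)
        de.append(DeGeneRecord(gene_id=g.gene_id, log2fc=float(rng.normal()),
                               qvalue=float(rng.uniform()), family=g.family))
    clusters = []
    for i in range(6):
        start = int(rng.integers(1, 1_500_000))
        clusters.append(
            make_cluster(f"c{i}", f"chr{rng.integers(1, 3)}",
                         start, start + int(rng.integers(10_000, 800_000)))
        )
    df, totals = overlap_de_with_clusters(clusters, de, genes)
    by_id = {g.gene_id: g for g in genes}
    for _, row in df.iterrows():
        expected = sum(
            1
            for d in de
            if d.is_de
            and by_id[d.gene_id].chrom == row["chrom"]
            and by_id[d.gene_id].start + 1 <= row["end"]
            and by_id[d.gene_id].end >= row["start"]
        )
        assert row["n_de"] == expected
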