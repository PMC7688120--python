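"""Synthetic-data generator: drift moments, selection, gene/DE layout."""

import numpy as np
import pytest

from allornone import (
    GeneWindow,
    P0Spec,
    ParameterError,
    SelectedLocus,
    SimulationConfig,
    classify_panel,
    exact_state_distribution,
    generate_dataset,
    generate_de_table,
    generate_gene_models,
    generate_panel,
    simulate_wf_line,
    io,
)


def test_absorbing_states():
    rng = np.random.default_rng(0)
    for p0, s in ((0.0, 0.0), (0.0, 2.0), (1.0, 0.0)):
        traj = simulate_wf_line(p0, 35, 50, s=s, rng=rng, return_trajectory=True)
        assert np.all(traj == p0)
        assert len(traj) == 51


def test_invalid_ne_rejected():
    with pytest.raises(ParameterError):
        simulate_wf_line(0.5, 0, 10)


def test_single_generation_transition_is_binomial():
    """Ne=1 (2 gametes), p0=0.5: endpoint counts 0/1/2 w.p. 1/4, 1/2, 1/4."""
    rng = np.random.default_rng(42)
    reps = 10_000
    finals = np.array([simulate_wf_line(0.5, 1, 1, rng=rng) for _ in range(reps)])
    counts = np.round(finals * 2).astype(int)
    for k, p in ((0, 0.25), (1, 0.5), (2, 0.25)):
        se = np.sqrt(p * (1 - p) / reps)
        assert abs(np.mean(counts == k) - p) <= 3 * se


def test_panel_generation_is_deterministic():
    cfg = SimulationConfig(n_loci=5, seed=123)
    assert generate_panel(cfg) == generate_panel(cfg)
    ds1, ds2 = generate_dataset(cfg), generate_dataset(cfg)
    assert ds1.truth.equals(ds2.truth)


def test_neutral_mean_and_variance_match_wright_fisher():
    """E[p_t] = p0 and Var[p_t] = p0(1-p0)(1-(1-1/2N)^t) within 3 SE."""
    cfg = SimulationConfig(n_loci=1000, p0=P0Spec(kind="fixed", value=0.5), seed=5)
    panel = generate_panel(cfg)
    freqs = np.array([[r.freqs[lid] for lid in panel.design.line_ids]
                      for r in panel.records]).ravel()
    n = freqs.size
    var_theory = 0.25 * (1 - (1 - 1 / 70) ** 88)
    assert abs(freqs.mean() - 0.5) <= 3 * np.sqrt(var_theory / n)
    m4 = np.mean((freqs - freqs.mean()) ** 4)
    se_var = np.sqrt((m4 - freqs.var() ** 2) / n)
    assert abs(freqs.var() - var_theory) <= 3 * se_var


def test_strong_selection_fixes_favored_allele():
    """s=1 at p0=0.5 fixes the favored allele in >99% of selected lines,
    matching the selection-adjusted exact chain."""
    exact_fix = exact_state_distribution(0.5, 70, 88, s=1.0)[-1]
    assert exact_fix > 0.99
    cfg = SimulationConfig(
        n_loci=60, p0=P0Spec(kind="fixed", value=0.5), seed=8,
        selected_loci=[SelectedLocus(index=i, s=1.0) for i in range(60)],
    )
    panel = generate_panel(cfg)
    sel_freqs = np.array([[r.freqs[lid] for lid in panel.design.selected_ids]
                          for r in panel.records]).ravel()
    frac_fixed = np.mean(sel_freqs == 1.0)
    se = np.sqrt(exact_fix * (1 - exact_fix) / sel_freqs.size)
    assert abs(frac_fixed - exact_fix) <= max(3 * se, 0.01)


def test_favored_other_allele_sweeps_down():
    cfg = SimulationConfig(
        n_loci=40, p0=P0Spec(kind="fixed", value=0.5), seed=9,
        selected_loci=[SelectedLocus(index=i, s=1.0, favored="other")
                       for i in range(40)],
    )
    panel = generate_panel(cfg)
    sel_freqs = np.array([[r.freqs[lid] for lid in panel.design.selected_ids]
                          for r in panel.records]).ravel()
    assert np.mean(sel_freqs == 0.0) > 0.95


def test_selected_locus_index_out_of_range():
    with pytest.raises(ParameterError):
        SimulationConfig(n_loci=5, selected_loci=[SelectedLocus(index=5, s=0.5)])


def test_cluster_window_confines_selected_loci():
    win = ("chr2", 4_000_000, 4_500_000)
    cfg = SimulationConfig(
        n_loci=50, seed=2, cluster_window=win,
        selected_loci=[SelectedLocus(index=i, s=0.5) for i in range(5)],
    )
    ds = generate_dataset(cfg)
    placed = ds.truth[ds.truth["s"] > 0]
    assert len(placed) == 5
    assert (placed["chrom"] == "chr2").all()
    assert placed["pos"].between(win[1], win[2]).all()


# ---------------------------------------------------------------------------
# gene models

def test_gene_models_disjoint_within_window():
    cfg = SimulationConfig(
        gene_windows=[GeneWindow("chr1", 1_000_000, 2_000_000, 10, "Vmn2r")], seed=4
    )
    genes = generate_gene_models(cfg)
    assert len(genes) == 10
    assert all(g.family == "Vmn2r" for g in genes)
    assert all(1_000_000 <= g.start < g.end <= 2_000_000 for g in genes)
    spans = sorted((g.start, g.end) for g in genes)
    assert all(e1 <= s2 for (_, e1), (s2, _) in zip(spans, spans[1:]))
    assert {g.strand for g in genes} == {"+", "-"}
    assert all(2 <= g.n_exons <= 5 for g in genes)


def test_zero_genes_requested():
    cfg = SimulationConfig(gene_windows=[GeneWindow("chr1", 0, 1_000_000, 0)])
    assert generate_gene_models(cfg) == []


def test_window_too_small_raises():
    cfg = SimulationConfig(gene_windows=[GeneWindow("chr1", 0, 10_000, 10)])
    with pytest.raises(ParameterError):
        generate_gene_models(cfg)


def test_generated_models_survive_serialization(tmp_path):
    cfg = SimulationConfig(
        gene_windows=[GeneWindow("chr1", 1_000_000, 2_000_000, 8, "Vmn1r"),
                      GeneWindow("chr2", 500_000, 1_200_000, 5, "other")],
        seed=6,
    )
    genes = generate_gene_models(cfg)
    path = tmp_path / "genes.gff3"
    io.write_gene_models(genes, path)
    assert io.read_gene_models(path) == sorted(genes, key=lambda g: (g.chrom, g.start))


# ---------------------------------------------------------------------------
# DE tables

def test_de_enrichment_zero_is_uniform_background():
    cfg = SimulationConfig(
        gene_windows=[GeneWindow("chr1", 0, 3_000_000, 100)],
        de_background=0.3, de_enrichment=0.0,
        de_windows=[("chr1", 0, 1_500_000)], seed=11,
    )
    genes = generate_gene_models(cfg)
    de = generate_de_table(genes, cfg)
    frac = np.mean([d.is_de for d in de])
    assert abs(frac - 0.3) <= 3 * np.sqrt(0.3 * 0.7 / len(de))


def test_full_enrichment_with_zero_background_confines_de_to_window():
    cfg = SimulationConfig(
        gene_windows=[GeneWindow("chr1", 0, 2_000_000, 50),
                      GeneWindow("chr2", 0, 2_000_000, 50)],
        de_background=0.0, de_enrichment=1.0,
        de_windows=[("chr1", 0, 2_000_000)], seed=12,
    )
    genes = generate_gene_models(cfg)
    de = generate_de_table(genes, cfg)
    status = {d.gene_id: d.is_de for d in de}
    for g in genes:
        assert status[g.gene_id] == (g.chrom == "chr1")


def test_window_de_fraction_matches_configured_probability():
    cfg = SimulationConfig(
        gene_windows=[GeneWindow("chr1", 0, 6_000_000, 200)],
        de_background=0.0, de_enrichment=0.4,
        de_windows=[("chr1", 0, 6_000_000)], seed=13,
    )
    genes = generate_gene_models(cfg)
    de = generate_de_table(genes, cfg)
    frac = np.mean([d.is_de for d in de])
    assert abs(frac - 0.4) <= 3 * np.sqrt(0.4 * 0.6 / len(de))


# ---------------------------------------------------------------------------
# downstream compatibility

def test_generated_panel_classifies_without_error():
    cfg = SimulationConfig(n_loci=50, seed=14)
    panel = generate_panel(cfg)
    classified, summary = classify_panel(panel)
    assert len(classified) == 50
    assert 0 <= summary["n_all_or_none"] <= 50
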