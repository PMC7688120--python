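"""Permutation tests for genomic co-localization.

Two label-permutation nulls, both position-preserving: the panel (or gene
set) keeps its real coordinates and only *which* loci (genes) carry the label
is resampled, so the null respects the data's own spatial density.  Tests are
one-sided upper (clustering and enrichment are directional hypotheses) and
p-values use the add-one estimator (1 + #{null >= observed}) / (1 + n_perm),
which can never be zero.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .cluster import DEFAULT_MAX_GAP, DEFAULT_PAD, cluster_snps, panel_sites
from .model import (
    DeGeneRecord,
    GeneModel,
    ParameterError,
    PermutationResult,
    SnpCluster,
    SnpPanel,
)

STATISTICS = ("frac_in_groups_ge3", "n_clusters", "max_cluster_size")


def add_one_p(null_samples: Sequence[float], observed: float) -> float:
    """One-sided upper add-one permutation p-value; always in (0, 1]."""
    null = np.asarray(null_samples, dtype=float)
    return float((1 + np.sum(null >= observed)) / (1 + null.size))


def _cluster_statistic(
    sites: list[tuple[str, int, str]],
    statistic: str,
    max_gap: int,
    min_size: int,
    pad: int,
) -> float:
    if statistic == "frac_in_groups_ge3":
        clusters, _ = cluster_snps(sites, max_gap=max_gap, min_size=3, pad=pad)
        return sum(c.size for c in clusters) / len(sites)
    clusters, _ = cluster_snps(sites, max_gap=max_gap, min_size=min_size, pad=pad)
    if statistic == "n_clusters":
        return float(len(clusters))
    if statistic == "max_cluster_size":
        return float(max((c.size for c in clusters), default=0))
    raise ParameterError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")


def permute_labels_cluster_test(
    panel: SnpPanel,
    labels: set[str] | Sequence[str],
    statistic: str = "frac_in_groups_ge3",
    n_perm: int = 10_000,
    seed: int = 0,
    cluster_params: dict | None = None,
) -> PermutationResult:
    """Are the labeled loci more spatially clustered than a random draw of the
    same size from the panel?

    The observed statistic is computed by clustering the labeled loci; the
    null redraws |labels| loci uniformly without replacement from the panel's
    positions ``n_perm`` times.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    label_set = set(labels)
    panel_ids = set(panel.snp_ids)
    if not label_set:
        raise ParameterError("labels must be non-empty")
    if not label_set <= panel_ids:
        raise ParameterError(f"labels not in panel: {sorted(label_set - panel_ids)[:5]}")

    params = dict(max_gap=DEFAULT_MAX_GAP, min_size=3, pad=DEFAULT_PAD)
    if cluster_params:
        params.update(cluster_params)

    all_sites = panel_sites(panel)
    labeled = [s for s in all_sites if s[2] in label_set]
    observed = _cluster_statistic(labeled, statistic, **params)

    rng = np.random.default_rng(seed)
    k, n = len(labeled), len(all_sites)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        null[i] = _cluster_statistic([all_sites[j] for j in idx], statistic, **params)
    return PermutationResult(
        statistic_name=statistic,
        observed=observed,
        null_samples=null.tolist(),
        p_value=add_one_p(null, observed),
        n_perm=n_perm,
        seed=seed,
    )


def de_in_cluster_enrichment(
    clusters: Sequence[SnpCluster],
    de_genes: Sequence[DeGeneRecord],
    all_genes: Sequence[GeneModel],
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Are DE genes over-represented inside the padded SNP clusters?

    Observed statistic: number of DE genes (q < 0.05) whose span intersects
    any cluster.  Null: the DE label is reassigned to a uniform random subset
    of the gene models of the same size, keeping every gene's position.
    """
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    gene_ids = [g.gene_id for g in all_genes]
    id_set = set(gene_ids)
    de_ids = [d.gene_id for d in de_genes if d.is_de]
    missing = [gid for gid in de_ids if gid not in id_set]
    if missing:
        raise ParameterError(f"DE gene ids not in gene models: {missing[:5]}")

    in_cluster = np.zeros(len(all_genes), dtype=bool)
    for i, g in enumerate(all_genes):
        for c in clusters:
            # gene 0-based half-open vs cluster 1-based inclusive
            if g.chrom == c.chrom and g.start + 1 <= c.end and g.end >= c.start:
                in_cluster[i] = True
                break
    index = {gid: i for i, gid in enumerate(gene_ids)}
    observed = float(sum(in_cluster[index[gid]] for gid in de_ids))

    rng = np.random.default_rng(seed)
    k, n = len(de_ids), len(all_genes)
    if k == 0:
        null = np.zeros(n_perm)
    else:
        null = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.choice(n, size=k, replace=False)
            null[i] = in_cluster[idx].sum()
    return PermutationResult(
        statistic_name="n_de_in_clusters",
        observed=observed,
        null_samples=null.tolist(),
        p_value=add_one_p(null, observed),
        n_perm=n_perm,
        seed=seed,
    )
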