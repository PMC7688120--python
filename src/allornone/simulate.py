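"""Synthetic data emulating a replicated selection experiment.

The generator reproduces the statistical structure the downstream analysis
assumes: 4 selected + 4 control replicate lines drifting independently for 88
generations at effective size Ne = 35 (all configurable), each locus starting
from a shared base-population frequency p0, with optional genic selection at
chosen loci in the selected lines only.  Gene models with receptor-family
tags are laid out in configurable windows so proximity annotation and
DE-gene co-localization can be exercised end to end, and a DE table with a
controllable enrichment of DE status inside target windows emulates the
clustered differential expression the analysis looks for.

Loci are unlinked and mutation-free; clusters of divergent loci arise here
only by explicit placement, not by hitchhiking.  Randomness is drawn from
independent streams keyed by (seed, purpose, line, locus), so the result for
any given locus is reproducible regardless of how many other loci are
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .model import (
    GeneModel,
    DeGeneRecord,
    LineDesign,
    ParameterError,
    SnpPanel,
    SnpRecord,
    ValidationError,
)
from .drift import selection_prob

# stream tags for keyed RNGs
_TAG_LAYOUT = 0
_TAG_WF = 1
_TAG_GENES = 2
_TAG_DE = 3


@dataclass
class P0Spec:
    """Starting-frequency distribution: ``uniform`` on [low, high] or ``fixed``.

    Default Uniform(0.1, 0.3): a standing-variation frequency band plausible
    for an outbred base population (the breeding experiment's actual base
    frequencies are unknown).
    """

    kind: str = "uniform"
    low: float = 0.1
    high: float = 0.3
    value: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "fixed"):
            raise ParameterError(f"unknown p0 distribution kind {self.kind!r}")
        if self.kind == "uniform" and not 0.0 <= self.low <= self.high <= 1.0:
            raise ParameterError(f"bad uniform p0 bounds [{self.low}, {self.high}]")
        if self.kind == "fixed" and not 0.0 <= self.value <= 1.0:
            raise ParameterError(f"fixed p0 {self.value} outside [0, 1]")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.value)
        return rng.uniform(self.low, self.high, size=n)


@dataclass
class SelectedLocus:
    """A locus under genic selection (coefficient s, favored allele) in the
    selected lines; control lines always drift neutrally."""

    index: int
    s: float
    favored: str = "focal"

    def __post_init__(self) -> None:
        if self.s <= -1.0:
            raise ParameterError(f"selection coefficient must be > -1, got {self.s}")
        if self.favored not in ("focal", "other"):
            raise ParameterError(f"favored allele must be focal/other, got {self.favored!r}")


@dataclass
class GeneWindow:
    """A genomic window to fill with ``n_genes`` non-overlapping genes of one family."""

    chrom: str
    start: int
    end: int
    n_genes: int
    family: str = "other"


@dataclass
class SimulationConfig:
    """Full parameterization of one synthetic dataset.

    ``cluster_window`` (chrom, start, end), when set, confines the positions
    of all selected loci to that interval so they form a genomic cluster.
    ``de_background`` is the DE probability of a gene anywhere;
    ``de_enrichment`` adds excess DE probability inside ``de_windows``:
    P(DE | in window) = background + enrichment * (1 - background), so
    enrichment 0 leaves DE genes uniform across the genome and enrichment 1
    makes every window gene DE.
    """

    n_loci: int = 1000
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 30_000_000, "chr2": 30_000_000}
    )
    p0: P0Spec = field(default_factory=P0Spec)
    ne: int = 35
    generations: int = 88
    n_selected_lines: int = 4
    n_control_lines: int = 4
    selected_loci: list[SelectedLocus] = field(default_factory=list)
    cluster_window: tuple[str, int, int] | None = None
    gene_windows: list[GeneWindow] = field(default_factory=list)
    de_background: float = 0.05
    de_enrichment: float = 0.0
    de_windows: list[tuple[str, int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ParameterError(f"n_loci must be >= 1, got {self.n_loci}")
        if any(length < 1 for length in self.chrom_sizes.values()):
            raise ParameterError("chromosome lengths must be >= 1")
        if self.ne < 1:
            raise ParameterError(f"ne must be >= 1, got {self.ne}")
        if self.n_selected_lines < 1 or self.n_control_lines < 1:
            raise ParameterError("need >= 1 line of each linetype")
        for sl in self.selected_loci:
            if not 0 <= sl.index < self.n_loci:
                raise ParameterError(f"selected locus index {sl.index} out of range")
        if not 0.0 <= self.de_background <= 1.0 or not 0.0 <= self.de_enrichment <= 1.0:
            raise ParameterError("DE fractions must be in [0, 1]")

    def design(self) -> LineDesign:
        lines = [(f"HR{i + 1}", "selected") for i in range(self.n_selected_lines)]
        lines += [(f"C{i + 1}", "control") for i in range(self.n_control_lines)]
        return LineDesign(lines=lines, ne=self.ne, generations=self.generations)


def simulate_wf_line(
    p0: float,
    ne: int,
    generations: int,
    s: float = 0.0,
    rng: np.random.Generator | None = None,
    return_trajectory: bool = False,
):
    """Simulate one line: 2*Ne gametes resampled binomially each generation.

    The first generation is drawn Binomial(2N, p') directly from the real-
    valued p0, so for s = 0 the endpoint mean is exactly p0 (martingale).
    States 0 and 1 are absorbing.  Returns the final focal-allele frequency,
    or the full trajectory (length ``generations`` + 1, starting at p0).
    """
    if ne < 1:
        raise ParameterError(f"ne must be >= 1, got {ne}")
    if not 0.0 <= p0 <= 1.0:
        raise ParameterError(f"p0 must be in [0, 1], got {p0}")
    if rng is None:
        rng = np.random.default_rng()
    two_n = 2 * ne
    freq = float(p0)
    traj = [freq] if return_trajectory else None
    for _ in range(generations):
        if freq in (0.0, 1.0):
            if traj is not None:
                traj.extend([freq] * (generations + 1 - len(traj)))
            break
        freq = rng.binomial(two_n, selection_prob(freq, s)) / two_n
        if traj is not None:
            traj.append(freq)
    if traj is not None:
        return np.array(traj)
    return freq


def _favored_to_focal_s(s: float, favored: str) -> float:
    """Selection coefficient on the focal allele equivalent to favoring the
    stated allele with coefficient s (genic model)."""
    return s if favored == "focal" else -s / (1.0 + s)


class Dataset(NamedTuple):
    panel: SnpPanel
    truth: pd.DataFrame


def _draw_positions(config: SimulationConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Unique (chrom, pos) per locus; selected loci confined to cluster_window."""
    chroms = sorted(config.chrom_sizes)
    lengths = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    selected_idx = {sl.index for sl in config.selected_loci}
    taken: set[tuple[str, int]] = set()
    positions: list[tuple[str, int]] = []
    for i in range(config.n_loci):
        for _ in range(1000):
            if i in selected_idx and config.cluster_window is not None:
                chrom, lo, hi = config.cluster_window
                pos = int(rng.integers(lo, hi + 1))
            else:
                chrom = chroms[rng.choice(len(chroms), p=weights)]
                pos = int(rng.integers(1, config.chrom_sizes[chrom] + 1))
            if (chrom, pos) not in taken:
                break
        else:  # pragma: no cover - would need a pathologically full window
            raise ParameterError("could not place loci at unique positions")
        taken.add((chrom, pos))
        positions.append((chrom, pos))
    return positions


def generate_panel(config: SimulationConfig) -> SnpPanel:
    """Simulate the allele-frequency panel; see :func:`generate_dataset`."""
    return generate_dataset(config).panel


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Simulate a panel plus its truth table (per-locus p0, s, favored allele).

    Every locus evolves independently in every line from a shared p0; the
    selection coefficient applies in selected lines only.  Deterministic
    given ``config.seed``.
    """
    design = config.design()
    layout_rng = np.random.default_rng([config.seed, _TAG_LAYOUT])
    positions = _draw_positions(config, layout_rng)
    p0s = config.p0.draw(config.n_loci, layout_rng)
    allele_pairs = [
        tuple(layout_rng.choice(list("ACGT"), size=2, replace=False))
        for _ in range(config.n_loci)
    ]
    sel_by_idx = {sl.index: sl for sl in config.selected_loci}

    width = max(4, len(str(config.n_loci)))
    records: list[SnpRecord] = []
    truth_rows = []
    for i, (chrom, pos) in enumerate(positions):
        sl = sel_by_idx.get(i)
        s_focal = _favored_to_focal_s(sl.s, sl.favored) if sl is not None else 0.0
        freqs: dict[str, float] = {}
        for li, (line_id, linetype) in enumerate(design.lines):
            s_line = s_focal if linetype == "selected" else 0.0
            rng = np.random.default_rng([config.seed, _TAG_WF, li, i])
            freqs[line_id] = simulate_wf_line(
                float(p0s[i]), config.ne, config.generations, s=s_line, rng=rng
            )
        snp_id = f"snp{i:0{width}d}"
        records.append(
            SnpRecord(
                snp_id=snp_id,
                chrom=chrom,
                pos=pos,
                focal_allele=allele_pairs[i][0],
                other_allele=allele_pairs[i][1],
                freqs=freqs,
            )
        )
        truth_rows.append(
            {
                "snp_id": snp_id,
                "chrom": chrom,
                "pos": pos,
                "p0": float(p0s[i]),
                "s": sl.s if sl is not None else 0.0,
                "favored_allele": sl.favored if sl is not None else "none",
            }
        )
    panel = SnpPanel(design=design, records=records)
    truth = pd.DataFrame(truth_rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return Dataset(panel=panel, truth=truth)


# ---------------------------------------------------------------------------
# gene models and DE tables

_MIN_GENE_LEN = 3_000
_MAX_GENE_LEN = 20_000
_MIN_GAP = 1_000


def generate_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Lay out non-overlapping genes (alternating strands, 2-5 exons) in each
    configured window; gene spans equal their exon hulls.

    Raises :class:`ParameterError` when a window cannot hold the requested
    number of genes at the minimum gene length and inter-gene gap.
    """
    genes: list[GeneModel] = []
    counters: dict[str, int] = {}
    for wi, win in enumerate(config.gene_windows):
        rng = np.random.default_rng([config.seed, _TAG_GENES, wi])
        span = win.end - win.start
        need = win.n_genes * (_MIN_GENE_LEN + _MIN_GAP)
        if win.n_genes > 0 and span < need:
            raise ParameterError(
                f"window {win.chrom}:{win.start}-{win.end} too small for "
                f"{win.n_genes} genes (needs >= {need} bp)"
            )
        if win.n_genes == 0:
            continue
        max_len = min(_MAX_GENE_LEN, span // win.n_genes - _MIN_GAP)
        lengths = rng.integers(_MIN_GENE_LEN, max(max_len, _MIN_GENE_LEN) + 1, size=win.n_genes)
        slack = span - int(lengths.sum()) - win.n_genes * _MIN_GAP
        extra = rng.multinomial(slack, np.ones(win.n_genes + 1) / (win.n_genes + 1))
        cursor = win.start
        for gi, length in enumerate(lengths):
            cursor += int(extra[gi]) + (_MIN_GAP if gi > 0 else 0)
            start, end = cursor, cursor + int(length)
            cursor = end
            n_exons = int(rng.integers(2, 6))
            exons = _random_exons(start, end, n_exons, rng)
            strand = "+" if gi % 2 == 0 else "-"
            if strand == "-":
                exons = exons[::-1]
            counters[win.family] = counters.get(win.family, 0) + 1
            prefix = win.family if win.family != "other" else "gene"
            genes.append(
                GeneModel(
                    gene_id=f"{prefix}{counters[win.family]}",
                    chrom=win.chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    family=win.family,
                )
            )
    return genes


def _random_exons(start: int, end: int, n_exons: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Split [start, end) into n exons and n-1 introns, each >= 50 bp,
    genomic order; first exon starts at ``start``, last ends at ``end``."""
    n_seg = 2 * n_exons - 1
    total = end - start
    min_seg = 50
    if total < n_seg * min_seg:
        n_exons = max(1, (total // min_seg + 1) // 2)
        n_seg = 2 * n_exons - 1
    spare = total - n_seg * min_seg
    parts = rng.multinomial(spare, np.ones(n_seg) / n_seg) + min_seg
    bounds = start + np.concatenate([[0], np.cumsum(parts)])
    return [(int(bounds[2 * k]), int(bounds[2 * k + 1])) for k in range(n_exons)]


def generate_de_table(
    gene_models: list[GeneModel], config: SimulationConfig
) -> list[DeGeneRecord]:
    """Assign DE status (q < 0.05) and log2 fold changes to genes.

    P(DE) = ``de_background`` everywhere, raised to background +
    enrichment * (1 - background) inside ``de_windows``.  DE genes get
    |log2FC| in [0.5, 3.3] with random sign; non-DE genes get small
    fold changes around 0.
    """
    rng = np.random.default_rng([config.seed, _TAG_DE])
    out: list[DeGeneRecord] = []
    for g in gene_models:
        in_window = any(
            g.chrom == c and g.start < end and g.end > start
            for c, start, end in config.de_windows
        )
        p_de = config.de_background
        if in_window:
            p_de = p_de + config.de_enrichment * (1.0 - p_de)
        de = rng.random() < p_de
        if de:
            q = float(rng.uniform(0.0, 0.05))
            lfc = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 3.3))
        else:
            q = float(rng.uniform(0.05, 1.0))
            lfc = float(rng.normal(0.0, 0.2))
        out.append(DeGeneRecord(gene_id=g.gene_id, log2fc=lfc, qvalue=q, family=g.family))
    return out


def config_from_dict(raw: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain (YAML-friendly) mapping."""
    raw = dict(raw)
    if "p0" in raw and isinstance(raw["p0"], dict):
        raw["p0"] = P0Spec(**raw["p0"])
    if "selected_loci" in raw:
        raw["selected_loci"] = [
            sl if isinstance(sl, SelectedLocus) else SelectedLocus(**sl)
            for sl in raw["selected_loci"]
        ]
    if "gene_windows" in raw:
        raw["gene_windows"] = [
            gw if isinstance(gw, GeneWindow) else GeneWindow(**gw)
            for gw in raw["gene_windows"]
        ]
    if "cluster_window" in raw and raw["cluster_window"] is not None:
        raw["cluster_window"] = tuple(raw["cluster_window"])
    if "de_windows" in raw:
        raw["de_windows"] = [tuple(w) for w in raw["de_windows"]]
    unknown = set(raw) - set(SimulationConfig.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**raw)
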