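import numpy as np
import pytest
from hypothesis import settings

from allornone import LineDesign, SnpPanel, SnpRecord

settings.register_profile("suite", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("suite")

SELECTED_IDS = ["HR1", "HR2", "HR3", "HR4"]
CONTROL_IDS = ["C1", "C2", "C3", "C4"]


DESIGN8 = LineDesign(
    lines=[(lid, "selected") for lid in SELECTED_IDS]
    + [(lid, "control") for lid in CONTROL_IDS],
    ne=35,
    generations=88,
)


@pytest.fixture(scope="session")
def design8() -> LineDesign:
    """4 selected + 4 control replicate lines, Ne=35, 88 generations."""
    return DESIGN8


def make_snp(snp_id, sel_freqs, con_freqs, chrom="chr1", pos=1000,
             focal="A", other="G") -> SnpRecord:
    freqs = dict(zip(SELECTED_IDS, sel_freqs)) | dict(zip(CONTROL_IDS, con_freqs))
    return SnpRecord(snp_id=snp_id, chrom=chrom, pos=pos,
                     focal_allele=focal, other_allele=other, freqs=freqs)


def make_panel(design: LineDesign, freq_matrix, positions=None) -> SnpPanel:
    """Panel from an (n_loci x 8) frequency matrix (selected lines first)."""
    freq_matrix = np.asarray(freq_matrix)
    records = []
    for i, row in enumerate(freq_matrix):
        chrom, pos = positions[i] if positions is not None else ("chr1", 1000 + 10_000 * i)
        records.append(
            make_snp(f"s{i:04d}", row[:4], row[4:], chrom=chrom, pos=pos)
        )
    return SnpPanel(design=design, records=records)
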