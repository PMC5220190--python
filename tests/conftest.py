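import numpy as np
import pytest

from peakscape import genome_io as gio
from peakscape import synthetic_data as sd


@pytest.fixture(scope="session")
def small_genome():
    spec = sd.SyntheticGenomeSpec(
        n_chromosomes=2, chrom_length=1_000_000, n_genes=120, seed=11
    )
    return sd.make_genome(spec)


@pytest.fixture(scope="session")
def small_state_map(small_genome):
    return sd.make_state_map(small_genome, seed=12)


@pytest.fixture(scope="session")
def small_peaks(small_genome, small_state_map):
    peaks, truth = sd.make_peaks(
        small_genome, n_peaks=800, state4_map=small_state_map, seed=13
    )
    return peaks, truth


@pytest.fixture(scope="session")
def small_track(small_peaks):
    return gio.peak_filter(small_peaks[0], min_height=7)


@pytest.fixture
def two_gene_fixture():
    """Two plus-strand genes 600 bp apart, head to tail (hand-enumerable)."""
    a = gio.TranscriptModel(
        transcript_id="A.1", gene_id="A", chrom="chr1", strand="+",
        tss=10_000, aug=10_200, tes=11_999, has_5utr=True,
    )
    b = gio.TranscriptModel(
        transcript_id="B.1", gene_id="B", chrom="chr1", strand="+",
        tss=12_600, aug=12_800, tes=14_599, has_5utr=True,
    )
    return [a, b]


def coverage_oracle(track, length, chrom="chr1"):
    """Per-base boolean coverage by naive python loops (oracle)."""
    cov = np.zeros(length, dtype=bool)
    for iv in track.intervals():
        if iv.chrom == chrom:
            for p in range(iv.start, min(iv.end, length)):
                cov[p] = True
    return cov
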