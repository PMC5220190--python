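"""Synthetic genomes, chromatin-state maps, peaks, motifs and annotations.

Every generator is a pure function of its seed and spec, and each dataset
can be written out in the same standard formats the pipeline ingests
(FASTA, GFF3, BED, TSV) together with a JSON truth sidecar recording the
planted parameters, so recovery tests never reach into generator
internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    ChromatinStateMap,
    GenomicInterval,
    Peak,
    Track,
    TranscriptModel,
)
from .motif import _IUPAC, CONSENSUS

__all__ = [
    "SyntheticGenomeSpec",
    "SyntheticGenome",
    "SyntheticTruth",
    "make_genome",
    "make_state_map",
    "make_peaks",
    "plant_motifs",
    "make_go_annotations",
    "write_gff",
    "write_peak_table",
]


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    n_chromosomes: int = 2
    chrom_length: int = 1_500_000
    n_genes: int = 300
    gene_length: tuple[int, int] = (1000, 3000)
    utr5_length: tuple[int, int] = (60, 300)
    gap_length: tuple[int, int] = (3000, 9000)
    utr_prob: float = 0.8
    gc: float = 0.36
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_genes < 1:
            raise ValueError("need at least one chromosome and one gene")
        if not (0 <= self.utr_prob <= 1):
            raise ValueError("utr_prob must be in [0, 1]")
        for lo, hi in (self.gene_length, self.utr5_length, self.gap_length):
            if lo < 0 or hi < lo:
                raise ValueError("length ranges must satisfy 0 <= lo <= hi")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth sidecar written next to every generated dataset."""

    params: dict

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.params, fh, indent=2, sort_keys=True, default=str)

    @classmethod
    def read(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(params=json.load(fh))


@dataclass
class SyntheticGenome:
    spec: SyntheticGenomeSpec
    chrom_lengths: dict[str, int]
    transcripts: list[TranscriptModel]
    sequences: dict[str, str] | None = None

    @property
    def chroms(self) -> list[str]:
        return sorted(self.chrom_lengths)


def make_genome(
    spec: SyntheticGenomeSpec, with_sequence: bool = False
) -> SyntheticGenome:
    """Pack non-overlapping genes onto chromosomes, one transcript per gene.

    Genes are laid out left to right with random intergenic gaps; strand,
    lengths and 5'UTR presence are drawn from the spec.  Raises if the
    requested genes do not fit.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_lengths = {
        f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chromosomes)
    }
    per_chrom = np.full(spec.n_chromosomes, spec.n_genes // spec.n_chromosomes)
    per_chrom[: spec.n_genes % spec.n_chromosomes] += 1

    transcripts: list[TranscriptModel] = []
    gene_idx = 0
    for ci, chrom in enumerate(sorted(chrom_lengths)):
        cursor = int(rng.integers(*_incl(spec.gap_length)))
        for _ in range(per_chrom[ci]):
            glen = int(rng.integers(*_incl(spec.gene_length)))
            if cursor + glen >= spec.chrom_length:
                raise ValueError(
                    f"cannot pack {spec.n_genes} genes into "
                    f"{spec.n_chromosomes} x {spec.chrom_length} bp "
                    f"(stuck on {chrom} at {cursor})"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            has_utr = bool(rng.random() < spec.utr_prob)
            max_utr = max(min(spec.utr5_length[1], glen - 100), 0)
            ulen = (
                int(rng.integers(spec.utr5_length[0], max_utr + 1))
                if has_utr and max_utr >= spec.utr5_length[0]
                else 0
            )
            gene_id = f"G{gene_idx:05d}"
            gene_idx += 1
            if strand == "+":
                tss = cursor
                aug = tss + ulen
                tes = cursor + glen - 1
            else:
                tss = cursor + glen - 1
                aug = tss - ulen
                tes = cursor
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.1",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    aug=aug,
                    tes=tes,
                    has_5utr=ulen > 0,
                )
            )
            cursor += glen + int(rng.integers(*_incl(spec.gap_length)))

    sequences = None
    if with_sequence:
        sequences = {}
        p = np.array(
            [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
        )
        for chrom, clen in sorted(chrom_lengths.items()):
            codes = rng.choice(4, size=clen, p=p)
            sequences[chrom] = (
                np.frombuffer(b"ACGT", dtype="S1")[codes]
                .tobytes()
                .decode("ascii")
            )
    return SyntheticGenome(
        spec=spec,
        chrom_lengths=chrom_lengths,
        transcripts=transcripts,
        sequences=sequences,
    )


def _incl(bounds: tuple[int, int]) -> tuple[int, int]:
    return bounds[0], bounds[1] + 1


def make_state_map(
    genome: SyntheticGenome,
    proximal_band: tuple[int, int] = (-500, 0),
    state1_band: tuple[int, int] = (-1000, -500),
    distal_band: tuple[int, int] = (-2400, -1100),
    rest_states: Sequence[int] = (5, 6, 7, 8, 9),
    rest_shares: Sequence[float] | None = None,
    rest_chunk: int = 500,
    seed: int | None = None,
) -> ChromatinStateMap:
    """A full-genome 9-state partition echoing the analysis assumptions.

    State 2 covers TSS-proximal bands, state 1 the next band out, state 4
    distal intergenic bands, state 3 gene bodies; every remaining base is
    assigned one of ``rest_states`` per contiguous run, with run labels
    drawn in proportion to ``rest_shares``.  Every base receives exactly
    one state.
    """
    rng = np.random.default_rng(genome.spec.seed if seed is None else seed)
    shares = (
        np.full(len(rest_states), 1 / len(rest_states))
        if rest_shares is None
        else np.asarray(rest_shares, dtype=float) / np.sum(rest_shares)
    )

    domains: dict[int, list[GenomicInterval]] = {i: [] for i in range(1, 10)}
    for chrom, clen in sorted(genome.chrom_lengths.items()):
        labels = np.zeros(clen, dtype=np.int8)

        def paint(lo: int, hi: int, lab: int) -> None:
            lo, hi = max(lo, 0), min(hi, clen)
            if lo < hi:
                labels[lo:hi] = lab

        txs = [t for t in genome.transcripts if t.chrom == chrom]
        for tx in txs:
            for band, lab in (
                (distal_band, 4),
                (state1_band, 1),
                (proximal_band, 2),
            ):
                if tx.strand == "+":
                    paint(tx.tss + band[0], tx.tss + band[1], lab)
                else:
                    paint(tx.tss - band[1] + 1, tx.tss - band[0] + 1, lab)
        for tx in txs:
            paint(tx.span.start, tx.span.end, 3)

        # fill leftover runs with rest states
        boundaries = np.flatnonzero(np.diff(labels)) + 1
        run_starts = np.concatenate([[0], boundaries])
        run_ends = np.concatenate([boundaries, [clen]])
        for s, e in zip(run_starts, run_ends):
            lab = int(labels[s])
            if lab != 0:
                domains[lab].append(GenomicInterval(chrom, int(s), int(e)))
                continue
            # unassigned runs become a mosaic of rest states; chunking keeps
            # any single run (e.g. a long chromosome tail) from handing one
            # state a disproportionate share of the genome
            for cs in range(int(s), int(e), rest_chunk):
                lab = int(rng.choice(rest_states, p=shares))
                domains[lab].append(
                    GenomicInterval(chrom, cs, min(cs + rest_chunk, int(e)))
                )

    return ChromatinStateMap(
        {
            lab: Track(ivs, name=f"state{lab}")
            for lab, ivs in domains.items()
            if ivs
        }
    )


def make_peaks(
    genome: SyntheticGenome,
    n_peaks: int = 3000,
    mix: tuple[float, float, float] = (0.25, 0.45, 0.30),
    m_prox: float = -150.0,
    sigma_prox: float = 80.0,
    m_dist: float = -900.0,
    sigma_dist: float = 250.0,
    peak_length: tuple[int, int] = (80, 400),
    retain_frac: float = 0.8,
    min_height: float = 7.0,
    state4_map: ChromatinStateMap | None = None,
    seed: int = 0,
) -> tuple[list[Peak], SyntheticTruth]:
    """Peaks whose TSS-relative centers follow background + two Gaussians.

    ``mix`` gives the (background, proximal, distal) component weights;
    background peaks land uniformly genome-wide (the flat C term of the
    profile model), Gaussian peaks center at a random gene's TSS plus a
    normal offset in transcript orientation.  Heights are drawn so that
    a ``retain_frac`` share reaches ``min_height``.  With ``state4_map``,
    distal centers are re-drawn (up to 50 tries) until they land in a
    state-4 domain.
    """
    if not np.isclose(sum(mix), 1.0) or min(mix) < 0:
        raise ValueError("mix must be a 3-part probability vector")
    rng = np.random.default_rng(seed)
    chroms = genome.chroms
    clens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = clens / clens.sum()
    txs = genome.transcripts
    state4 = state4_map.track(4) if state4_map is not None else None

    peaks: list[Peak] = []
    comps = rng.choice(3, size=n_peaks, p=mix)
    for comp in comps:
        length = int(rng.integers(peak_length[0], peak_length[1] + 1))
        for _attempt in range(50):
            if comp == 0:
                ci = rng.choice(len(chroms), p=chrom_p)
                chrom = chroms[ci]
                clen = genome.chrom_lengths[chrom]
                center = int(rng.integers(0, clen))
            else:
                tx = txs[int(rng.integers(0, len(txs)))]
                chrom = tx.chrom
                clen = genome.chrom_lengths[chrom]
                m, s = (
                    (m_prox, sigma_prox) if comp == 1 else (m_dist, sigma_dist)
                )
                offset = rng.normal(m, s)
                center = int(
                    tx.tss + offset if tx.strand == "+" else tx.tss - offset
                )
            start = max(center - length // 2, 0)
            end = min(start + length, clen)
            if end - start < 10:
                continue
            if comp == 2 and state4 is not None:
                arr = state4.arrays(chrom)
                idx = np.searchsorted(arr[:, 0], center, side="right") - 1
                inside = idx >= 0 and center < arr[idx, 1]
                if not inside:
                    continue
            break
        else:
            continue
        if rng.random() < retain_frac:
            height = min_height + rng.poisson(5)
        else:
            height = float(rng.integers(1, int(min_height)))
        peaks.append(Peak(GenomicInterval(chrom, start, end), float(height)))

    truth = SyntheticTruth(
        params=dict(
            kind="peaks",
            n_peaks=n_peaks,
            mix=list(mix),
            m_prox=m_prox,
            sigma_prox=sigma_prox,
            m_dist=m_dist,
            sigma_dist=sigma_dist,
            peak_length=list(peak_length),
            retain_frac=retain_frac,
            min_height=min_height,
            seed=seed,
        )
    )
    return peaks, truth


def plant_motifs(
    sequences: Mapping[str, str],
    domains: Mapping[int, Track],
    rates_per_kb: Mapping[int, float],
    seed: int = 0,
    consensus: str = CONSENSUS,
) -> tuple[dict[str, str], SyntheticTruth]:
    """Write consensus-sampled motif instances into domain sequences.

    Instance counts per domain are Poisson with mean ``rate * kb``;
    positions are uniform within the domain and re-drawn on collision
    with an earlier plant.  Returns mutated sequences plus a truth
    sidecar listing every planted (chrom, position, octamer, state).
    """
    rng = np.random.default_rng(seed)
    L = len(consensus)
    muts = {c: bytearray(s, "ascii") for c, s in sequences.items()}
    occupied: dict[str, set[int]] = {c: set() for c in sequences}
    planted: list[dict] = []

    for label in sorted(rates_per_kb):
        rate = rates_per_kb[label]
        if rate < 0:
            raise ValueError("plant rates must be >= 0")
        if rate == 0 or label not in domains:
            continue
        for iv in domains[label].intervals():
            if iv.chrom not in muts or iv.length < L:
                continue
            n = rng.poisson(rate * iv.length / 1000)
            for _ in range(n):
                for _try in range(100):
                    pos = int(rng.integers(iv.start, iv.end - L + 1))
                    if all(
                        p not in occupied[iv.chrom]
                        for p in range(pos, pos + L)
                    ):
                        break
                else:
                    continue
                octamer = "".join(
                    _IUPAC[sym][rng.integers(0, len(_IUPAC[sym]))]
                    for sym in consensus
                )
                muts[iv.chrom][pos : pos + L] = octamer.encode("ascii")
                occupied[iv.chrom].update(range(pos, pos + L))
                planted.append(
                    dict(
                        chrom=iv.chrom, pos=pos, octamer=octamer,
                        state=int(label),
                    )
                )

    truth = SyntheticTruth(
        params=dict(
            kind="motifs",
            consensus=consensus,
            rates_per_kb={str(k): v for k, v in rates_per_kb.items()},
            seed=seed,
            planted=planted,
        )
    )
    return {c: b.decode("ascii") for c, b in muts.items()}, truth


def make_go_annotations(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    background_genes: Sequence[str],
    term_fractions: Sequence[tuple[float, float]],
    bg_fraction: float = 0.02,
    vocabularies: Sequence[str] = ("BP", "MF", "CC"),
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Annotation table with controlled per-term fractions in two lists.

    ``term_fractions[i] = (frac_a, frac_b)`` sets the Bernoulli membership
    probability of term i for genes of each list; background genes join
    at ``bg_fraction``.  Vocabularies cycle BP/MF/CC.
    """
    rng = np.random.default_rng(seed)
    rows = []
    all_genes = [
        (g, "a") for g in genes_a
    ] + [(g, "b") for g in genes_b] + [
        (g, "bg") for g in background_genes
        if g not in set(genes_a) | set(genes_b)
    ]
    for i, (fa, fb) in enumerate(term_fractions):
        if not (0 <= fa <= 1 and 0 <= fb <= 1):
            raise ValueError("term fractions must lie in [0, 1]")
        term = f"T{i:04d}"
        vocab = vocabularies[i % len(vocabularies)]
        probs = {"a": fa, "b": fb, "bg": bg_fraction}
        for gene, grp in all_genes:
            if rng.random() < probs[grp]:
                rows.append(
                    dict(gene_id=gene, term_id=term, vocabulary=vocab)
                )
    df = pd.DataFrame(rows, columns=["gene_id", "term_id", "vocabulary"])
    truth = SyntheticTruth(
        params=dict(
            kind="go_annotations",
            term_fractions=[list(t) for t in term_fractions],
            bg_fraction=bg_fraction,
            seed=seed,
        )
    )
    return df, truth


# ---------------------------------------------------------------------------
# Writers for the generated datasets
# ---------------------------------------------------------------------------

def write_gff(genome: SyntheticGenome, path: str | Path) -> None:
    """GFF3 (1-based, inclusive) with gene/mRNA/five_prime_UTR/CDS rows."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in sorted(
            genome.transcripts, key=lambda t: (t.chrom, t.span.start)
        ):
            s1, e1 = tx.span.start + 1, tx.span.end  # 1-based inclusive
            common = f"{tx.chrom}\tpeakscape\t"
            tail = f"\t.\t{tx.strand}\t.\t"
            fh.write(
                f"{common}gene\t{s1}\t{e1}{tail}ID={tx.gene_id}\n"
                f"{common}mRNA\t{s1}\t{e1}{tail}"
                f"ID={tx.transcript_id};Parent={tx.gene_id}\n"
            )
            if tx.utr5 is not None:
                u = tx.utr5
                fh.write(
                    f"{common}five_prime_UTR\t{u.start + 1}\t{u.end}{tail}"
                    f"Parent={tx.transcript_id}\n"
                )
            c = tx.cds_span
            fh.write(
                f"{common}CDS\t{c.start + 1}\t{c.end}{tail}"
                f"Parent={tx.transcript_id}\n"
            )


def write_peak_table(peaks: Sequence[Peak], path: str | Path) -> None:
    """BED4 peak table: chrom, start, end, height."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.height:g}\n"
            )
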