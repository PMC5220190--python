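"""Monte-Carlo permutation tests for genome tracks.

The null model re-places every interval uniformly at random on its own
chromosome, preserving interval lengths; placements are independent, so
permuted intervals may overlap each other.  Extremely small p-values that
a finite number of permutations cannot resolve are reported through a
normal approximation against the permutation moments (``p_normal``) in
addition to the empirical ``(r + 1) / (n_perm + 1)`` estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genome_io import Track, TranscriptModel
from .interval_engine import (
    _overlap_lengths_vs_merged,
    transcript_span_track,
    tss_positions,
)

__all__ = [
    "PermutationResult",
    "permute_track",
    "location_class_test",
    "track_overlap_test",
]


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null_mean: float
    null_sd: float
    n_perm: int
    p_empirical: float
    p_normal: float
    direction: str  # "enriched" | "depleted" | "neutral"
    p_enriched: float = 1.0
    """Fixed upper-tail empirical p, regardless of direction.

    ``p_empirical`` is one-sided in the observed direction (a min-tail),
    which is the right number to report but is not uniform under the
    null; calibration checks should use this fixed-tail value instead.
    """

    def __post_init__(self) -> None:
        if not (0 < self.p_empirical <= 1):
            raise ValueError("p_empirical must be in (0, 1]")
        if self.null_sd < 0:
            raise ValueError("null_sd must be >= 0")


def _summarise(observed: float, null: np.ndarray, n_perm: int) -> PermutationResult:
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    n_ge = int((null >= observed).sum())
    if observed > mean:
        direction = "enriched"
        r = n_ge
    elif observed < mean:
        direction = "depleted"
        r = int((null <= observed).sum())
    else:
        direction = "neutral"
        r = n_perm
    p_emp = (r + 1) / (n_perm + 1)
    if sd > 0:
        z = (observed - mean) / sd
        p_norm = float(stats.norm.sf(z) if observed >= mean else stats.norm.cdf(z))
    else:
        p_norm = 1.0 if observed == mean else 0.0
    return PermutationResult(
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        n_perm=n_perm,
        p_empirical=p_emp,
        p_normal=p_norm,
        direction=direction,
        p_enriched=(n_ge + 1) / (n_perm + 1),
    )


def _random_starts(
    track: Track,
    chrom_lengths: Mapping[str, int],
    rng: np.random.Generator,
    n_perm: int,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: interval lengths (m,) and random starts (n_perm, m)."""
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in track.chroms:
        arr = track.arrays(chrom)
        if chrom not in chrom_lengths:
            raise ValueError(f"no length given for chromosome {chrom!r}")
        clen = int(chrom_lengths[chrom])
        lengths = arr[:, 1] - arr[:, 0]
        if (lengths > clen).any():
            raise ValueError(
                f"interval longer than chromosome {chrom!r} ({clen} bp)"
            )
        # start uniform over [0, clen - length], inclusive
        starts = rng.integers(
            0, clen - lengths + 1, size=(n_perm, lengths.size), dtype=np.int64
        )
        out[chrom] = (lengths, starts)
    return out


def permute_track(
    track: Track,
    chrom_lengths: Mapping[str, int],
    seed: int | np.random.Generator = 0,
) -> Track:
    """One uniform random re-placement of every interval, lengths preserved."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    placed = _random_starts(track, chrom_lengths, rng, 1)
    out = {
        chrom: np.stack([starts[0], starts[0] + lengths], axis=1)
        for chrom, (lengths, starts) in placed.items()
    }
    return Track.from_arrays(out, name=f"{track.name}~perm")


def location_class_test(
    track: Track,
    transcripts: Sequence[TranscriptModel],
    chrom_lengths: Mapping[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict[str, PermutationResult]:
    """Per-class enrichment/depletion of interval counts vs random placement.

    Returns one :class:`PermutationResult` per class (TSS, GENE,
    INTERGENIC); the observed statistic is the number of track intervals
    assigned to the class.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    from .interval_engine import classify_locations

    observed = classify_locations(track, transcripts).counts

    rng = np.random.default_rng(seed)
    tss = tss_positions(transcripts)
    bodies = transcript_span_track(transcripts)
    null_tss = np.zeros(n_perm, dtype=np.int64)
    null_gene = np.zeros(n_perm, dtype=np.int64)
    total = 0
    for chrom, (lengths, starts) in _random_starts(
        track, chrom_lengths, rng, n_perm
    ).items():
        total += lengths.size
        ends = starts + lengths
        t = tss.get(chrom, np.empty(0, dtype=np.int64))
        is_tss = np.searchsorted(t, ends) > np.searchsorted(t, starts)
        b = bodies.arrays(chrom)
        ov = _overlap_lengths_vs_merged(
            starts.ravel(), ends.ravel(), b
        ).reshape(starts.shape)
        is_gene = (ov > 0) & ~is_tss
        null_tss += is_tss.sum(axis=1)
        null_gene += is_gene.sum(axis=1)
    null_inter = total - null_tss - null_gene
    nulls = {"TSS": null_tss, "GENE": null_gene, "INTERGENIC": null_inter}
    return {
        cls: _summarise(observed[cls], nulls[cls].astype(float), n_perm)
        for cls in ("TSS", "GENE", "INTERGENIC")
    }


def track_overlap_test(
    query: Track,
    reference: Track,
    chrom_lengths: Mapping[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
    permute: str = "query",
) -> PermutationResult:
    """Significance of the fraction of overlap between two tracks.

    The statistic is total overlap length divided by the total length of
    the permuted track (lengths are preserved under permutation, so the
    denominator is constant).  ``permute`` chooses which track is
    randomised ("query", the default, or "reference").
    """
    if permute not in ("query", "reference"):
        raise ValueError("permute must be 'query' or 'reference'")
    if permute == "reference":
        query, reference = reference, query
    if len(query) == 0:
        raise ValueError("cannot permute an empty track")

    # per-interval overlap with the raw total length as denominator, so the
    # observed and permuted statistics are computed identically (permuted
    # intervals may overlap each other, making a merged denominator unstable)
    raw_denom = query.total_length
    rm = reference.merged()
    obs = 0
    for chrom in query.chroms:
        arr = query.arrays(chrom)
        obs += int(
            _overlap_lengths_vs_merged(
                arr[:, 0], arr[:, 1], rm.arrays(chrom)
            ).sum()
        )
    observed = obs / raw_denom

    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm, dtype=np.float64)
    for chrom, (lengths, starts) in _random_starts(
        query, chrom_lengths, rng, n_perm
    ).items():
        ends = starts + lengths
        ov = _overlap_lengths_vs_merged(
            starts.ravel(), ends.ravel(), rm.arrays(chrom)
        ).reshape(starts.shape)
        null += ov.sum(axis=1)
    null /= raw_denom
    return _summarise(observed, null, n_perm)
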