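"""Interval arithmetic over tracks and transcript annotations.

Location classification (TSS / GENE / INTERGENIC), track intersection and
subtraction, overlap measurement, strand-aware upstream windows, the
eight upstream-region datasets, and gene linkage.

Overlap always means at least one shared base under half-open semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome_io import GenomicInterval, Track, TranscriptModel

__all__ = [
    "LocationClassResult",
    "UpstreamDatasets",
    "classify_locations",
    "intersect",
    "subtract",
    "union",
    "overlap_length",
    "overlap_fraction",
    "upstream_window",
    "build_upstream_datasets",
    "link_genes",
    "transcript_span_track",
    "tss_positions",
]

CLASSES = ("TSS", "GENE", "INTERGENIC")


@dataclass
class LocationClassResult:
    """Counts and fractions of intervals in each location class."""

    counts: dict[str, int]
    labels: list[str] = field(repr=False, default_factory=list)

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        n = self.n
        if n == 0:
            return {c: 0.0 for c in CLASSES}
        return {c: self.counts[c] / n for c in CLASSES}


def tss_positions(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, np.ndarray]:
    """Sorted unique TSS base positions per chromosome."""
    by_chrom: dict[str, set[int]] = {}
    for tx in transcripts:
        by_chrom.setdefault(tx.chrom, set()).add(tx.tss)
    return {
        c: np.asarray(sorted(v), dtype=np.int64) for c, v in by_chrom.items()
    }


def transcript_span_track(transcripts: Iterable[TranscriptModel]) -> Track:
    """Union of gene-body spans of all transcripts."""
    return Track((tx.span for tx in transcripts), name="transcripts").merged()


def classify_locations(
    track: Track, transcripts: Sequence[TranscriptModel]
) -> LocationClassResult:
    """Assign every interval exactly one of TSS / GENE / INTERGENIC.

    TSS: the interval covers at least one transcription start base.
    GENE: otherwise, it shares >= 1 bp with any gene body.
    INTERGENIC: everything else.  Intervals on chromosomes absent from the
    annotation are INTERGENIC (with a warning).
    """
    if not transcripts:
        raise ValueError("classify_locations requires a non-empty annotation")
    tss = tss_positions(transcripts)
    bodies = transcript_span_track(transcripts)
    known_chroms = set(tss) | set(bodies.chroms)

    counts = {c: 0 for c in CLASSES}
    labels: list[str] = []
    warned: set[str] = set()
    for chrom in track.chroms:
        arr = track.arrays(chrom)
        if chrom not in known_chroms:
            if chrom not in warned:
                warnings.warn(
                    f"chromosome {chrom!r} absent from annotation; intervals "
                    "classified INTERGENIC",
                    stacklevel=2,
                )
                warned.add(chrom)
            counts["INTERGENIC"] += arr.shape[0]
            labels.extend(["INTERGENIC"] * arr.shape[0])
            continue
        t = tss.get(chrom, np.empty(0, dtype=np.int64))
        b = bodies.arrays(chrom)
        starts, ends = arr[:, 0], arr[:, 1]
        has_tss = np.searchsorted(t, ends, side="left") > np.searchsorted(
            t, starts, side="left"
        )
        ov = _overlap_lengths_vs_merged(starts, ends, b)
        for s_tss, s_ov in zip(has_tss, ov > 0):
            if s_tss:
                lab = "TSS"
            elif s_ov:
                lab = "GENE"
            else:
                lab = "INTERGENIC"
            counts[lab] += 1
            labels.append(lab)
    return LocationClassResult(counts=counts, labels=labels)


# ---------------------------------------------------------------------------
# Set operations (operands are normalised internally)
# ---------------------------------------------------------------------------

def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-pointer intersection of merged, sorted (n,2) arrays."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < a.shape[0] and j < b.shape[0]:
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append((int(lo), int(hi)))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def intersect(a: Track, b: Track, name: str = "") -> Track:
    """Maximal continuous fragments present in both tracks."""
    am, bm = a.merged(), b.merged()
    out: dict[str, np.ndarray] = {}
    for chrom in am.chroms:
        frag = _intersect_arrays(am.arrays(chrom), bm.arrays(chrom))
        if frag.shape[0]:
            out[chrom] = frag
    return Track.from_arrays(out, name=name or f"{a.name}&{b.name}")


def union(a: Track, b: Track, name: str = "") -> Track:
    return Track(
        list(a.intervals()) + list(b.intervals()), name=name or f"{a.name}|{b.name}"
    ).merged()


def subtract(a: Track, b: Track, name: str = "") -> Track:
    """Bases of ``a`` not covered by ``b`` (a \\ b), as maximal fragments."""
    am, bm = a.merged(), b.merged()
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in am.chroms:
        barr = bm.arrays(chrom)
        pieces: list[tuple[int, int]] = []
        for s, e in am.arrays(chrom):
            cur = int(s)
            lo = np.searchsorted(barr[:, 1], cur, side="right")
            k = int(lo)
            while k < barr.shape[0] and barr[k, 0] < e:
                if barr[k, 0] > cur:
                    pieces.append((cur, int(barr[k, 0])))
                cur = max(cur, int(barr[k, 1]))
                k += 1
            if cur < e:
                pieces.append((cur, int(e)))
        if pieces:
            out[chrom] = np.asarray(pieces, dtype=np.int64)
    return Track.from_arrays(out, name=name or f"{a.name}-{b.name}")


def _overlap_lengths_vs_merged(
    starts: np.ndarray, ends: np.ndarray, merged: np.ndarray
) -> np.ndarray:
    """Per-query overlap length against a merged reference array.

    Uses prefix sums of merged coverage so each query costs O(log n).
    """
    if merged.shape[0] == 0:
        return np.zeros(len(starts), dtype=np.int64)
    ms, me = merged[:, 0], merged[:, 1]
    cum = np.concatenate([[0], np.cumsum(me - ms)])

    def covered_upto(pos: np.ndarray) -> np.ndarray:
        # covered bases in [0, pos): complete intervals left of pos plus the
        # clipped part of the rightmost interval starting before pos
        idx = np.searchsorted(ms, pos, side="right")
        prev = np.maximum(idx - 1, 0)
        clipped = np.clip(pos - ms[prev], 0, me[prev] - ms[prev])
        return np.where(idx > 0, cum[prev] + clipped, 0)

    return covered_upto(ends) - covered_upto(starts)


def overlap_length(query: Track, reference: Track) -> int:
    """Total shared bases between the two tracks (both union-normalised)."""
    qm, rm = query.merged(), reference.merged()
    total = 0
    for chrom in qm.chroms:
        arr = qm.arrays(chrom)
        total += int(
            _overlap_lengths_vs_merged(arr[:, 0], arr[:, 1], rm.arrays(chrom)).sum()
        )
    return total


def overlap_fraction(query: Track, reference: Track) -> float:
    """Total overlap length divided by the query track's total length."""
    qlen = query.merged().total_length
    if qlen == 0:
        raise ValueError("overlap_fraction undefined for an empty query track")
    return overlap_length(query, reference) / qlen


# ---------------------------------------------------------------------------
# Upstream windows and the eight upstream-region datasets
# ---------------------------------------------------------------------------

def upstream_window(
    tx: TranscriptModel, from_offset: int, to_offset: int
) -> GenomicInterval | None:
    """Strand-aware genomic interval for TSS-relative offsets.

    Offsets are in transcript orientation; the window covers offsets
    ``from_offset <= x < to_offset`` where offset 0 is the TSS base itself.
    E.g. ``(-500, 0)`` is the 500 bp immediately upstream, excluding the
    TSS; ``(-500, 1)`` includes it.  Windows truncated at position 0 are
    kept if non-empty; fully off-chromosome windows return None.
    """
    if from_offset >= to_offset:
        raise ValueError("from_offset must be < to_offset")
    if tx.strand == "+":
        s, e = tx.tss + from_offset, tx.tss + to_offset
    else:
        s, e = tx.tss - to_offset + 1, tx.tss - from_offset + 1
    s = max(s, 0)
    if s >= e:
        return None
    return GenomicInterval(tx.chrom, s, e, tx.strand)


@dataclass
class UpstreamDatasets:
    """The eight upstream-region tracks and their surviving-region counts.

    Datasets 1..7 are the seven 500-bp bins walking from offset -3500 up
    to the TSS; dataset 8 is the 5'UTR ([TSS, AUG)).
    """

    tracks: list[Track]

    @property
    def counts(self) -> list[int]:
        return [len(t) for t in self.tracks]


def build_upstream_datasets(
    transcripts: Sequence[TranscriptModel],
    span: int = 3500,
    bin_width: int = 500,
) -> UpstreamDatasets:
    """Construct the eight upstream-region datasets with their filters.

    Per transcript the candidate regions are the ``span/bin_width`` 500-bp
    bins tiling [-span, 0) upstream of the TSS plus the 5'UTR [TSS, AUG).
    Filters (all "overlap" = >= 1 shared base, vs the union over ALL
    transcripts):
      * bins 1..7: dropped if overlapping any transcript gene body;
      * bin k <= 6: additionally dropped if overlapping the nested
        upstream range [-(span - k*bin_width), 0) of any transcript;
      * the 5'UTR dataset: dropped if overlapping any translated region
        ([AUG, stop]) or any [-bin_width, 0) proximal upstream window.
    """
    if span % bin_width:
        raise ValueError("span must be a multiple of bin_width")
    n_bins = span // bin_width
    spans = transcript_span_track(transcripts)

    # union upstream windows [-x, 0) over all transcripts, one per depth
    depth_tracks: dict[int, Track] = {}
    for depth in range(bin_width, span, bin_width):
        ivs = [
            w
            for tx in transcripts
            if (w := upstream_window(tx, -depth, 0)) is not None
        ]
        depth_tracks[depth] = Track(ivs).merged()

    datasets: list[Track] = []
    for k in range(1, n_bins + 1):
        lo = -span + (k - 1) * bin_width
        hi = lo + bin_width
        regions = [
            w
            for tx in transcripts
            if (w := upstream_window(tx, lo, hi)) is not None
        ]
        keep = _drop_overlapping(regions, spans)
        if k < n_bins:
            nested = depth_tracks[span - k * bin_width]
            keep = _drop_overlapping(keep, nested)
        datasets.append(Track(keep, name=f"upstream_bin_{k}"))

    # dataset 8: 5'UTRs
    utrs = [u for tx in transcripts if (u := tx.utr5) is not None]
    cds = Track((tx.cds_span for tx in transcripts), name="cds").merged()
    keep = _drop_overlapping(utrs, cds)
    keep = _drop_overlapping(keep, depth_tracks.get(bin_width) or Track())
    datasets.append(Track(keep, name="utr5"))
    return UpstreamDatasets(tracks=datasets)


def _drop_overlapping(
    regions: list[GenomicInterval], blocked: Track
) -> list[GenomicInterval]:
    if not regions:
        return []
    out = []
    for iv in regions:
        merged = blocked.arrays(iv.chrom)
        ov = _overlap_lengths_vs_merged(
            np.asarray([iv.start]), np.asarray([iv.end]), merged
        )[0]
        if ov == 0:
            out.append(iv)
    return out


def link_genes(
    track: Track,
    transcripts: Sequence[TranscriptModel],
    window: tuple[int, int] = (-3500, 1),
) -> dict[str, list[GenomicInterval]]:
    """Map gene_id -> track intervals overlapping its upstream window.

    A gene is linked iff at least one base of an interval falls in the
    strand-aware window of ANY of its transcripts (default: offsets
    -3500..0 inclusive of the TSS base).
    """
    if window[0] >= window[1]:
        raise ValueError("window upstream bound must be < downstream bound")
    hits: dict[str, dict[GenomicInterval, None]] = {}
    # per-gene union of windows
    windows: dict[str, list[GenomicInterval]] = {}
    for tx in transcripts:
        w = upstream_window(tx, window[0], window[1])
        if w is not None:
            windows.setdefault(tx.gene_id, []).append(w)
    for gene_id, wins in windows.items():
        wt = Track(wins).merged()
        for chrom in wt.chroms:
            arr = track.arrays(chrom)
            if arr.shape[0] == 0:
                continue
            ov = _overlap_lengths_vs_merged(
                arr[:, 0], arr[:, 1], wt.arrays(chrom)
            )
            for (s, e), o in zip(arr, ov):
                if o > 0:
                    hits.setdefault(gene_id, {})[
                        GenomicInterval(chrom, int(s), int(e))
                    ] = None
    return {g: list(d) for g, d in hits.items()}
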