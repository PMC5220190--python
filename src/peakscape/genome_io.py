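"""Core genomic data model and format readers/writers.

All internal coordinates are 0-based, half-open ``[start, end)``.  GFF3
(1-based, fully closed) and BED (0-based, half-open) values are converted
here and nowhere else, so coordinate arithmetic elsewhere in the package
never has to know which file format a region came from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "Track",
    "TranscriptModel",
    "Peak",
    "ChromatinStateMap",
    "read_gff_transcripts",
    "read_peaks",
    "peak_filter",
    "read_state_map",
    "write_state_map",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "dedupe_by_tss",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class Track:
    """A named collection of intervals, stored per chromosome and sorted.

    Intervals may overlap each other unless the track has been normalised
    with :meth:`merged`; ``total_length`` always counts every interval,
    overlapping or not.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), name: str = ""):
        self.name = name
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._by_chrom: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            arr = np.asarray(sorted(pairs), dtype=np.int64)
            self._by_chrom[chrom] = arr

    @classmethod
    def from_arrays(
        cls, by_chrom: Mapping[str, np.ndarray], name: str = ""
    ) -> "Track":
        """Build directly from per-chromosome ``(n, 2)`` start/end arrays."""
        t = cls(name=name)
        for chrom, arr in by_chrom.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size and not (arr[:, 0] < arr[:, 1]).all():
                raise ValueError(f"empty or inverted interval on {chrom}")
            order = np.argsort(arr[:, 0], kind="stable")
            t._by_chrom[chrom] = arr[order]
        return t

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def arrays(self, chrom: str) -> np.ndarray:
        """Sorted ``(n, 2)`` array of [start, end) for one chromosome."""
        return self._by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    def intervals(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            for s, e in self._by_chrom[chrom]:
                yield GenomicInterval(chrom, int(s), int(e))

    def __len__(self) -> int:
        return sum(a.shape[0] for a in self._by_chrom.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        return self.intervals()

    @property
    def total_length(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._by_chrom.values())
        )

    def merged(self, name: str | None = None) -> "Track":
        """Union-normalised copy: overlapping/adjacent intervals coalesced."""
        out: dict[str, np.ndarray] = {}
        for chrom, arr in self._by_chrom.items():
            if arr.shape[0] == 0:
                continue
            merged: list[list[int]] = [[int(arr[0, 0]), int(arr[0, 1])]]
            for s, e in arr[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], int(e))
                else:
                    merged.append([int(s), int(e)])
            out[chrom] = np.asarray(merged, dtype=np.int64)
        return Track.from_arrays(out, name=self.name if name is None else name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Track):
            return NotImplemented
        if set(self._by_chrom) != set(other._by_chrom):
            return False
        return all(
            np.array_equal(self._by_chrom[c], other._by_chrom[c])
            for c in self._by_chrom
        )

    def __repr__(self) -> str:
        return (
            f"Track(name={self.name!r}, n={len(self)}, "
            f"total_length={self.total_length})"
        )


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript reduced to the anchors the analysis needs.

    ``tss``, ``aug`` and ``tes`` are 0-based base positions (not half-open
    bounds): the first transcribed base, the first base of the start codon
    and the last transcribed base.  On the minus strand the genomic order
    is ``tes <= aug <= tss``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int
    aug: int
    tes: int
    has_5utr: bool = False
    is_protein_coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be +/-, got {self.strand!r}")
        if self.strand == "+":
            ok = self.tss <= self.aug <= self.tes
        else:
            ok = self.tes <= self.aug <= self.tss
        if not ok:
            raise ValueError(
                f"{self.transcript_id}: inconsistent tss/aug/tes ordering "
                f"({self.tss}, {self.aug}, {self.tes}) on strand {self.strand}"
            )
        if self.has_5utr and self.tss == self.aug:
            raise ValueError(
                f"{self.transcript_id}: has_5utr requires tss != aug"
            )

    @property
    def span(self) -> GenomicInterval:
        """Gene-body interval [leftmost, rightmost+1)."""
        lo = min(self.tss, self.tes)
        hi = max(self.tss, self.tes)
        return GenomicInterval(self.chrom, lo, hi + 1, self.strand)

    @property
    def utr5(self) -> GenomicInterval | None:
        """5'UTR as [TSS, AUG) in transcript orientation, or None."""
        if self.tss == self.aug:
            return None
        if self.strand == "+":
            return GenomicInterval(self.chrom, self.tss, self.aug, "+")
        return GenomicInterval(self.chrom, self.aug + 1, self.tss + 1, "-")

    @property
    def cds_span(self) -> GenomicInterval:
        """Translated region [AUG..stop] as a genomic interval."""
        if self.strand == "+":
            return GenomicInterval(self.chrom, self.aug, self.tes + 1, "+")
        return GenomicInterval(self.chrom, self.tes, self.aug + 1, "-")


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    height: float

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError(f"peak height must be >= 0, got {self.height}")


class ChromatinStateMap:
    """Per-state domain tracks for a 9-state genome segmentation.

    Domains of distinct states must not share a single base; state labels
    are integers in 1..9 (not every label has to be present).
    """

    VALID_LABELS = frozenset(range(1, 10))

    def __init__(self, domains: Mapping[int, Track]):
        bad = set(domains) - self.VALID_LABELS
        if bad:
            raise ValueError(f"state labels outside 1..9: {sorted(bad)}")
        self.domains: dict[int, Track] = {
            int(k): v.merged(name=f"state{k}") for k, v in domains.items()
        }
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        total = sum(t.total_length for t in self.domains.values())
        union = Track(
            iv for t in self.domains.values() for iv in t.intervals()
        ).merged()
        if union.total_length != total:
            raise ValueError(
                "domains of different chromatin states overlap "
                f"(union {union.total_length} < sum {total})"
            )

    @property
    def labels(self) -> list[int]:
        return sorted(self.domains)

    def track(self, *labels: int) -> Track:
        """Union track over one or more state labels (absent labels: empty)."""
        ivs = [
            iv
            for lab in labels
            for iv in self.domains.get(lab, Track()).intervals()
        ]
        return Track(ivs, name="state" + "+".join(map(str, labels))).merged()


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.strip().strip(";").split(";"):
        if not item:
            continue
        if "=" in item:
            k, _, v = item.partition("=")
            out[k.strip()] = v.strip()
    return out


def read_gff_transcripts(
    path: str | Path,
    protein_coding_only: bool = True,
) -> list[TranscriptModel]:
    """Parse a GFF3 (TAIR dialect) into :class:`TranscriptModel` records.

    One record per mRNA feature.  A transcript is protein-coding iff it has
    at least one CDS child; mRNAs without CDS are skipped with a warning.
    ``has_5utr`` is set from the presence of a ``five_prime_UTR`` child.
    """
    mrnas: dict[str, dict] = {}
    cds_bounds: dict[str, list[int]] = {}
    has_utr: set[str] = set()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{path}: malformed GFF3 line {lineno}: "
                    f"expected 9 tab-separated fields, got {len(cols)}"
                )
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed GFF3 line {lineno}: non-numeric "
                    f"coordinates {start!r}/{end!r}"
                ) from exc
            if ftype in ("mRNA", "transcript"):
                a = _parse_attributes(attrs)
                tid = a.get("ID")
                if tid is None:
                    raise ValueError(
                        f"{path}: line {lineno}: mRNA without ID attribute"
                    )
                mrnas[tid] = {
                    "chrom": chrom,
                    # GFF3 is 1-based inclusive; store 0-based positions
                    "start": start_i - 1,
                    "end": end_i - 1,
                    "strand": strand,
                    "gene_id": a.get("Parent", tid),
                }
            elif ftype == "CDS":
                a = _parse_attributes(attrs)
                for parent in a.get("Parent", "").split(","):
                    if parent:
                        cds_bounds.setdefault(parent, []).extend(
                            (start_i - 1, end_i - 1)
                        )
            elif ftype == "five_prime_UTR":
                a = _parse_attributes(attrs)
                for parent in a.get("Parent", "").split(","):
                    if parent:
                        has_utr.add(parent)

    out: list[TranscriptModel] = []
    for tid, rec in mrnas.items():
        coding = tid in cds_bounds
        if not coding:
            if protein_coding_only:
                warnings.warn(
                    f"transcript {tid} has no CDS feature; skipped",
                    stacklevel=2,
                )
                continue
            aug = rec["start"] if rec["strand"] == "+" else rec["end"]
        else:
            bounds = cds_bounds[tid]
            aug = min(bounds) if rec["strand"] == "+" else max(bounds)
        if rec["strand"] == "+":
            tss, tes = rec["start"], rec["end"]
        else:
            tss, tes = rec["end"], rec["start"]
        utr = tid in has_utr and tss != aug
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                tss=tss,
                aug=aug,
                tes=tes,
                has_5utr=utr,
                is_protein_coding=coding,
            )
        )
    return out


def dedupe_by_tss(transcripts: Iterable[TranscriptModel]) -> list[TranscriptModel]:
    """Keep one transcript per distinct (chrom, strand, tss).

    Ties are broken by transcript_id so the result is deterministic.
    """
    best: dict[tuple[str, str, int], TranscriptModel] = {}
    for tx in transcripts:
        key = (tx.chrom, tx.strand, tx.tss)
        if key not in best or tx.transcript_id < best[key].transcript_id:
            best[key] = tx
    return sorted(best.values(), key=lambda t: (t.chrom, t.tss, t.transcript_id))


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

def read_peaks(
    path: str | Path,
    height_col: int = 3,
    one_based: bool = False,
) -> list[Peak]:
    """Read a BED-like or MACS-style peak table.

    ``height_col`` is the 0-based column index of the peak-height value
    (default 3: the 4th column of a BED4).  For a MACS-1.4 ``.xls`` table
    pass ``one_based=True`` and the index of the column to treat as height.
    Comment lines (``#``) and a single header line are tolerated.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) <= height_col:
                raise ValueError(
                    f"{path}: line {lineno}: height column {height_col} "
                    f"missing (row has {len(cols)} columns)"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
                height = float(cols[height_col])
            except ValueError:
                if lineno == 1 or not peaks:
                    continue  # header line
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric coordinate or height"
                )
            if one_based:
                start -= 1
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            peaks.append(Peak(GenomicInterval(cols[0], start, end), height))
    return peaks


def peak_filter(peaks: Iterable[Peak], min_height: float = 7) -> Track:
    """Retain peaks with height >= ``min_height``; return their intervals."""
    if min_height < 0:
        raise ValueError("min_height must be >= 0")
    return Track(
        (p.interval for p in peaks if p.height >= min_height),
        name=f"peaks_ge_{min_height:g}",
    )


# ---------------------------------------------------------------------------
# Chromatin-state map (BED4 with integer state label in column 4)
# ---------------------------------------------------------------------------

def read_state_map(path: str | Path) -> ChromatinStateMap:
    by_state: dict[int, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"{path}: line {lineno}: need 4 columns")
            try:
                label = int(cols[3])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: state label {cols[3]!r} "
                    "is not an integer"
                ) from exc
            if label not in ChromatinStateMap.VALID_LABELS:
                raise ValueError(
                    f"{path}: line {lineno}: state label {label} outside 1..9"
                )
            by_state.setdefault(label, []).append(
                GenomicInterval(cols[0], int(cols[1]), int(cols[2]))
            )
    return ChromatinStateMap(
        {lab: Track(ivs, name=f"state{lab}") for lab, ivs in by_state.items()}
    )


def write_state_map(state_map: ChromatinStateMap, path: str | Path) -> None:
    rows = []
    for lab in state_map.labels:
        for iv in state_map.domains[lab].intervals():
            rows.append((iv.chrom, iv.start, iv.end, lab))
    rows.sort()
    with open(path, "w") as fh:
        for chrom, start, end, lab in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{lab}\n")


def write_bed(track: Track, path: str | Path, name_prefix: str = "") -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(track.intervals()):
            if name_prefix:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name_prefix}{i}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# FASTA (simple whole-chromosome records; genomes here are small)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                seqs[current] = []
            else:
                if current is None:
                    raise ValueError(f"{path}: sequence data before header")
                seqs[current].append(line.upper())
    return {name: "".join(parts) for name, parts in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
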