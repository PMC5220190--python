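"""PWM construction, min-max normalised scoring and sequence scanning.

The octamer consensus AYGWAYCT (Y = C/T, W = A/T) is shipped as a
reconstructed position-frequency matrix; the weight function is a
pluggable log-odds with background-proportional pseudocounts, and scores
are min-max normalised per matrix so a single threshold (default 0.91)
applies on a [0, 1] scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHABET = "ACGT"
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_CODE = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CONSENSUS = "AYGWAYCT"
DEFAULT_THRESHOLD = 0.91

__all__ = [
    "Pfm",
    "PwmModel",
    "SiteScanResult",
    "CONSENSUS",
    "DEFAULT_THRESHOLD",
    "teil_pfm",
    "pwm_from_pfm",
    "score_normalized",
    "scan",
    "density_compare",
    "density_vs_threshold",
    "read_pfm",
    "write_pfm",
]


@dataclass(frozen=True)
class Pfm:
    """4 x L count matrix, rows in A, C, G, T order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x L matrix with L >= 1")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        sums = counts.sum(axis=0)
        if (sums == 0).any():
            raise ValueError("every column must have a positive count sum")
        if not np.allclose(sums, sums[0]):
            raise ValueError("column sums must be equal (aligned-site counts)")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        """IUPAC consensus: all bases carrying the column's maximal count."""
        out = []
        rev = {frozenset(v): k for k, v in _IUPAC.items()}
        for col in self.counts.T:
            present = frozenset(
                ALPHABET[i] for i in range(4) if col[i] == col.max()
            )
            out.append(rev[present])
        return "".join(out)

    @classmethod
    def from_consensus(cls, consensus: str, sites: int = 12) -> "Pfm":
        """Counts of ``sites`` idealised aligned sites matching a consensus."""
        counts = np.zeros((4, len(consensus)), dtype=float)
        for j, sym in enumerate(consensus.upper()):
            bases = _IUPAC.get(sym)
            if bases is None:
                raise ValueError(f"invalid IUPAC symbol {sym!r}")
            if sites % len(bases):
                raise ValueError(
                    f"sites={sites} not divisible by degeneracy of {sym!r}"
                )
            for b in bases:
                counts[_CODE[b], j] = sites / len(bases)
        return cls(counts)


def teil_pfm(sites: int = 12) -> Pfm:
    """The shipped octamer matrix, reconstructed from consensus AYGWAYCT."""
    return Pfm.from_consensus(CONSENSUS, sites=sites)


def _default_weights(
    counts: np.ndarray, background: np.ndarray, pseudocount: float
) -> np.ndarray:
    n = counts.sum(axis=0)
    return np.log(
        (counts + pseudocount * background[:, None])
        / ((n + pseudocount) * background[:, None])
    )


@dataclass(frozen=True)
class PwmModel:
    weights: np.ndarray
    s_min: float
    s_max: float
    threshold: float = DEFAULT_THRESHOLD
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.s_min >= self.s_max:
            raise ValueError(
                "degenerate matrix: min and max raw scores coincide"
            )
        if not (0 <= self.threshold <= 1):
            raise ValueError("threshold must be in [0, 1]")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.weights.shape[1]


def pwm_from_pfm(
    pfm: Pfm,
    background: Sequence[float] | None = None,
    pseudocount: float = 1.0,
    threshold: float = DEFAULT_THRESHOLD,
    weight_fn: Callable[[np.ndarray, np.ndarray, float], np.ndarray] | None = None,
) -> PwmModel:
    """Turn a count matrix into a scoring matrix with min-max bounds.

    ``weight_fn(counts, background, pseudocount)`` may replace the default
    log-odds weighting.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = np.asarray(
        background if background is not None else np.full(4, 0.25), dtype=float
    )
    fn = weight_fn or _default_weights
    w = fn(pfm.counts, bg, pseudocount)
    s_min = float(w.min(axis=0).sum())
    s_max = float(w.max(axis=0).sum())
    return PwmModel(
        weights=w,
        s_min=s_min,
        s_max=s_max,
        threshold=threshold,
        background=bg,
        pseudocount=pseudocount,
    )


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for b, i in _CODE.items():
        code[ord(b)] = i
    return code[arr]


def _window_scores(enc: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Normalised-scale raw sums per window; NaN where a window holds non-ACGT."""
    L = weights.shape[1]
    n = enc.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        col = enc[j : j + n]
        bad = col < 0
        valid &= ~bad
        scores += weights[np.where(bad, 0, col), j]
    scores[~valid] = np.nan
    return scores


def score_normalized(pwm: PwmModel, seq: str) -> float:
    """Min-max normalised score of a single length-L sequence."""
    if len(seq) != pwm.length:
        raise ValueError(
            f"sequence length {len(seq)} != matrix length {pwm.length}"
        )
    enc = _encode(seq)
    if (enc < 0).any():
        raise ValueError(f"ambiguous base in {seq!r}: score undefined")
    raw = float(pwm.weights[enc, np.arange(pwm.length)].sum())
    return (raw - pwm.s_min) / (pwm.s_max - pwm.s_min)


@dataclass(frozen=True)
class SiteScanResult:
    """Hit statistics of one scanned sequence set."""

    positions: int
    hits: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.hits <= self.positions):
            raise ValueError("need 0 <= hits <= positions")

    @property
    def density(self) -> float:
        if self.positions == 0:
            raise ZeroDivisionError(
                f"density undefined: no scorable positions in {self.label!r}"
            )
        return self.hits / self.positions

    def normalized_density(self, genome: "SiteScanResult") -> float:
        gd = genome.density
        if gd == 0:
            raise ZeroDivisionError("genome-average density is zero")
        return self.density / gd

    @property
    def misses(self) -> int:
        return self.positions - self.hits


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan(
    pwm: PwmModel,
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    threshold: float | None = None,
    both_strands: bool = True,
    label: str = "",
) -> SiteScanResult:
    """Slide a width-L window (step 1) over every sequence and count hits.

    A position counts once; with ``both_strands`` it is a hit if either
    orientation reaches the threshold.  Windows containing non-ACGT bases
    are excluded from both counts.
    """
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    thr = pwm.threshold if threshold is None else threshold
    span = pwm.s_max - pwm.s_min
    raw_thr = pwm.s_min + thr * span

    positions = hits = 0
    n_seqs = 0
    for _name, seq in items:
        n_seqs += 1
        enc = _encode(seq)
        fwd = _window_scores(enc, pwm.weights)
        if fwd.size == 0:
            continue
        valid = ~np.isnan(fwd)
        hit = np.zeros(fwd.size, dtype=bool)
        hit[valid] = fwd[valid] >= raw_thr - 1e-12
        if both_strands:
            rev = _window_scores(_encode(_revcomp(seq)), pwm.weights)[::-1]
            rvalid = ~np.isnan(rev)
            hit[rvalid] |= rev[rvalid] >= raw_thr - 1e-12
            valid |= rvalid
        positions += int(valid.sum())
        hits += int(hit[valid].sum())
    if n_seqs == 0:
        raise ValueError("scan requires at least one sequence")
    return SiteScanResult(positions=positions, hits=hits, label=label)


def density_compare(
    results_a: Sequence[SiteScanResult],
    results_b: Sequence[SiteScanResult],
    alpha: float = 0.05,
    strong_alpha: float = 0.01,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Per-interval Fisher test of hit proportions between two conditions.

    Rows pair up ``results_a[i]`` vs ``results_b[i]``; Bonferroni
    significance flags are evaluated at ``alpha/n`` and ``strong_alpha/n``
    where ``n`` defaults to the number of comparable pairs.  Pairs where
    either side has zero scorable positions are skipped with a note.
    """
    if len(results_a) != len(results_b):
        raise ValueError("result lists must have equal length")
    n = n_tests if n_tests is not None else len(results_a)
    rows = []
    for a, b in zip(results_a, results_b):
        label = a.label or b.label
        if a.positions == 0 or b.positions == 0:
            rows.append(
                dict(
                    interval=label, p=np.nan, odds_ratio=np.nan,
                    significant=False, strongly_significant=False,
                    note="skipped: zero scorable positions",
                )
            )
            continue
        table = [[a.hits, a.misses], [b.hits, b.misses]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            dict(
                interval=label,
                p=float(p),
                odds_ratio=float(odds),
                significant=bool(p < alpha / n),
                strongly_significant=bool(p < strong_alpha / n),
                note="",
            )
        )
    return pd.DataFrame(rows)


def density_vs_threshold(
    pwm: PwmModel,
    foreground: Mapping[str, str],
    background_seqs: Mapping[str, str],
    thresholds: Sequence[float],
    both_strands: bool = True,
) -> pd.DataFrame:
    """Density of hits in a foreground vs a background set per threshold.

    Generic threshold-calibration curve: pick the threshold giving clear
    foreground enrichment at an acceptable background (false positive)
    density.
    """
    rows = []
    for thr in thresholds:
        fg = scan(pwm, foreground, threshold=thr, both_strands=both_strands)
        bg = scan(
            pwm, background_seqs, threshold=thr, both_strands=both_strands
        )
        fg_d = fg.hits / fg.positions if fg.positions else np.nan
        bg_d = bg.hits / bg.positions if bg.positions else np.nan
        rows.append(
            dict(
                threshold=thr,
                fg_density=fg_d,
                bg_density=bg_d,
                enrichment=fg_d / bg_d if bg_d else np.nan,
            )
        )
    return pd.DataFrame(rows)


def read_pfm(path: str | Path) -> Pfm:
    """Read a 4-row whitespace-separated count matrix.

    The optional header line names the row order and must be A C G T.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if all(p.rstrip(":") in set("ACGT") for p in parts):
                if [p.rstrip(":") for p in parts] != list("ACGT"):
                    raise ValueError(
                        f"{path}: header row order must be A C G T"
                    )
                continue
            if parts[0].rstrip(":") in set("ACGT"):
                parts = parts[1:]
            rows.append([float(v) for v in parts])
    if len(rows) != 4:
        raise ValueError(f"{path}: expected 4 count rows, got {len(rows)}")
    return Pfm(np.asarray(rows))


def write_pfm(pfm: Pfm, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# rows: A C G T\n")
        for i, base in enumerate(ALPHABET):
            fh.write(
                base + ":\t" + "\t".join(f"{v:g}" for v in pfm.counts[i]) + "\n"
            )
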