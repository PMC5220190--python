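"""TSS-relative occurrence profiles and the bimodal Gaussian profile model.

The profile value at offset ``x`` is the fraction of genes whose
strand-aware position TSS+x is covered by at least one track interval
(a gene counts if any of its transcripts hits).  The model is

    f(x) = C + A_prox * phi(x; m_prox, s_prox) + A_dist * phi(x; m_dist, s_dist)

with ``phi`` the normal density (units 1/bp, so the amplitudes A carry
units of bp * fraction) and ``C`` a flat non-specific baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .genome_io import ChromatinStateMap, Track, TranscriptModel
from .interval_engine import intersect, subtract

__all__ = [
    "OccurrenceProfile",
    "BimodalModelParams",
    "BimodalFit",
    "occurrence_profile",
    "model_eval",
    "fit_bimodal",
    "stratified_profile",
]

DEFAULT_WINDOW = (-1500, 100)


@dataclass(frozen=True)
class OccurrenceProfile:
    """Per-offset fraction of genes hit by a track, over a TSS window."""

    window: tuple[int, int]  # inclusive offsets [from, to]
    values: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        lo, hi = self.window
        if len(self.values) != hi - lo + 1:
            raise ValueError("profile length must equal to - from + 1")
        if self.values.size and (
            self.values.min() < 0 or self.values.max() > 1
        ):
            raise ValueError("profile values must lie in [0, 1]")

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1] + 1)


@dataclass(frozen=True)
class BimodalModelParams:
    c: float
    a_prox: float
    m_prox: float
    sigma_prox: float
    a_dist: float
    m_dist: float
    sigma_dist: float

    def __post_init__(self) -> None:
        if self.sigma_prox <= 0 or self.sigma_dist <= 0:
            raise ValueError("sigma values must be > 0")
        if self.a_prox < 0 or self.a_dist < 0 or self.c < 0:
            raise ValueError("C and amplitudes must be >= 0")


@dataclass(frozen=True)
class BimodalFit:
    params: BimodalModelParams
    rss: float
    n_starts: int


def model_eval(x, params: BimodalModelParams):
    """Evaluate the bimodal model at offset(s) ``x``."""
    x = np.asarray(x, dtype=float)
    y = (
        params.c
        + params.a_prox * stats.norm.pdf(x, params.m_prox, params.sigma_prox)
        + params.a_dist * stats.norm.pdf(x, params.m_dist, params.sigma_dist)
    )
    return float(y) if y.ndim == 0 else y


def _gene_hit_matrix(
    track: Track,
    transcripts: Sequence[TranscriptModel],
    window: tuple[int, int],
) -> tuple[np.ndarray, int]:
    """Per-offset gene-hit counts: (#genes hit at each offset, n_genes)."""
    if not transcripts:
        raise ValueError("occurrence_profile requires a non-empty gene set")
    lo, hi = window
    width = hi - lo + 1

    # boolean coverage per chromosome, padded so TSS-window slices never
    # run off either end
    pad = max(abs(lo), abs(hi)) + 1
    cov: dict[str, np.ndarray] = {}
    maxend: dict[str, int] = {}
    for tx in transcripts:
        maxend[tx.chrom] = max(maxend.get(tx.chrom, 0), tx.tss + 1)
    for chrom in set(maxend) | set(track.chroms):
        arr = track.arrays(chrom)
        top = max(maxend.get(chrom, 0), int(arr[:, 1].max()) if arr.size else 0)
        c = np.zeros(top + 2 * pad, dtype=bool)
        for s, e in arr:
            c[s + pad : e + pad] = True
        cov[chrom] = c

    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)

    counts = np.zeros(width, dtype=np.int64)
    for txs in by_gene.values():
        acc: np.ndarray | None = None
        for tx in txs:
            c = cov[tx.chrom]
            if tx.strand == "+":
                sl = c[tx.tss + lo + pad : tx.tss + hi + 1 + pad]
            else:
                sl = c[tx.tss - hi + pad : tx.tss - lo + 1 + pad][::-1]
            acc = sl.copy() if acc is None else (acc | sl)
        counts += acc
    return counts, len(by_gene)


def occurrence_profile(
    track: Track,
    transcripts: Sequence[TranscriptModel],
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> OccurrenceProfile:
    """Fraction of genes hit by the track at each TSS-relative offset."""
    counts, n_genes = _gene_hit_matrix(track, transcripts, window)
    return OccurrenceProfile(
        window=window, values=counts / n_genes, n_genes=n_genes
    )


def stratified_profile(
    track: Track,
    state_map: ChromatinStateMap,
    transcripts: Sequence[TranscriptModel],
    window: tuple[int, int] = DEFAULT_WINDOW,
    groups: Sequence[tuple[int, ...]] = ((1,), (2,), (4,)),
) -> dict[str, OccurrenceProfile]:
    """One profile per state group plus the remainder ("rest").

    The track is split into the fragments falling inside each group's
    domains and a remainder; because chromatin-state domains partition
    the covered bases, the per-group profiles sum positionwise to the
    unstratified profile whenever genes carry a single transcript.
    """
    profiles: dict[str, OccurrenceProfile] = {}
    covered = Track()
    for group in groups:
        sub = intersect(track, state_map.track(*group))
        covered = Track(
            list(covered.intervals()) + list(sub.intervals())
        ).merged()
        key = "+".join(map(str, group))
        profiles[key] = occurrence_profile(sub, transcripts, window)
    rest = subtract(track, covered, name="rest")
    profiles["rest"] = occurrence_profile(rest, transcripts, window)
    return profiles


def _residuals(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # theta parameterises the distal mean as m_prox - gap so the optimiser
    # cannot collapse the two components onto the same location
    c, ap, mp, sp, ad, gap, sd = theta
    return (
        c
        + ap * stats.norm.pdf(x, mp, sp)
        + ad * stats.norm.pdf(x, mp - gap, sd)
        - y
    )


class FitError(RuntimeError):
    """Raised when no start converges; carries the best partial fit."""

    def __init__(self, message: str, best: BimodalFit | None = None):
        super().__init__(message)
        self.best = best


def fit_bimodal(
    profile: OccurrenceProfile,
    prox_grid: Sequence[float] | None = None,
    dist_grid: Sequence[float] | None = None,
    min_separation: float = 300.0,
) -> BimodalFit:
    """Nonlinear least-squares fit of the bimodal model to a profile.

    Multi-start over a grid of (m_prox, m_dist) initial means.  The means
    are constrained to be <= 0 (the model describes upstream binding) and
    at least ``min_separation`` bp apart, which keeps the two components
    identifiable: on a unimodal profile the distal amplitude is forced
    toward zero instead of splitting the single peak in two.
    Deterministic: no randomness is involved.
    """
    y = profile.values.astype(float)
    if np.unique(y).size < 2:
        raise ValueError("profile is degenerate (constant); nothing to fit")
    x = profile.offsets.astype(float)
    lo, hi = profile.window
    span = hi - lo

    if prox_grid is None:
        prox_grid = [lo * 0.05, lo * 0.15, lo * 0.3]
    if dist_grid is None:
        dist_grid = [lo * 0.8, lo * 0.6, lo * 0.45]

    c0 = max(float(y.min()), 1e-9)
    amp0 = max(float(y.max() - y.min()), 1e-9)
    bounds_lo = [0.0, 0.0, float(lo), 1.0, 0.0, float(min_separation), 1.0]
    bounds_hi = [1.0, np.inf, 0.0, float(span), np.inf, float(span), float(span)]

    best: BimodalFit | None = None
    n_starts = 0
    for mp0 in prox_grid:
        for md0 in dist_grid:
            gap0 = float(np.clip(mp0 - md0, min_separation, span))
            for sp0, sd0 in ((60.0, 250.0), (120.0, 400.0)):
                n_starts += 1
                theta0 = [
                    c0,
                    amp0 * sp0 * np.sqrt(2 * np.pi),
                    float(np.clip(mp0, lo, 0)),
                    sp0,
                    amp0 * sd0 * np.sqrt(2 * np.pi) / 2,
                    gap0,
                    sd0,
                ]
                try:
                    res = optimize.least_squares(
                        _residuals,
                        theta0,
                        bounds=(bounds_lo, bounds_hi),
                        args=(x, y),
                        method="trf",
                    )
                except Exception:  # noqa: BLE001 - keep trying other starts
                    continue
                rss = float(2 * res.cost)
                c, ap, mp, sp, ad, gap, sd = res.x
                md = mp - gap
                fit = BimodalFit(
                    params=BimodalModelParams(c, ap, mp, sp, ad, md, sd),
                    rss=rss,
                    n_starts=n_starts,
                )
                if res.success and (best is None or fit.rss < best.rss):
                    best = fit
    if best is None:
        raise FitError("no optimisation start converged", best=None)
    return best
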