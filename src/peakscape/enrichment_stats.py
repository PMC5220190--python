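"""Gene-list compilation by chromatin state and GO-term comparison.

Enrichment against a background universe uses the EASE variant of the
one-sided Fisher exact test (term-positive count jackknifed by one);
robust terms (fraction > 3% of the list and BH-adjusted enrichment
p < 0.05) from either list are then compared between the two lists with
a two-sided Fisher test, BH-adjusted again.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import ChromatinStateMap, Track, TranscriptModel
from .interval_engine import link_genes, overlap_length

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact",
    "ease_score",
    "bh_adjust",
    "compile_state_gene_lists",
    "go_compare",
    "read_annotations",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b / c, d: rows = lists (X1/Y1), columns = in/out (X2/Y2)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cells must be >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("grand total must be > 0")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(
    table: ContingencyTable2x2, sided: str = "two"
) -> tuple[float, float]:
    """Exact hypergeometric p-value and odds ratio for a 2x2 table."""
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}[
        sided
    ]
    t = table.as_array
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        import warnings

        warnings.warn("empty margin: Fisher p fixed at 1", stacklevel=2)
        return 1.0, np.nan
    odds, p = stats.fisher_exact(t, alternative=alternative)
    return float(p), float(odds)


def ease_score(table: ContingencyTable2x2) -> float:
    """One-sided (enrichment) Fisher p after the EASE one-gene jackknife."""
    if table.a == 0:
        return 1.0
    jack = ContingencyTable2x2(table.a - 1, table.b + 1, table.c, table.d)
    p, _ = fisher_exact(jack, sided="greater")
    return p


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, monotone, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def compile_state_gene_lists(
    ebrs: Track,
    state_map: ChromatinStateMap,
    transcripts: Sequence[TranscriptModel],
    window: tuple[int, int] = (-3500, 1),
    proximal_states: tuple[int, ...] = (1, 2),
    distal_states: tuple[int, ...] = (4,),
) -> tuple[list[str], list[str]]:
    """Two disjoint gene lists: proximal-state-only vs distal-state-only.

    Genes are linked to peak intervals through their upstream windows;
    each linked interval is flagged by >= 1 bp overlap with the state
    domains, flags are aggregated per gene over all its intervals, and
    genes carrying both flags (or appearing in both lists) are dropped.
    """
    prox_track = state_map.track(*proximal_states)
    dist_track = state_map.track(*distal_states)
    linked = link_genes(ebrs, transcripts, window=window)

    list_prox: set[str] = set()
    list_dist: set[str] = set()
    for gene_id, intervals in linked.items():
        t = Track(intervals)
        has_prox = overlap_length(t, prox_track) > 0
        has_dist = overlap_length(t, dist_track) > 0
        if has_prox and not has_dist:
            list_prox.add(gene_id)
        elif has_dist and not has_prox:
            list_dist.add(gene_id)
    both = list_prox & list_dist
    return sorted(list_prox - both), sorted(list_dist - both)


def read_annotations(path) -> pd.DataFrame:
    """Gene->term annotation TSV with columns gene_id, term_id, vocabulary."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id", "vocabulary"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"annotation table must have columns {sorted(required)}"
        )
    return df


def _term_members(annotations: pd.DataFrame) -> dict[str, set[str]]:
    return {
        term: set(group["gene_id"])
        for term, group in annotations.groupby("term_id")
    }


def go_compare(
    list_a: Iterable[str],
    list_b: Iterable[str],
    annotations: pd.DataFrame,
    background: Iterable[str] | None = None,
    min_fraction: float = 0.03,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Robust-term selection per list, then a between-list Fisher comparison.

    Per list, a term is robust when its gene fraction exceeds
    ``min_fraction`` AND its BH-adjusted EASE enrichment p (vs the
    background universe) is below ``fdr``.  The union of robust terms is
    compared between the lists with a two-sided Fisher test on the
    lists-by-membership table, BH-adjusted at ``fdr``.
    """
    set_a, set_b = set(list_a), set(list_b)
    universe = (
        set(background) if background is not None else set(annotations["gene_id"])
    )
    universe |= set_a | set_b
    members = _term_members(annotations)
    vocab = dict(
        zip(annotations["term_id"], annotations["vocabulary"], strict=True)
    )

    def enrich(genes: set[str]) -> pd.DataFrame:
        n_list = len(genes)
        n_bg = len(universe) - n_list
        recs = []
        for term, tgenes in members.items():
            a = len(genes & tgenes)
            if a == 0:
                continue
            c = len((universe - genes) & tgenes)
            table = ContingencyTable2x2(a, n_list - a, c, n_bg - c)
            recs.append(
                dict(
                    term_id=term,
                    n=a,
                    fraction=a / n_list if n_list else 0.0,
                    p_enrich=ease_score(table),
                )
            )
        df = pd.DataFrame(
            recs, columns=["term_id", "n", "fraction", "p_enrich"]
        )
        if len(df):
            df["fdr_enrich"] = bh_adjust(df["p_enrich"].to_numpy())
        else:
            df["fdr_enrich"] = pd.Series(dtype=float)
        df["robust"] = (df["fraction"] > min_fraction) & (
            df["fdr_enrich"] < fdr
        )
        return df.set_index("term_id")

    ea, eb = enrich(set_a), enrich(set_b)
    robust_terms = sorted(
        set(ea.index[ea["robust"]]) | set(eb.index[eb["robust"]])
    )

    rows = []
    for term in robust_terms:
        tgenes = members[term]
        a = len(set_a & tgenes)
        c = len(set_b & tgenes)
        table = ContingencyTable2x2(a, len(set_a) - a, c, len(set_b) - c)
        p, odds = fisher_exact(table, sided="two")
        rows.append(
            dict(
                term_id=term,
                vocabulary=vocab.get(term, ""),
                n_a=a,
                n_b=c,
                fraction_a=a / len(set_a) if set_a else 0.0,
                fraction_b=c / len(set_b) if set_b else 0.0,
                fdr_enrich_a=float(ea["fdr_enrich"].get(term, np.nan)),
                fdr_enrich_b=float(eb["fdr_enrich"].get(term, np.nan)),
                p_between=p,
                odds_ratio=odds,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "vocabulary", "n_a", "n_b", "fraction_a", "fraction_b",
            "fdr_enrich_a", "fdr_enrich_b", "p_between", "odds_ratio",
        ],
    )
    if len(out):
        out["fdr_between"] = bh_adjust(out["p_between"].to_numpy())
        out["significant"] = out["fdr_between"] < fdr
        out["enriched_in"] = np.where(
            ~out["significant"],
            "",
            np.where(out["fraction_b"] > out["fraction_a"], "B", "A"),
        )
    else:
        out["fdr_between"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        out["enriched_in"] = pd.Series(dtype=str)
    return out
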