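"""Multi-mark integration logic.

Combines per-mark differential calls into imputed expression directions,
Venn-region accounting, time-course trend profiles, RNA x ChIP concordance,
and a generic hypergeometric gene-set enrichment test.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffenrich import adjust_pvalues

__all__ = [
    "MarkCallSet",
    "TrendProfile",
    "PROFILE_CODES",
    "impute_up_genes",
    "impute_down_genes",
    "venn_counts",
    "trend_profile",
    "concordance_table",
    "hypergeom_enrichment",
]

ACTIVE_MARKS = ("H3K4me3", "H3K27ac")
SUPPRESSIVE_MARKS = ("H3K9me3", "H3K27me3")
TRANSCRIBED_MARK = "H3K36me3"


class MarkCallSet:
    """Per-mark sets of genes called more / less enriched.

    Constructed either from explicit sets or from classified differential
    tables (:func:`epidiet.diffenrich.classify_calls` output) via
    :meth:`from_call_tables`.
    """

    def __init__(self, calls: Mapping[str, Mapping[str, Iterable[str]]]):
        self._more: dict[str, frozenset[str]] = {}
        self._less: dict[str, frozenset[str]] = {}
        for mark, d in calls.items():
            more = frozenset(d.get("more", ()))
            less = frozenset(d.get("less", ()))
            if more & less:
                raise ValueError(f"{mark}: more and less sets intersect")
            self._more[mark] = more
            self._less[mark] = less

    @classmethod
    def from_call_tables(cls, tables: Mapping[str, pd.DataFrame]) -> "MarkCallSet":
        return cls(
            {
                mark: {
                    "more": set(df.index[df["call"] == "more"]),
                    "less": set(df.index[df["call"] == "less"]),
                }
                for mark, df in tables.items()
            }
        )

    @property
    def marks(self) -> list[str]:
        return list(self._more)

    def more(self, mark: str) -> frozenset[str]:
        return self._more.get(mark, frozenset())

    def less(self, mark: str) -> frozenset[str]:
        return self._less.get(mark, frozenset())

    def changed(self, mark: str) -> frozenset[str]:
        """Genes significantly changed in either direction for a mark."""
        return self.more(mark) | self.less(mark)


def impute_up_genes(calls: MarkCallSet) -> set[str]:
    """Genes imputed up-regulated from promoter mark combinatorics.

    A gene qualifies when both activating marks (H3K4me3 and H3K27ac) gained
    enrichment while neither suppressive mark (H3K9me3, H3K27me3) did.
    """
    return set(
        calls.more("H3K4me3")
        & calls.more("H3K27ac")
        - calls.more("H3K9me3")
        - calls.more("H3K27me3")
    )


def impute_down_genes(calls: MarkCallSet, suppressive_rule: str = "or") -> set[str]:
    """Genes imputed down-regulated: no activating gain, suppressive gain.

    ``suppressive_rule`` selects whether a gain of either suppressive mark
    suffices (``"or"``, the default) or both are required (``"and"``).
    """
    if suppressive_rule == "or":
        suppressed = calls.more("H3K9me3") | calls.more("H3K27me3")
    elif suppressive_rule == "and":
        suppressed = calls.more("H3K9me3") & calls.more("H3K27me3")
    else:
        raise ValueError(f"unknown suppressive_rule {suppressive_rule!r}")
    return set(suppressed - calls.more("H3K4me3") - calls.more("H3K27ac"))


def venn_counts(sets: Mapping[str, Iterable[str]]) -> dict[tuple[bool, ...], int]:
    """Counts of every non-empty membership pattern across 2-4 named sets.

    Keys are boolean membership tuples in the order of ``sets``; values sum to
    the size of the union.
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_counts requires 2-4 sets")
    frozen = [frozenset(sets[n]) for n in names]
    universe = frozenset().union(*frozen)
    counts = {
        pattern: 0
        for pattern in itertools.product((True, False), repeat=len(names))
        if any(pattern)
    }
    for g in universe:
        pattern = tuple(g in s for s in frozen)
        counts[pattern] += 1
    return counts


# profile codes p1..p9: lexicographic over (step1, step2) with up < flat < down,
# so p1 is the monotone less-to-more trajectory
_STEP_ORDER = ("up", "flat", "down")
PROFILE_CODES: dict[tuple[str, str], str] = {
    pair: f"p{i + 1}"
    for i, pair in enumerate(itertools.product(_STEP_ORDER, repeat=2))
}


@dataclass(frozen=True)
class TrendProfile:
    gene_id: str
    log2fc: tuple[float, float, float]
    steps: tuple[str, str]
    code: str


def trend_profile(
    log2fc_triple: Sequence[float],
    gene_id: str = "",
    slope_threshold: float = 1.0,
) -> TrendProfile:
    """Classify a time-course of three log2 fold changes into one of 9 profiles.

    Each adjacent-step difference is classed up (>= threshold), down
    (<= -threshold) or flat; the step-class pair maps to codes p1..p9.
    """
    values = tuple(float(v) for v in log2fc_triple)
    if len(values) != 3:
        raise ValueError("expected exactly three log2FC values")
    if not all(np.isfinite(values)):
        raise ValueError("log2FC values must be finite")

    def classify(delta: float) -> str:
        if delta >= slope_threshold:
            return "up"
        if delta <= -slope_threshold:
            return "down"
        return "flat"

    steps = (classify(values[1] - values[0]), classify(values[2] - values[1]))
    return TrendProfile(gene_id, values, steps, PROFILE_CODES[steps])


def concordance_table(
    rna_up: Iterable[str],
    rna_down: Iterable[str],
    calls: MarkCallSet,
) -> tuple[set[str], set[str], pd.DataFrame]:
    """RNA x ChIP concordance: intersect RNA directions with mark patterns.

    Up-concordant genes are RNA-up genes whose promoters gained all three
    transcription-associated marks (H3K4me3, H3K27ac, H3K36me3) and neither
    suppressive mark; down-concordant genes show the mirrored pattern (both
    suppressive marks gained, none of the active three). Returns the two gene
    sets and the Sankey-ready edge table with one (rna_direction, mark, count)
    row per pair.
    """
    rna_up = frozenset(rna_up)
    rna_down = frozenset(rna_down)
    active = (*ACTIVE_MARKS, TRANSCRIBED_MARK)

    up_pattern = frozenset.intersection(*(calls.more(m) for m in active))
    for m in SUPPRESSIVE_MARKS:
        up_pattern -= calls.more(m)
    up_concordant = set(rna_up & up_pattern)

    down_pattern = frozenset.intersection(*(calls.more(m) for m in SUPPRESSIVE_MARKS))
    for m in active:
        down_pattern -= calls.more(m)
    down_concordant = set(rna_down & down_pattern)

    rows = [("up", m, len(up_concordant)) for m in active]
    rows += [("down", m, len(down_concordant)) for m in SUPPRESSIVE_MARKS]
    edges = pd.DataFrame(rows, columns=["rna_direction", "mark", "count"])
    return up_concordant, down_concordant, edges


def hypergeom_enrichment(
    query: Iterable[str],
    universe: Iterable[str],
    terms: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric gene-set enrichment with BH adjustment.

    For each term, p = P(X >= k) where X counts query genes in the term under
    sampling n genes from a universe of N containing K term genes. Terms are
    intersected with the universe before testing; results are sorted by p.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    query = frozenset(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for term_id, genes in terms.items():
        term_genes = frozenset(genes) & universe
        K = len(term_genes)
        k = len(query & term_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, N, n, K, k, min(1.0, p)))
    df = pd.DataFrame(
        rows, columns=["term", "universe_size", "query_size", "term_size", "overlap", "p"]
    )
    df["p_adj"] = adjust_pvalues(df["p"].to_numpy(), "BH") if len(df) else []
    return df.sort_values("p", kind="stable").reset_index(drop=True)
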