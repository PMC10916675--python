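"""Two-condition differential enrichment testing for count data.

Window-count construction plus an exact conditional count test in the
edgeR-style common-dispersion family: counts are rescaled to a common
(geometric-mean) library size, and the two counts are compared conditionally
on their sum. With dispersion 0 the conditional law is Binomial(n, 1/2); with
dispersion phi > 0 it is obtained by enumerating the joint negative-binomial
probabilities over all splits of the sum (equivalently a symmetric
beta-binomial with shape 1/phi). Two-sided p-values sum the probabilities of
all outcomes no more probable than the observed one.

Per-assay fold-change/significance cutoffs reproduce the study design:
log2FC >= 1 for H3K4me3 and H3K9me3, >= 2 for the other three histone marks
and MeDIP, >= 0.3 for RNA; alpha 0.05 except 0.01 for H3K27ac.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, _trees_by_chrom

__all__ = [
    "ASSAY_CUTOFFS",
    "count_in_windows",
    "exact_count_test",
    "log2_fold_change",
    "adjust_pvalues",
    "differential_table",
    "classify_calls",
    "read_count_table",
    "write_count_table",
]

# assay -> (|log2FC| cutoff, significance level)
ASSAY_CUTOFFS: dict[str, tuple[float, float]] = {
    "H3K4me3": (1.0, 0.05),
    "H3K9me3": (1.0, 0.05),
    "H3K27me3": (2.0, 0.05),
    "H3K36me3": (2.0, 0.05),
    "H3K27ac": (2.0, 0.01),
    "MeDIP": (2.0, 0.05),
    "RNA": (0.3, 0.05),
}


def count_in_windows(
    reads: Sequence[GenomicInterval],
    windows: Mapping[str, Sequence[GenomicInterval]],
) -> pd.Series:
    """Count reads into per-feature window unions by any-overlap.

    ``windows`` maps a feature id to the list of intervals forming its window
    (e.g. promoter alone, or promoter plus gene body for a transcription-body
    mark). A read overlapping any base of any piece increments the feature
    once; a read spanning two features increments both.
    """
    pieces: list[GenomicInterval] = []
    owners: list[str] = []
    for feature, ivs in windows.items():
        for iv in ivs:
            pieces.append(iv)
            owners.append(feature)
    trees = _trees_by_chrom(pieces)
    counts = {feature: 0 for feature in windows}
    for r in reads:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        hit_features = {owners[h.data] for h in tree.overlap(r.start, r.end)}
        for f in hit_features:
            counts[f] += 1
    return pd.Series(counts, name="count")


def _common_library_counts(
    a: int, b: int, lib_a: float, lib_b: float
) -> tuple[int, int, float]:
    """Rescale both counts to the geometric-mean library size.

    Quantile adjustment is approximated by deterministic proportional
    rescaling with round-half-even.
    """
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be > 0")
    common = float(np.sqrt(lib_a * lib_b))
    a_adj = int(np.round(a * common / lib_a))
    b_adj = int(np.round(b * common / lib_b))
    return a_adj, b_adj, common


def _conditional_weights(n: int, dispersion: float) -> np.ndarray:
    """P(A = k | A + B = n) for k = 0..n under the symmetric conditional law.

    dispersion == 0: Binomial(n, 1/2). dispersion > 0: joint negative-binomial
    enumeration — the conditional law is free of the common mean, so any
    positive mean gives the same normalized weights.
    """
    k = np.arange(n + 1)
    if dispersion == 0:
        return stats.binom.pmf(k, n, 0.5)
    r = 1.0 / dispersion
    mu = max(n / 2.0, 1.0)
    p = r / (r + mu)
    logw = stats.nbinom.logpmf(k, r, p) + stats.nbinom.logpmf(n - k, r, p)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def exact_count_test(
    a: int,
    b: int,
    lib_a: float = 1.0,
    lib_b: float = 1.0,
    dispersion: float = 0.0,
) -> float:
    """Two-sided exact p-value for a difference between two counts.

    Counts are first rescaled to the common library size; the p-value is the
    total conditional probability of all splits of the (rescaled) sum that are
    no more probable than the observed split. ``a = b = 0`` returns 1 by
    convention.
    """
    if a < 0 or b < 0:
        raise ValueError("counts must be >= 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    a_adj, b_adj, _ = _common_library_counts(a, b, lib_a, lib_b)
    n = a_adj + b_adj
    if n == 0:
        return 1.0
    w = _conditional_weights(n, dispersion)
    observed = w[a_adj]
    p = float(w[w <= observed * (1 + 1e-12)].sum())
    return min(1.0, p)


def log2_fold_change(
    a: float,
    b: float,
    lib_a: float = 1.0,
    lib_b: float = 1.0,
    pseudocount: float = 1.0,
) -> float:
    """log2 ratio of library-normalized counts with a pseudocount.

    The pseudocount is scaled to the common (geometric-mean) library so the
    value is antisymmetric under swapping conditions.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    common = float(np.sqrt(lib_a * lib_b))
    eps = pseudocount / common
    return float(np.log2((a / lib_a + eps) / (b / lib_b + eps)))


def adjust_pvalues(pvalues: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` or ``BH`` step-up."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must be in [0, 1]")
    key = {"bonferroni": "bonferroni", "BH": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def differential_table(
    counts_a: pd.Series,
    counts_b: pd.Series,
    lib_a: float,
    lib_b: float,
    dispersion: float = 0.0,
    pseudocount: float = 1.0,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Per-feature exact tests, fold changes and adjusted p-values.

    Returns a table with columns count_a, count_b, log2fc, p, p_adj indexed by
    feature; use :func:`classify_calls` to add categorical calls.
    """
    features = counts_a.index
    if not features.equals(counts_b.index):
        counts_b = counts_b.reindex(features, fill_value=0)
    p = np.array(
        [
            exact_count_test(int(a), int(b), lib_a, lib_b, dispersion)
            for a, b in zip(counts_a.to_numpy(), counts_b.to_numpy())
        ]
    )
    lfc = np.array(
        [
            log2_fold_change(a, b, lib_a, lib_b, pseudocount)
            for a, b in zip(counts_a.to_numpy(), counts_b.to_numpy())
        ]
    )
    return pd.DataFrame(
        {
            "count_a": counts_a.to_numpy(),
            "count_b": counts_b.to_numpy(),
            "log2fc": lfc,
            "p": p,
            "p_adj": adjust_pvalues(p, adjust),
        },
        index=features,
    )


def classify_calls(
    table: pd.DataFrame,
    assay: str,
    cutoffs: Mapping[str, tuple[float, float]] | None = None,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Add the categorical call column ``{more, less, ns}`` for an assay.

    ``more`` requires log2FC >= the assay's cutoff and p below its alpha;
    ``less`` is the mirror. p defaults to the raw p-value (the study design
    thresholds raw p for these assays); set ``use_adjusted`` to threshold the
    adjusted column instead.
    """
    cutoffs = dict(ASSAY_CUTOFFS if cutoffs is None else cutoffs)
    if assay not in cutoffs:
        raise KeyError(f"unknown assay {assay!r}")
    lfc_cut, alpha = cutoffs[assay]
    p = table["p_adj"] if use_adjusted else table["p"]
    call = np.where(
        (table["log2fc"] >= lfc_cut) & (p < alpha),
        "more",
        np.where((table["log2fc"] <= -lfc_cut) & (p < alpha), "less", "ns"),
    )
    out = table.copy()
    out["call"] = call
    return out


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV count table (feature_id, count_a, count_b, lib_a, lib_b)."""
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    if df.index.has_duplicates:
        raise ValueError("duplicate feature ids")
    return df


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")
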