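"""Single-nucleus ATAC layer.

Fragment ingestion with the transposase strand shift (+4 / −5), per-cell QC
filtering, gene-activity scoring from fragment overlaps, TF-IDF/LSI
normalization of accessibility matrices, condition-wise cell-type composition
change, and per-cell-type differential gene activity by rank-sum testing.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffenrich import adjust_pvalues
from .intervals import GeneModel, _trees_by_chrom, GenomicInterval

__all__ = [
    "load_fragments",
    "write_fragments",
    "qc_filter",
    "gene_activity",
    "tfidf_lsi",
    "LSIResult",
    "composition_change",
    "differential_activity",
]

logger = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ("chrom", "start", "end", "barcode", "count")


def load_fragments(path: str | Path, apply_shift: bool = True) -> pd.DataFrame:
    """Read a fragments TSV (chrom, start, end, barcode[, count]).

    With ``apply_shift`` the start is increased by 4 and the end decreased by
    5 so both ends mark transposase cut sites; records that collapse to
    non-positive length after shifting are dropped (the count is logged).
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected >=4 tab-separated fields")
        try:
            rows.append(
                (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3],
                    int(fields[4]) if len(fields) > 4 else 1,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed fragment line") from exc
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    if (df["barcode"] == "").any():
        raise ValueError("empty barcode")
    if apply_shift:
        df["start"] += 4
        df["end"] -= 5
        bad = df["start"] >= df["end"]
        if bad.any():
            logger.info("dropped %d fragments with non-positive length after shift", bad.sum())
            df = df.loc[~bad].reset_index(drop=True)
    elif (df["start"] >= df["end"]).any():
        raise ValueError("fragment with start >= end")
    return df


def write_fragments(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def qc_filter(
    qc: pd.DataFrame,
    min_fragments: int = 200,
    max_fragments_quantile: float = 0.95,
    max_nucleosome_signal: float = 4.0,
    min_tss_enrichment: float = 2.0,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the four per-cell QC thresholds and return kept barcodes.

    A cell passes when its fragments-in-peaks count is at least
    ``min_fragments`` and at most the ``max_fragments_quantile`` quantile of
    the input distribution, its nucleosome signal is at most
    ``max_nucleosome_signal``, and its TSS enrichment is at least
    ``min_tss_enrichment``. The quantile cap is computed once on the input
    table, so the filter is idempotent and order-independent.
    """
    if qc.empty:
        raise ValueError("empty QC table")
    required = {"barcode", "fragments_in_peaks", "nucleosome_signal", "tss_enrichment"}
    missing = required - set(qc.columns)
    if missing:
        raise ValueError(f"QC table missing columns: {sorted(missing)}")
    cap = qc["fragments_in_peaks"].quantile(max_fragments_quantile)
    passed = (
        (qc["fragments_in_peaks"] >= min_fragments)
        & (qc["fragments_in_peaks"] <= cap)
        & (qc["nucleosome_signal"] <= max_nucleosome_signal)
        & (qc["tss_enrichment"] >= min_tss_enrichment)
    )
    out = qc.copy()
    out["pass"] = passed.to_numpy()
    return list(qc.loc[passed, "barcode"]), out


def gene_activity(
    fragments: pd.DataFrame,
    genes: Sequence[GeneModel],
    barcodes: Sequence[str] | None = None,
    upstream_extension: int = 2000,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-cell gene activity from fragments over extended gene bodies.

    Each gene's window is its body extended ``upstream_extension`` bases
    upstream of the TSS (strand-aware); a fragment overlapping the window by
    any base contributes one count. With ``normalize`` the counts are
    depth-scaled per cell to the median total and log1p-transformed. Cells
    with zero total activity keep an all-zero row.
    """
    if barcodes is None:
        barcodes = list(pd.unique(fragments["barcode"]))
    windows = []
    for g in genes:
        if g.strand == "+":
            lo, hi = max(0, g.tx_start - upstream_extension), g.tx_end
        else:
            lo, hi = g.tx_start, g.tx_end + upstream_extension
        windows.append(GenomicInterval(g.chrom, lo, hi, name=g.gene_id))
    trees = _trees_by_chrom(windows)
    gene_ids = [g.gene_id for g in genes]
    bc_index = {b: i for i, b in enumerate(barcodes)}
    mat = np.zeros((len(barcodes), len(genes)))
    sub = fragments[fragments["barcode"].isin(bc_index)]
    for chrom, group in sub.groupby("chrom", sort=False):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for start, end, bc in zip(group["start"], group["end"], group["barcode"]):
            for hit in tree.overlap(start, end):
                mat[bc_index[bc], hit.data] += 1
    if normalize:
        totals = mat.sum(axis=1)
        if (totals == 0).any():
            logger.info("%d cells have zero total gene activity", int((totals == 0).sum()))
        median = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
        scale = np.divide(median, totals, out=np.zeros_like(totals), where=totals > 0)
        mat = np.log1p(mat * scale[:, None])
    return pd.DataFrame(mat, index=list(barcodes), columns=gene_ids)


@dataclass
class LSIResult:
    """Output of TF-IDF/LSI: per-cell component scores and diagnostics."""

    scores: pd.DataFrame  # cells x kept components
    singular_values: np.ndarray
    depth_correlation: float  # Pearson r of component 1 with cell depth
    dropped_first_component: bool
    features: list[str]  # retained top-accessible features


def tfidf_lsi(
    matrix: pd.DataFrame,
    n_components: int = 30,
    top_feature_fraction: float = 0.25,
    depth_corr_threshold: float = 0.9,
) -> LSIResult:
    """TF-IDF normalization followed by truncated SVD (latent semantic indexing).

    TF is the per-cell frequency, IDF = n_cells / (1 + cells with signal),
    transformed as log(1 + 1e4 * TF * IDF). Features are ranked by overall
    accessibility and the top fraction retained before the SVD. The first
    component's correlation with cell depth is reported and the component
    dropped when it exceeds the threshold in magnitude (it then tracks
    sequencing depth rather than biology).
    """
    X = matrix.to_numpy(dtype=float)
    if X.min() < 0:
        raise ValueError("matrix must be nonnegative")
    depth = X.sum(axis=1)
    if not depth.any():
        raise ValueError("all-zero matrix")

    order = np.argsort(-X.sum(axis=0), kind="stable")
    n_keep = max(1, int(np.ceil(top_feature_fraction * X.shape[1])))
    keep = np.sort(order[:n_keep])
    features = [matrix.columns[j] for j in keep]
    Xk = X[:, keep]

    totals = Xk.sum(axis=1, keepdims=True)
    tf = np.divide(Xk, totals, out=np.zeros_like(Xk), where=totals > 0)
    idf = X.shape[0] / (1 + (Xk > 0).sum(axis=0))
    Z = np.log1p(1e4 * tf * idf)

    n_components = min(n_components, min(Z.shape))
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # deterministic sign convention: make each component's largest loading positive
    signs = np.sign(Vt[np.arange(n_components), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1
    scores = U * s * signs

    with np.errstate(invalid="ignore"):
        r = float(np.corrcoef(scores[:, 0], depth)[0, 1]) if len(depth) > 1 else 0.0
    drop_first = bool(np.isfinite(r) and abs(r) > depth_corr_threshold)
    kept = scores[:, 1:] if drop_first else scores
    cols = [f"LSI{i + (2 if drop_first else 1)}" for i in range(kept.shape[1])]
    return LSIResult(
        scores=pd.DataFrame(kept, index=matrix.index, columns=cols),
        singular_values=s,
        depth_correlation=r,
        dropped_first_component=drop_first,
        features=features,
    )


def composition_change(
    cell_types: Sequence[str],
    conditions: Sequence[str],
    baseline: str,
    treatment: str,
) -> pd.DataFrame:
    """Per-type shares (%) in each condition and the relative change.

    share(type, condition) = 100 * cells of that type / cells in the
    condition; relative change = 100 * (share_treatment − share_baseline) /
    share_baseline. A type absent from the baseline yields NaN change.
    """
    df = pd.DataFrame({"cell_type": list(cell_types), "condition": list(conditions)})
    present = set(df["condition"])
    if baseline not in present or treatment not in present:
        raise ValueError("both conditions must be present")
    shares = (
        df.groupby(["condition", "cell_type"]).size().unstack(fill_value=0)
    )
    shares = 100.0 * shares.div(shares.sum(axis=1), axis=0)
    out = pd.DataFrame(
        {
            "share_baseline": shares.loc[baseline],
            "share_treatment": shares.loc[treatment],
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        change = 100.0 * (out["share_treatment"] - out["share_baseline"]) / out["share_baseline"]
    out["relative_change_pct"] = change.where(out["share_baseline"] > 0)
    out.index.name = "cell_type"
    return out


def differential_activity(
    matrix: pd.DataFrame,
    cell_types: Mapping[str, str] | pd.Series,
    conditions: Mapping[str, str] | pd.Series,
    cell_type: str,
    baseline: str,
    treatment: str,
    alpha: float = 0.05,
    adjust: str = "BH",
) -> pd.DataFrame:
    """Per-gene rank-sum test between conditions within one cell type.

    Uses the two-sample Wilcoxon rank-sum (Mann-Whitney) test per gene, BH
    adjustment across genes, and calls up/down by the sign of the median
    difference (treatment − baseline) when the adjusted p is below ``alpha``.
    A gene constant across both groups gets p = 1 by convention.
    """
    cell_types = pd.Series(cell_types)
    conditions = pd.Series(conditions)
    cells = matrix.index
    in_type = cells[(cell_types.reindex(cells) == cell_type).to_numpy()]
    grp_a = [c for c in in_type if conditions[c] == baseline]
    grp_b = [c for c in in_type if conditions[c] == treatment]
    if len(grp_a) < 3 or len(grp_b) < 3:
        raise ValueError("need >=3 cells per condition within the cell type")
    A = matrix.loc[grp_a].to_numpy()
    B = matrix.loc[grp_b].to_numpy()

    pvals = np.ones(matrix.shape[1])
    med_diff = np.median(B, axis=0) - np.median(A, axis=0)
    for j in range(matrix.shape[1]):
        a, b = A[:, j], B[:, j]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            continue  # constant gene: p = 1 by convention
        pvals[j] = stats.mannwhitneyu(b, a, alternative="two-sided").pvalue
    p_adj = adjust_pvalues(pvals, adjust)
    call = np.where(
        (p_adj < alpha) & (med_diff > 0),
        "up",
        np.where((p_adj < alpha) & (med_diff < 0), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "statistic": med_diff,
            "p": pvals,
            "p_adj": p_adj,
            "call": call,
        },
        index=matrix.columns,
    )
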