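"""Chromatin-state segmentation from binarized histone marks.

A hidden Markov chain over fixed-size genome bins with independent Bernoulli
emissions per mark, fitted by Baum–Welch EM, plus the annotation statistics
that characterize each state: genome coverage, TSS-neighborhood enrichment,
annotation overlap enrichment and methylation-peak coverage per state.

Chromosomes are treated as independent sequences; there is no wrap-around.
Decoding defaults to posterior marginals (per-bin annotation questions are
posterior-mass questions); Viterbi is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .intervals import (
    GenomeDescription,
    GenomicInterval,
    GeneModel,
    bin_genome,
    coverage_fraction,
    merge_intervals,
)

__all__ = [
    "BinnedMarkMatrix",
    "BinarizationModel",
    "ChromatinStateModel",
    "StatePath",
    "poisson_threshold",
    "count_reads_in_bins",
    "binarize_bins",
    "fit_state_model",
    "decode_states",
    "state_genome_fractions",
    "tss_neighborhood_enrichment",
    "annotation_overlap_enrichment",
    "state_methylation_levels",
]

DEFAULT_MARKS = ("H3K4me3", "H3K27ac", "H3K9me3", "H3K27me3", "H3K36me3")

# marks whose joint emission defines the "active-promoter-like" end of the
# deterministic state relabeling
ACTIVE_MARKS = ("H3K4me3", "H3K27ac")

PROB_FLOOR = 1e-6


@dataclass
class BinnedMarkMatrix:
    """Ordered genome bins × marks with binary occupancy values."""

    bins: list[GenomicInterval]
    marks: tuple[str, ...]
    values: np.ndarray  # (n_bins, n_marks) in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.bins), len(self.marks)):
            raise ValueError("values shape does not match bins x marks")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("values must be binary")

    def sequence_slices(self) -> list[slice]:
        """One slice per chromosome (bins are contiguous per chromosome)."""
        slices = []
        start = 0
        for i in range(1, len(self.bins) + 1):
            if i == len(self.bins) or self.bins[i].chrom != self.bins[start].chrom:
                slices.append(slice(start, i))
                start = i
        return slices


@dataclass(frozen=True)
class BinarizationModel:
    """Per-mark Poisson background model for binarizing bin counts.

    A bin is called present for a mark when its read count reaches the
    smallest integer c* with P(Poisson(lambda) >= c*) <= alpha.
    """

    lam: Mapping[str, float]
    alpha: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for mark, lam in self.lam.items():
            if lam <= 0:
                raise ValueError(f"{mark}: lambda must be > 0")

    def threshold(self, mark: str) -> int:
        return poisson_threshold(self.lam[mark], self.alpha)


def poisson_threshold(lam: float, alpha: float) -> int:
    """Smallest integer c >= 1 with P(Poisson(lam) >= c) <= alpha."""
    c = max(1, int(stats.poisson.isf(alpha, lam)))
    while stats.poisson.sf(c - 1, lam) > alpha:
        c += 1
    while c > 1 and stats.poisson.sf(c - 2, lam) <= alpha:
        c -= 1
    return c


def count_reads_in_bins(
    reads: Iterable[GenomicInterval],
    genome: GenomeDescription,
    bin_size: int,
) -> tuple[list[GenomicInterval], np.ndarray]:
    """Count reads into fixed-size bins by any-overlap.

    A read overlapping several bins increments each of them. Returns the bin
    list (ordered as :func:`bin_genome`) and the per-bin count vector.
    """
    bins = bin_genome(genome, bin_size)
    offsets = {}
    pos = 0
    for chrom, length in genome.items():
        offsets[chrom] = pos
        pos += -(-length // bin_size)
    counts = np.zeros(len(bins), dtype=np.int64)
    for r in reads:
        if r.chrom not in offsets:
            continue
        length = genome[r.chrom]
        first = min(r.start, length - 1) // bin_size
        last = (min(r.end, length) - 1) // bin_size
        counts[offsets[r.chrom] + first : offsets[r.chrom] + last + 1] += 1
    return bins, counts


def binarize_bins(
    counts: np.ndarray,
    bins: Sequence[GenomicInterval],
    marks: Sequence[str],
    model: BinarizationModel | None = None,
    alpha: float = 1e-4,
) -> BinnedMarkMatrix:
    """Binarize a (bins × marks) count matrix against a Poisson background.

    With no explicit model, each mark's background rate defaults to its
    genome-wide mean count per bin.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape != (len(bins), len(marks)):
        raise ValueError("counts must be (n_bins, n_marks)")
    if (counts < 0).any():
        raise ValueError("negative counts")
    if model is None:
        lam = {m: max(float(counts[:, j].mean()), 1e-12) for j, m in enumerate(marks)}
        model = BinarizationModel(lam, alpha)
    thresholds = np.array([model.threshold(m) for m in marks])
    return BinnedMarkMatrix(list(bins), tuple(marks), (counts >= thresholds).astype(np.uint8))


# ---------------------------------------------------------------------------
# Baum-Welch EM for the Bernoulli-emission hidden Markov chain
# ---------------------------------------------------------------------------

@dataclass
class ChromatinStateModel:
    """Fitted hidden-state model: initial/transition/emission parameters."""

    n_states: int
    marks: tuple[str, ...]
    initial: np.ndarray  # (K,)
    transition: np.ndarray  # (K, K)
    emission: np.ndarray  # (K, M) Bernoulli success probabilities
    log_likelihood: float = np.nan
    converged: bool = True
    log_likelihood_history: list[float] = field(default_factory=list)

    @property
    def state_labels(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_states)]

    def validate(self) -> None:
        if abs(self.initial.sum() - 1) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if np.abs(self.transition.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("transition rows must sum to 1")
        if ((self.emission < 0) | (self.emission > 1)).any():
            raise ValueError("emission probabilities must be in [0, 1]")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"n_states\t{self.n_states}\n")
            fh.write("marks\t" + "\t".join(self.marks) + "\n")
            fh.write("initial\t" + "\t".join(f"{x:.10g}" for x in self.initial) + "\n")
            for i in range(self.n_states):
                fh.write(
                    f"transition_S{i + 1}\t"
                    + "\t".join(f"{x:.10g}" for x in self.transition[i])
                    + "\n"
                )
            for i in range(self.n_states):
                fh.write(
                    f"emission_S{i + 1}\t"
                    + "\t".join(f"{x:.10g}" for x in self.emission[i])
                    + "\n"
                )


@dataclass
class StatePath:
    """Per-bin state assignment with contiguous same-state segments."""

    bins: list[GenomicInterval]
    states: np.ndarray  # (n_bins,) int
    n_states: int

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if len(self.states) != len(self.bins):
            raise ValueError("path length must equal bin count")

    def segments(self) -> list[tuple[GenomicInterval, int]]:
        """Maximal runs of the same state on the same chromosome."""
        segs = []
        start = 0
        for i in range(1, len(self.bins) + 1):
            boundary = (
                i == len(self.bins)
                or self.bins[i].chrom != self.bins[start].chrom
                or self.states[i] != self.states[start]
            )
            if boundary:
                segs.append(
                    (
                        GenomicInterval(
                            self.bins[start].chrom,
                            self.bins[start].start,
                            self.bins[i - 1].end,
                        ),
                        int(self.states[start]),
                    )
                )
                start = i
        return segs

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv, s in self.segments():
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tS{s + 1}\n")


@njit(cache=True)
def _forward_backward(emit, A, pi):  # pragma: no cover - exercised via fit/decode
    """Scaled forward-backward. Returns (gamma, xi_sum, first_gamma, loglik)."""
    T, K = emit.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    scale = np.empty(T)

    for k in range(K):
        alpha[0, k] = pi[k] * emit[0, k]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, T):
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * A[j, k]
            alpha[t, k] = acc * emit[t, k]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]

    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += A[k, j] * emit[t + 1, j] * beta[t + 1, j]
            beta[t, k] = acc / scale[t + 1]

    gamma = alpha * beta
    for t in range(T):
        gamma[t] /= gamma[t].sum()

    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        denom = 0.0
        for j in range(K):
            for k in range(K):
                denom += alpha[t, j] * A[j, k] * emit[t + 1, k] * beta[t + 1, k]
        for j in range(K):
            for k in range(K):
                xi_sum[j, k] += alpha[t, j] * A[j, k] * emit[t + 1, k] * beta[t + 1, k] / denom

    loglik = np.log(scale).sum()
    return gamma, xi_sum, gamma[0].copy(), loglik


@njit(cache=True)
def _viterbi(log_emit, log_A, log_pi):  # pragma: no cover
    T, K = log_emit.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    delta[0] = log_pi + log_emit[0]
    for t in range(1, T):
        for k in range(K):
            best, arg = -np.inf, 0
            for j in range(K):
                v = delta[t - 1, j] + log_A[j, k]
                if v > best:
                    best, arg = v, j
            delta[t, k] = best + log_emit[t, k]
            psi[t, k] = arg
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta[T - 1])
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _emission_probs(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-bin likelihood of the observed mark vector under each state."""
    logB = np.log(np.clip(B, PROB_FLOOR, 1 - PROB_FLOOR))
    log1mB = np.log(np.clip(1 - B, PROB_FLOOR, 1 - PROB_FLOOR))
    return np.exp(X @ logB.T + (1 - X) @ log1mB.T)


def fit_state_model(
    matrix: BinnedMarkMatrix,
    n_states: int = 6,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
    active_marks: Sequence[str] = ACTIVE_MARKS,
) -> ChromatinStateModel:
    """Fit the Bernoulli-emission hidden Markov chain by Baum–Welch EM.

    Runs ``n_restarts`` EM fits from random starts and keeps the one with the
    highest log-likelihood. The per-iteration log-likelihood is non-decreasing
    (EM guarantee); iteration stops when the relative improvement drops below
    ``tol``. Emission and transition parameters are floored at 1e-6 so no
    state becomes absorbing or deterministic.

    States are then relabeled deterministically so that S1 is the most
    "active-promoter-like": states are sorted by descending summed emission of
    the ``active_marks`` (falling back to total emission when none of those
    marks are present), ties broken by descending genome coverage.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    X = matrix.values.astype(np.float64)
    T, M = X.shape
    if T == 0:
        raise ValueError("empty matrix")
    n_patterns = len({tuple(row) for row in matrix.values})
    if n_states > n_patterns:
        import warnings

        warnings.warn(
            f"n_states={n_states} exceeds the {n_patterns} distinct emission "
            "patterns present; some states may be redundant",
            stacklevel=2,
        )
    slices = matrix.sequence_slices()
    rng = np.random.default_rng(seed)

    best: ChromatinStateModel | None = None
    for _ in range(max(1, n_restarts)):
        pi = rng.dirichlet(np.ones(n_states))
        A = rng.dirichlet(np.ones(n_states) * 2, size=n_states)
        A = 0.8 * np.eye(n_states) + 0.2 * A  # self-loop-heavy starting point
        A /= A.sum(axis=1, keepdims=True)
        B = rng.uniform(0.2, 0.8, size=(n_states, M))

        history: list[float] = []
        converged = False
        for _iter in range(max_iter):
            emit = _emission_probs(X, B)
            gamma_sum = np.zeros(n_states)
            gamma_x = np.zeros((n_states, M))
            xi_total = np.zeros((n_states, n_states))
            pi_acc = np.zeros(n_states)
            loglik = 0.0
            gammas = np.empty((T, n_states))
            for sl in slices:
                gamma, xi_sum, first, ll = _forward_backward(
                    emit[sl], A, pi
                )
                gammas[sl] = gamma
                gamma_sum += gamma.sum(axis=0)
                gamma_x += gamma.T @ X[sl]
                xi_total += xi_sum
                pi_acc += first
                loglik += ll
            history.append(loglik)

            pi = np.clip(pi_acc / len(slices), PROB_FLOOR, None)
            pi /= pi.sum()
            A = np.clip(xi_total, PROB_FLOOR, None)
            A /= A.sum(axis=1, keepdims=True)
            B = np.clip(gamma_x / gamma_sum[:, None], PROB_FLOOR, 1 - PROB_FLOOR)

            if len(history) > 1:
                prev, cur = history[-2], history[-1]
                if abs(cur - prev) <= tol * abs(prev):
                    converged = True
                    break

        model = ChromatinStateModel(
            n_states=n_states,
            marks=matrix.marks,
            initial=pi,
            transition=A,
            emission=B,
            log_likelihood=history[-1],
            converged=converged,
            log_likelihood_history=history,
        )
        model._coverage = gammas.sum(axis=0)  # for the relabeling tie-break
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model

    return _relabel(best, active_marks)


def _relabel(model: ChromatinStateModel, active_marks: Sequence[str]) -> ChromatinStateModel:
    idx = [model.marks.index(m) for m in active_marks if m in model.marks]
    if idx:
        activity = model.emission[:, idx].sum(axis=1)
    else:
        activity = model.emission.sum(axis=1)
    coverage = getattr(model, "_coverage", np.zeros(model.n_states))
    order = sorted(
        range(model.n_states), key=lambda k: (-activity[k], -coverage[k], k)
    )
    perm = np.array(order)
    model.initial = model.initial[perm]
    model.transition = model.transition[np.ix_(perm, perm)]
    model.emission = model.emission[perm]
    return model


def decode_states(
    model: ChromatinStateModel,
    matrix: BinnedMarkMatrix,
    method: str = "posterior",
) -> StatePath:
    """Per-bin state assignment by posterior marginals (default) or Viterbi.

    Posterior ties break toward the lower state index.
    """
    if tuple(model.marks) != tuple(matrix.marks):
        raise ValueError("model marks do not match matrix marks")
    X = matrix.values.astype(np.float64)
    states = np.empty(len(matrix.bins), dtype=np.int64)
    emit = _emission_probs(X, model.emission)
    for sl in matrix.sequence_slices():
        if method == "posterior":
            gamma, _, _, _ = _forward_backward(emit[sl], model.transition, model.initial)
            states[sl] = np.argmax(gamma, axis=1)
        elif method == "viterbi":
            states[sl] = _viterbi(
                np.log(np.clip(emit[sl], 1e-300, None)),
                np.log(np.clip(model.transition, PROB_FLOOR, None)),
                np.log(np.clip(model.initial, PROB_FLOOR, None)),
            )
        else:
            raise ValueError(f"unknown decoding method {method!r}")
    return StatePath(matrix.bins, states, model.n_states)


def posterior_marginals(model: ChromatinStateModel, matrix: BinnedMarkMatrix) -> np.ndarray:
    """Per-bin posterior state probabilities (n_bins × K)."""
    if tuple(model.marks) != tuple(matrix.marks):
        raise ValueError("model marks do not match matrix marks")
    X = matrix.values.astype(np.float64)
    emit = _emission_probs(X, model.emission)
    out = np.empty((len(matrix.bins), model.n_states))
    for sl in matrix.sequence_slices():
        gamma, _, _, _ = _forward_backward(emit[sl], model.transition, model.initial)
        out[sl] = gamma
    return out


# ---------------------------------------------------------------------------
# State annotation statistics
# ---------------------------------------------------------------------------

def state_genome_fractions(path: StatePath) -> np.ndarray:
    """Base-weighted percentage of the genome occupied by each state (sums to 100)."""
    if len(path.bins) == 0:
        raise ValueError("empty path")
    lengths = np.array([len(b) for b in path.bins], dtype=np.float64)
    totals = np.bincount(path.states, weights=lengths, minlength=path.n_states)
    return 100.0 * totals / lengths.sum()


def tss_neighborhood_enrichment(
    path: StatePath,
    genes: Sequence[GeneModel],
    window: int = 2000,
    step: int = 200,
) -> pd.DataFrame:
    """State × offset fold enrichment in the TSS neighborhood.

    Offsets tile [−window, +window) in ``step``-sized bins, oriented along the
    direction of transcription. The fold for state s at offset o is
    P(state = s | offset bin o) / P(state = s genome-wide, base-weighted).
    Offset bins falling outside chromosome bounds are skipped.
    """
    if not genes:
        raise ValueError("no genes supplied")
    bin_size = len(path.bins[0])
    chrom_index: dict[str, tuple[int, int]] = {}
    start = 0
    for sl_start, sl_end in _chrom_runs(path.bins):
        chrom_index[path.bins[sl_start].chrom] = (sl_start, sl_end)
        start = sl_end

    offsets = np.arange(-window, window, step)
    counts = np.zeros((path.n_states, len(offsets)), dtype=np.float64)
    totals = np.zeros(len(offsets), dtype=np.float64)
    for g in genes:
        if g.chrom not in chrom_index:
            continue
        lo, hi = chrom_index[g.chrom]
        sign = 1 if g.strand == "+" else -1
        for j, off in enumerate(offsets):
            # midpoint of the offset bin, mapped along the strand
            pos = g.tss + sign * (off + step // 2)
            if pos < 0:
                continue
            idx = lo + pos // bin_size
            if idx >= hi:
                continue
            counts[path.states[idx], j] += 1
            totals[j] += 1

    genome_frac = state_genome_fractions(path) / 100.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = (counts / totals[None, :]) / genome_frac[:, None]
    return pd.DataFrame(
        fold, index=[f"S{i + 1}" for i in range(path.n_states)], columns=offsets
    )


def _chrom_runs(bins: Sequence[GenomicInterval]) -> list[tuple[int, int]]:
    runs = []
    start = 0
    for i in range(1, len(bins) + 1):
        if i == len(bins) or bins[i].chrom != bins[start].chrom:
            runs.append((start, i))
            start = i
    return runs


def annotation_overlap_enrichment(
    path: StatePath,
    annotations: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """State × annotation fold enrichment.

    fold = (fraction of the state's bases inside the annotation) /
    (fraction of the genome inside the annotation). An annotation covering
    zero bases yields NaN for every state.
    """
    segs = path.segments()
    state_bases = np.zeros(path.n_states)
    for iv, s in segs:
        state_bases[s] += len(iv)
    genome_bases = state_bases.sum()

    result = {}
    for name, ivs in annotations.items():
        merged = {
            chrom: merge_intervals(
                [(iv.start, iv.end) for iv in ivs if iv.chrom == chrom]
            )
            for chrom in {iv.chrom for iv in ivs}
        }
        anno_total = sum(e - s for spans in merged.values() for s, e in spans)
        if anno_total == 0:
            result[name] = np.full(path.n_states, np.nan)
            continue
        in_state = np.zeros(path.n_states)
        for iv, s in segs:
            for a_start, a_end in merged.get(iv.chrom, ()):
                ov = min(iv.end, a_end) - max(iv.start, a_start)
                if ov > 0:
                    in_state[s] += ov
        with np.errstate(invalid="ignore", divide="ignore"):
            result[name] = (in_state / state_bases) / (anno_total / genome_bases)
    return pd.DataFrame(result, index=[f"S{i + 1}" for i in range(path.n_states)])


def state_methylation_levels(
    path: StatePath,
    medip_peaks: Sequence[GenomicInterval],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Methylation-peak coverage of each contiguous chromatin-state segment.

    The unit of observation is the contiguous same-state segment. For each
    segment the fraction of bases covered by the (merged) methylation peaks is
    computed; a segment counts as overlapped when that fraction is positive.
    Returns (per-segment table, per-state summary) where the summary carries
    segment counts, overlapped-segment counts and boxplot five-number
    statistics (median, quartiles, whiskers at 1.5× the interquartile range).
    """
    rows = []
    for iv, s in path.segments():
        frac = coverage_fraction(iv, medip_peaks)
        rows.append((iv.chrom, iv.start, iv.end, f"S{s + 1}", s, frac))
    per_segment = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "state", "state_index", "fraction"]
    )

    summaries = []
    for s in range(path.n_states):
        fr = per_segment.loc[per_segment.state_index == s, "fraction"].to_numpy()
        if fr.size == 0:
            summaries.append((f"S{s + 1}", 0, 0, *([np.nan] * 5)))
            continue
        q1, med, q3 = np.percentile(fr, [25, 50, 75])
        iqr = q3 - q1
        lo = fr[fr >= q1 - 1.5 * iqr].min()
        hi = fr[fr <= q3 + 1.5 * iqr].max()
        summaries.append((f"S{s + 1}", fr.size, int((fr > 0).sum()), med, q1, q3, lo, hi))
    summary = pd.DataFrame(
        summaries,
        columns=[
            "state",
            "n_segments",
            "n_overlapped",
            "median",
            "q1",
            "q3",
            "whisker_lo",
            "whisker_hi",
        ],
    )
    return per_segment, summary
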