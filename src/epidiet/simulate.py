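"""Synthetic-data generator for the whole pipeline, with planted ground truth.

Every input the analysis consumes can be generated here: a toy genome with
genes and TSSs, a hidden chromatin-state path over fixed-size bins emitting
binary histone marks, per-condition mark reads and promoter count tables with
planted log2 fold changes, methylation peaks concentrated on chosen states,
and single-nucleus ATAC fragments with cell-type labels, QC covariates and
condition-dependent composition. All generators are deterministic under the
configured seed, and each emits a machine-readable truth sidecar so that
downstream recovery tests never re-derive the truth.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chromstate import BinnedMarkMatrix, StatePath, DEFAULT_MARKS
from .intervals import (
    GenomeDescription,
    GenomicInterval,
    GeneModel,
    bin_genome,
    make_promoters,
)

__all__ = [
    "SimulationConfig",
    "make_toy_genome",
    "simulate_state_path_and_marks",
    "simulate_mark_reads",
    "simulate_medip_peaks",
    "simulate_atac",
    "MarkReadSimulation",
    "AtacSimulation",
]

DEFAULT_CONDITIONS = ("Chow-3M", "HFD-1M", "HFD-3M", "Chow-6M", "HFD-6M")

CELL_TYPES = (
    "excitatory_neuron",
    "inhibitory_neuron",
    "astrocyte",
    "microglia",
    "oligodendrocyte",
    "OPC",
    "endothelial",
)

# hypothalamic composition (%) under chow feeding and after 1 month of HFD;
# chow shares follow the field's reported make-up, the HFD vector applies the
# reported relative shifts (excitatory +67.8%, oligodendrocyte +20.7%,
# astrocyte -57.6%) and renormalizes
_CHOW_SHARES = np.array([5.9, 51.0, 12.5, 4.4, 22.2, 3.6, 0.4])
_HFD_SHARES = _CHOW_SHARES * np.array([1.678, 1.0, 0.424, 1.0, 1.207, 1.0, 1.0])


def _default_emission() -> np.ndarray:
    # rows: S1 active TSS, S2 flanking/enhancer, S3 bivalent, S4 repressed,
    # S5/S6 quiescent; columns: H3K4me3, H3K27ac, H3K9me3, H3K27me3, H3K36me3
    return np.array(
        [
            [0.90, 0.85, 0.05, 0.05, 0.10],
            [0.10, 0.80, 0.05, 0.05, 0.30],
            [0.70, 0.10, 0.60, 0.65, 0.10],
            [0.05, 0.05, 0.55, 0.45, 0.05],
            [0.02, 0.02, 0.05, 0.05, 0.02],
            [0.01, 0.01, 0.01, 0.01, 0.01],
        ]
    )


def _default_transition() -> np.ndarray:
    diag = np.array([0.90, 0.90, 0.90, 0.90, 0.985, 0.985])
    K = len(diag)
    A = np.empty((K, K))
    for i in range(K):
        A[i] = (1 - diag[i]) / (K - 1)
        A[i, i] = diag[i]
    return A


def _default_initial() -> np.ndarray:
    return np.array([0.04, 0.04, 0.04, 0.04, 0.42, 0.42])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults emulate the study design.

    The five marks, five feeding conditions, 200-bp bins, six hidden states
    with quiescent-dominated coverage, negative-binomial promoter counts with
    planted log2 fold changes on the activating marks, methylation peaks
    biased toward marked states, and a two-condition snATAC layer with the
    reported hypothalamic cell-type composition and its HFD shifts.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 200_000
    n_genes: int = 60
    bin_size: int = 200
    marks: tuple[str, ...] = DEFAULT_MARKS
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    baseline_condition: str = "Chow-3M"
    # hidden-state model
    initial: np.ndarray = field(default_factory=_default_initial)
    transition: np.ndarray = field(default_factory=_default_transition)
    emission: np.ndarray = field(default_factory=_default_emission)
    # differential plant
    planted_fraction: float = 0.2
    planted_log2fc: float = 3.0
    planted_marks: tuple[str, ...] = ("H3K4me3", "H3K27ac")
    planted_log2fc_by_condition: Mapping[str, float] | None = None
    # count model
    mean_depth: float = 50.0
    dispersion: float = 0.05
    read_length: int = 100
    background_reads: int = 20_000
    # methylation peaks
    medip_affinity: tuple[float, ...] = (1.0, 0.5, 1.0, 0.8, 0.05, 0.05)
    n_medip_peaks: int = 400
    medip_peak_width: int = 400
    # snATAC layer
    atac_conditions: tuple[str, str] = ("Chow-3M", "HFD-1M")
    cell_types: tuple[str, ...] = CELL_TYPES
    composition: Mapping[str, np.ndarray] | None = None
    n_cells_per_condition: int = 2000
    frag_log_mean: float = float(np.log(600.0))
    frag_log_sigma: float = 0.6
    nucleosome_shape: float = 4.0
    nucleosome_scale: float = 0.5
    tss_shape: float = 6.0
    tss_scale: float = 1.0
    marker_boost: float = 5.0
    atac_condition_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        if abs(self.initial.sum() - 1) > 1e-9:
            raise ValueError("initial distribution must sum to 1")
        if np.abs(self.transition.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("transition rows must sum to 1")
        if ((self.emission < 0) | (self.emission > 1)).any():
            raise ValueError("emission probabilities must be in [0, 1]")
        if self.emission.shape != (self.n_states, len(self.marks)):
            raise ValueError("emission must be (n_states, n_marks)")
        if self.dispersion < 0 or self.mean_depth < 0:
            raise ValueError("rates must be >= 0")
        if self.composition is None:
            chow, hfd = self.atac_conditions
            self.composition = {
                chow: _CHOW_SHARES / _CHOW_SHARES.sum(),
                hfd: _HFD_SHARES / _HFD_SHARES.sum(),
            }
        for cond, vec in self.composition.items():
            vec = np.asarray(vec, dtype=float)
            if abs(vec.sum() - 1) > 1e-9:
                raise ValueError(f"composition for {cond} must sum to 1")
            self.composition[cond] = vec  # type: ignore[index]

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def hfd_conditions(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if c.startswith("HFD"))

    def marker_genes(self, genes: Sequence[GeneModel]) -> dict[str, str]:
        """One marker gene per cell type (the first genes, in order)."""
        if len(genes) < len(self.cell_types):
            raise ValueError("need at least one gene per cell type for markers")
        return {t: genes[i].gene_id for i, t in enumerate(self.cell_types)}


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# genome and genes
# ---------------------------------------------------------------------------

def make_toy_genome(
    config: SimulationConfig,
) -> tuple[GenomeDescription, list[GeneModel]]:
    """A toy genome with evenly spaced genes whose promoters do not overlap.

    TSS positions are aligned to bin boundaries; strands are sampled 50/50.
    Raises if the requested genes cannot be packed with non-overlapping
    2-kb promoters.
    """
    if config.chrom_length < 10 * config.bin_size:
        raise ValueError("chromosome length must be >= 10 bins")
    genome = GenomeDescription(
        [(f"chr{i + 1}", config.chrom_length) for i in range(config.n_chroms)]
    )
    rng = _rng(config, 1)
    genes: list[GeneModel] = []
    if config.n_genes == 0:
        return genome, genes
    per_chrom = -(-config.n_genes // config.n_chroms)
    spacing = config.chrom_length // per_chrom
    if spacing < 4400:
        raise ValueError("cannot pack genes with non-overlapping promoters")
    body_max = min(4000, spacing - 4400)
    body_max = max(config.bin_size, body_max - body_max % config.bin_size)
    gi = 0
    for chrom in genome.chroms:
        for j in range(per_chrom):
            if gi >= config.n_genes:
                break
            anchor = (j * spacing + spacing // 2) // config.bin_size * config.bin_size
            strand = "+" if rng.random() < 0.5 else "-"
            n_body_bins = int(rng.integers(body_max // config.bin_size // 2 + 1,
                                           body_max // config.bin_size + 1))
            body = n_body_bins * config.bin_size
            if strand == "+":
                tx_start, tx_end = anchor, anchor + body
            else:
                tx_start, tx_end = anchor - body, anchor
            # two exon blocks at the transcript ends
            exon = max(config.bin_size // 2, body // 5)
            exons = ((tx_start, tx_start + exon), (tx_end - exon, tx_end))
            if exons[0][1] > exons[1][0]:
                exons = ((tx_start, tx_end),)
            genes.append(
                GeneModel(f"gene{gi:04d}", chrom, strand, tx_start, tx_end, exons)
            )
            gi += 1
    for g in genes:
        if g.tx_start < 0 or g.tx_end > genome[g.chrom]:
            raise ValueError("infeasible gene packing")
    return genome, genes


# ---------------------------------------------------------------------------
# hidden states and marks
# ---------------------------------------------------------------------------

def simulate_state_path_and_marks(
    config: SimulationConfig,
    genome: GenomeDescription | None = None,
) -> tuple[StatePath, BinnedMarkMatrix]:
    """Sample the hidden state path (first-order Markov chain per chromosome)
    and the binary mark matrix (Bernoulli emissions per state)."""
    if genome is None:
        genome = GenomeDescription(
            [(f"chr{i + 1}", config.chrom_length) for i in range(config.n_chroms)]
        )
    bins = bin_genome(genome, config.bin_size)
    rng = _rng(config, 2)
    K = config.n_states
    cum_init = np.cumsum(config.initial)
    cum_trans = np.cumsum(config.transition, axis=1)

    states = np.empty(len(bins), dtype=np.int64)
    pos = 0
    for chrom, length in genome.items():
        n = -(-length // config.bin_size)
        u = rng.random(n)
        s = int(np.searchsorted(cum_init, u[0]))
        states[pos] = s
        for t in range(1, n):
            s = int(np.searchsorted(cum_trans[s], u[t]))
            states[pos + t] = s
        pos += n

    values = (rng.random((len(bins), len(config.marks))) < config.emission[states]).astype(
        np.uint8
    )
    path = StatePath(bins, states, K)
    matrix = BinnedMarkMatrix(bins, tuple(config.marks), values)
    return path, matrix


# ---------------------------------------------------------------------------
# mark reads and count tables
# ---------------------------------------------------------------------------

@dataclass
class MarkReadSimulation:
    """Per-condition, per-mark reads and counts with the planted truth."""

    reads: dict[tuple[str, str], list[GenomicInterval]]
    counts: dict[tuple[str, str], pd.Series]
    library_sizes: dict[tuple[str, str], int]
    windows: dict[str, dict[str, list[GenomicInterval]]]  # mark -> feature windows
    truth: pd.DataFrame  # gene_id, mark, condition, log2fc
    planted_genes: list[str]


def _feature_windows(
    config: SimulationConfig,
    genome: GenomeDescription,
    genes: Sequence[GeneModel],
) -> dict[str, dict[str, list[GenomicInterval]]]:
    promoters = {p.name: [p] for p in make_promoters(genes, genome)}
    windows: dict[str, dict[str, list[GenomicInterval]]] = {}
    for mark in config.marks:
        if mark == "H3K36me3":
            # transcription-body mark: promoter plus gene body
            windows[mark] = {
                g.gene_id: promoters[g.gene_id]
                + [GenomicInterval(g.chrom, g.tx_start, g.tx_end)]
                for g in genes
            }
        else:
            windows[mark] = {g.gene_id: promoters[g.gene_id] for g in genes}
    return windows


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_mark_reads(
    config: SimulationConfig,
    genome: GenomeDescription,
    genes: Sequence[GeneModel],
) -> MarkReadSimulation:
    """Simulate per-condition mark reads over promoter (and gene-body) windows.

    Non-planted genes share the configured mean depth; planted genes are
    scaled by 2^log2FC for the planted marks in the HFD conditions. Counts
    are negative-binomial (Poisson at dispersion 0); each counted read is a
    fixed-length interval placed uniformly inside the feature window, and
    uniformly placed background reads bring the library to a realistic size.
    """
    rng = _rng(config, 3)
    gene_ids = [g.gene_id for g in genes]
    n_planted = int(round(config.planted_fraction * len(genes)))
    planted = sorted(rng.choice(gene_ids, size=n_planted, replace=False)) if n_planted else []
    planted_set = set(planted)
    if not set(planted_set) <= set(gene_ids):
        raise ValueError("planted genes must be a subset of the gene set")
    windows = _feature_windows(config, genome, genes)

    lfc_by_cond = dict(config.planted_log2fc_by_condition or {})
    reads: dict[tuple[str, str], list[GenomicInterval]] = {}
    counts: dict[tuple[str, str], pd.Series] = {}
    libs: dict[tuple[str, str], int] = {}
    truth_rows = []
    chrom_names = genome.chroms
    chrom_lengths = np.array([genome[c] for c in chrom_names])
    chrom_p = chrom_lengths / chrom_lengths.sum()

    for cond in config.conditions:
        is_hfd = cond.startswith("HFD")
        for mark in config.marks:
            lfc = np.zeros(len(genes))
            for i, g in enumerate(genes):
                if g.gene_id in planted_set and mark in config.planted_marks and is_hfd:
                    lfc[i] = lfc_by_cond.get(cond, config.planted_log2fc)
                truth_rows.append((g.gene_id, mark, cond, lfc[i]))
            mean = config.mean_depth * np.power(2.0, lfc)
            c = _draw_counts(rng, mean, config.dispersion)
            counts[(cond, mark)] = pd.Series(c, index=gene_ids, name="count")

            ivs: list[GenomicInterval] = []
            for g, n_reads in zip(genes, c):
                pieces = windows[mark][g.gene_id]
                lengths = np.array([len(p) for p in pieces], dtype=float)
                picks = rng.choice(len(pieces), size=n_reads, p=lengths / lengths.sum())
                for pi in picks:
                    piece = pieces[pi]
                    span = max(1, len(piece) - config.read_length)
                    start = piece.start + int(rng.integers(0, span))
                    end = min(start + config.read_length, genome[piece.chrom])
                    ivs.append(GenomicInterval(piece.chrom, start, end))
            n_bg = int(rng.poisson(config.background_reads))
            bg_chrom = rng.choice(len(chrom_names), size=n_bg, p=chrom_p)
            for ci in bg_chrom:
                chrom = chrom_names[ci]
                start = int(rng.integers(0, genome[chrom] - config.read_length))
                ivs.append(GenomicInterval(chrom, start, start + config.read_length))
            reads[(cond, mark)] = ivs
            libs[(cond, mark)] = len(ivs)

    truth = pd.DataFrame(truth_rows, columns=["gene_id", "mark", "condition", "log2fc"])
    return MarkReadSimulation(reads, counts, libs, windows, truth, list(planted))


# ---------------------------------------------------------------------------
# methylation peaks
# ---------------------------------------------------------------------------

def simulate_medip_peaks(
    config: SimulationConfig,
    path: StatePath,
    n_peaks: int | None = None,
) -> list[GenomicInterval]:
    """Fixed-width methylation peaks centered on bins sampled with probability
    proportional to the affinity of each bin's true state."""
    affinity = np.asarray(config.medip_affinity, dtype=float)
    if (affinity < 0).any():
        raise ValueError("affinity weights must be >= 0")
    if affinity.sum() == 0:
        raise ValueError("all-zero affinities")
    if n_peaks is None:
        n_peaks = config.n_medip_peaks
    if n_peaks == 0:
        return []
    rng = _rng(config, 4)
    w = affinity[path.states]
    p = w / w.sum()
    picks = rng.choice(len(path.bins), size=n_peaks, p=p)
    half = config.medip_peak_width // 2
    peaks = []
    for i, bi in enumerate(sorted(picks)):
        b = path.bins[bi]
        center = b.midpoint
        start = max(0, center - half)
        peaks.append(
            GenomicInterval(b.chrom, start, start + config.medip_peak_width, name=f"mpk{i}")
        )
    return peaks


# ---------------------------------------------------------------------------
# snATAC fragments
# ---------------------------------------------------------------------------

@dataclass
class AtacSimulation:
    """Fragments plus the per-barcode truth sidecar (type, condition, QC)."""

    fragments: pd.DataFrame
    truth: pd.DataFrame
    marker_genes: dict[str, str]


def simulate_atac(
    config: SimulationConfig,
    genome: GenomeDescription,
    genes: Sequence[GeneModel],
) -> AtacSimulation:
    """Simulate snATAC fragments with cell-type labels and QC covariates.

    Cell types are multinomial draws from the per-condition composition
    vectors; per-cell fragment counts are lognormal, nucleosome signal and
    TSS enrichment are gamma. Fragments fall inside extended gene bodies,
    with each type's marker gene boosted and optional condition-dependent
    per-gene effects. QC covariates are generated directly rather than
    derived from the fragments themselves.
    """
    rng = _rng(config, 5)
    markers = config.marker_genes(genes)
    gene_ids = [g.gene_id for g in genes]
    spans = []
    for g in genes:
        if g.strand == "+":
            lo, hi = max(0, g.tx_start - 2000), g.tx_end
        else:
            lo, hi = g.tx_start, min(genome[g.chrom], g.tx_end + 2000)
        spans.append((g.chrom, lo, hi))

    truth_rows = []
    frag_parts: list[pd.DataFrame] = []
    for cond in config.atac_conditions:
        comp = config.composition[cond]
        types = rng.choice(len(config.cell_types), size=config.n_cells_per_condition, p=comp)
        n_frags = np.maximum(
            1,
            rng.lognormal(config.frag_log_mean, config.frag_log_sigma,
                          config.n_cells_per_condition).astype(np.int64),
        )
        nuc = rng.gamma(config.nucleosome_shape, config.nucleosome_scale,
                        config.n_cells_per_condition)
        tss = rng.gamma(config.tss_shape, config.tss_scale, config.n_cells_per_condition)
        barcodes = [f"{cond}:BC{i:05d}" for i in range(config.n_cells_per_condition)]
        for bc, ti, nf, nu, te in zip(barcodes, types, n_frags, nuc, tss):
            truth_rows.append((bc, config.cell_types[ti], cond, int(nf), nu, te))

        is_treatment = cond != config.atac_conditions[0]
        for ti in np.unique(types):
            cell_type = config.cell_types[ti]
            weights = np.ones(len(genes))
            weights[gene_ids.index(markers[cell_type])] *= config.marker_boost
            if is_treatment:
                for (t, gid), mult in config.atac_condition_effects.items():
                    if t == cell_type:
                        weights[gene_ids.index(gid)] *= mult
            p = weights / weights.sum()
            mask = types == ti
            group_counts = n_frags[mask]
            group_barcodes = np.repeat(
                np.array(barcodes, dtype=object)[mask], group_counts
            )
            total = int(group_counts.sum())
            gidx = rng.choice(len(genes), size=total, p=p)
            lens = rng.integers(80, 300, size=total)
            chroms = np.empty(total, dtype=object)
            starts = np.empty(total, dtype=np.int64)
            ends = np.empty(total, dtype=np.int64)
            span_arr = np.array([(lo, hi) for _, lo, hi in spans])
            chrom_arr = np.array([c for c, _, _ in spans], dtype=object)
            lo = span_arr[gidx, 0]
            hi = span_arr[gidx, 1]
            max_start = np.maximum(lo + 1, hi - lens)
            starts = lo + (rng.random(total) * (max_start - lo)).astype(np.int64)
            ends = np.minimum(starts + lens, hi)
            ends = np.maximum(ends, starts + 1)
            chroms = chrom_arr[gidx]
            frag_parts.append(
                pd.DataFrame(
                    {
                        "chrom": chroms,
                        "start": starts,
                        "end": ends,
                        "barcode": group_barcodes,
                        "count": 1,
                    }
                )
            )

    fragments = pd.concat(frag_parts, ignore_index=True)
    fragments = fragments.sort_values(
        ["chrom", "start", "end", "barcode"], kind="stable"
    ).reset_index(drop=True)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "barcode",
            "cell_type",
            "condition",
            "fragments_in_peaks",
            "nucleosome_signal",
            "tss_enrichment",
        ],
    )
    return AtacSimulation(fragments, truth, markers)


def write_truth_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
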