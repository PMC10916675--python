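"""Binarization, Baum-Welch fitting, decoding and state annotation statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epidiet.chromstate import (
    BinarizationModel,
    BinnedMarkMatrix,
    StatePath,
    annotation_overlap_enrichment,
    binarize_bins,
    count_reads_in_bins,
    decode_states,
    fit_state_model,
    poisson_threshold,
    state_genome_fractions,
    state_methylation_levels,
    tss_neighborhood_enrichment,
)
from epidiet.intervals import (
    GenomeDescription,
    GenomicInterval,
    GeneModel,
    bin_genome,
    coverage_fraction,
)


def make_matrix(values, marks=None, bin_size=200):
    values = np.asarray(values, dtype=np.uint8)
    genome = GenomeDescription({"chr1": len(values) * bin_size})
    bins = bin_genome(genome, bin_size)
    marks = marks or tuple(f"m{i}" for i in range(values.shape[1]))
    return BinnedMarkMatrix(bins, tuple(marks), values)


class TestBinarization:
    def test_poisson_threshold_tail_rule(self):
        # P(Poisson(1) >= 7) ~ 8.3e-5 <= 1e-4 while P(>= 6) ~ 5.9e-4
        assert poisson_threshold(1.0, 1e-4) == 7
        for lam, alpha in [(0.5, 1e-4), (2.0, 1e-3), (10.0, 1e-2)]:
            c = poisson_threshold(lam, alpha)
            assert stats.poisson.sf(c - 1, lam) <= alpha
            assert c == 1 or stats.poisson.sf(c - 2, lam) > alpha

    def test_zero_counts_stay_zero(self):
        genome = GenomeDescription({"chr1": 1000})
        bins = bin_genome(genome, 200)
        counts = np.zeros((5, 2), dtype=int)
        counts[:, 1] = [1, 2, 50, 1, 1]
        mat = binarize_bins(counts, bins, ("a", "b"))
        assert not mat.values[:, 0].any()  # all-zero track
        assert mat.values[2, 1] == 1  # far above background

    def test_explicit_model_threshold(self):
        genome = GenomeDescription({"chr1": 600})
        bins = bin_genome(genome, 200)
        model = BinarizationModel({"a": 1.0}, alpha=1e-4)
        counts = np.array([[6], [7], [0]])
        mat = binarize_bins(counts, bins, ("a",), model)
        assert list(mat.values[:, 0]) == [0, 1, 0]

    def test_negative_counts_rejected(self):
        genome = GenomeDescription({"chr1": 400})
        with pytest.raises(ValueError):
            binarize_bins(np.array([[-1], [0]]), bin_genome(genome, 200), ("a",))


def test_count_reads_in_bins_any_overlap():
    genome = GenomeDescription({"chr1": 1000})
    reads = [
        GenomicInterval("chr1", 150, 250),  # spans bins 0 and 1
        GenomicInterval("chr1", 400, 420),  # bin 2 only
        GenomicInterval("chr1", 999, 1000),  # final base
    ]
    bins, counts = count_reads_in_bins(reads, genome, 200)
    assert list(counts) == [1, 1, 1, 0, 1]
    # a fully contained read touches exactly one bin
    _, c2 = count_reads_in_bins([GenomicInterval("chr1", 50, 150)], genome, 200)
    assert list(c2) == [1, 0, 0, 0, 0]


class TestFit:
    def test_single_state_closed_form(self, rng):
        X = (rng.random((2000, 3)) < [0.3, 0.6, 0.1]).astype(np.uint8)
        model = fit_state_model(make_matrix(X), 1, seed=0, n_restarts=1)
        assert model.emission[0] == pytest.approx(X.mean(axis=0), abs=1e-9)

    def test_loglik_monotone_nondecreasing(self, rng):
        X = (rng.random((3000, 4)) < 0.4).astype(np.uint8)
        model = fit_state_model(make_matrix(X), 3, seed=1, n_restarts=2, max_iter=50)
        ll = np.array(model.log_likelihood_history)
        assert np.all(np.diff(ll) >= -1e-8 * np.abs(ll[:-1]))

    def test_two_state_recovery(self, rng):
        B = np.array([[0.9, 0.9, 0.9], [0.05, 0.05, 0.05]])
        states = np.zeros(12000, dtype=int)
        u = rng.random(12000)
        for t in range(1, 12000):
            states[t] = states[t - 1] if u[t] < 0.95 else 1 - states[t - 1]
        X = (rng.random((12000, 3)) < B[states]).astype(np.uint8)
        model = fit_state_model(make_matrix(X), 2, seed=0)
        # relabeling puts the high-emission state first
        assert np.abs(model.emission - B).max() < 0.05
        path = decode_states(model, make_matrix(X))
        assert (path.states == states).mean() >= 0.95

    def test_refit_same_seed_identical(self, rng):
        X = (rng.random((2000, 3)) < 0.3).astype(np.uint8)
        m1 = fit_state_model(make_matrix(X), 2, seed=5, n_restarts=2)
        m2 = fit_state_model(make_matrix(X), 2, seed=5, n_restarts=2)
        assert np.array_equal(m1.emission, m2.emission)
        assert np.array_equal(m1.transition, m2.transition)

    def test_too_many_states_warns(self, rng):
        X = np.zeros((100, 2), dtype=np.uint8)  # one distinct pattern
        with pytest.warns(UserWarning):
            fit_state_model(make_matrix(X), 2, seed=0, n_restarts=1, max_iter=5)


class TestDecode:
    def test_mark_mismatch_rejected(self, rng):
        X = (rng.random((100, 2)) < 0.5).astype(np.uint8)
        model = fit_state_model(make_matrix(X, marks=("a", "b")), 2, seed=0, n_restarts=1, max_iter=5)
        with pytest.raises(ValueError):
            decode_states(model, make_matrix(X, marks=("a", "c")))

    def test_identical_emissions_tie_to_lower_state(self, rng):
        X = (rng.random((50, 2)) < 0.5).astype(np.uint8)
        mat = make_matrix(X)
        model = fit_state_model(mat, 2, seed=0, n_restarts=1, max_iter=1)
        model.emission[:] = 0.5
        model.transition[:] = 0.5
        model.initial[:] = 0.5
        path = decode_states(model, mat)
        assert (path.states == 0).all()

    def test_segments_partition_genome(self, rng):
        X = (rng.random((500, 2)) < 0.5).astype(np.uint8)
        mat = make_matrix(X)
        model = fit_state_model(mat, 2, seed=0, n_restarts=1, max_iter=10)
        path = decode_states(model, mat)
        segs = path.segments()
        assert sum(len(iv) for iv, _ in segs) == 500 * 200
        for (a, _), (b, _) in zip(segs, segs[1:]):
            assert a.end == b.start or a.chrom != b.chrom


class TestStateStatistics:
    def test_genome_fractions(self):
        path = StatePath(bin_genome(GenomeDescription({"c": 1000}), 200), [0, 0, 1, 1, 1], 2)
        assert state_genome_fractions(path) == pytest.approx([40.0, 60.0])

    def test_single_state_path(self):
        path = StatePath(bin_genome(GenomeDescription({"c": 600}), 200), [1, 1, 1], 3)
        fr = state_genome_fractions(path)
        assert fr[1] == pytest.approx(100.0) and fr.sum() == pytest.approx(100.0)

    def test_fractions_sum_with_remainder_bins(self, rng):
        bins = bin_genome(GenomeDescription({"c1": 1001, "c2": 399}), 200)
        path = StatePath(bins, rng.integers(0, 3, len(bins)), 3)
        assert state_genome_fractions(path).sum() == pytest.approx(100.0, abs=1e-9)


class TestTssEnrichment:
    def test_shape_and_null(self, rng):
        genome = GenomeDescription({"chr1": 200_000})
        bins = bin_genome(genome, 200)
        path = StatePath(bins, rng.integers(0, 3, len(bins)), 3)
        genes = [
            GeneModel(f"g{i}", "chr1", "+", s, s + 1000)
            for i, s in enumerate(range(10_000, 190_000, 2_000))
        ]
        fold = tss_neighborhood_enrichment(path, genes)
        assert fold.shape == (3, 20)
        assert np.nanmax(np.abs(fold.to_numpy() - 1)) < 0.6  # MC noise around 1

    def test_state_concentrated_at_tss(self):
        genome = GenomeDescription({"chr1": 400_000})
        bins = bin_genome(genome, 200)
        states = np.zeros(len(bins), dtype=int)
        genes = []
        for i, tss in enumerate(range(20_000, 400_000 - 20_000, 4_000)):
            states[tss // 200] = 1
            genes.append(GeneModel(f"g{i}", "chr1", "+", tss, tss + 2000))
        # pad state 1 to exactly 5% of bins, far away from any TSS window
        need = int(0.05 * len(bins)) - (states == 1).sum()
        filler = np.where(states == 0)[0]
        filler = [b for b in filler if b % 20 == 1][:need]
        states[filler] = 1
        path = StatePath(bins, states, 2)
        fold = tss_neighborhood_enrichment(path, genes)
        frac = (states == 1).mean()
        assert fold.loc["S2", 0] == pytest.approx(1 / frac, rel=0.05)

    def test_no_genes_rejected(self, rng):
        bins = bin_genome(GenomeDescription({"c": 1000}), 200)
        path = StatePath(bins, rng.integers(0, 2, 5), 2)
        with pytest.raises(ValueError):
            tss_neighborhood_enrichment(path, [])


class TestAnnotationEnrichment:
    def test_whole_genome_fold_is_one(self, rng):
        bins = bin_genome(GenomeDescription({"c": 10_000}), 200)
        path = StatePath(bins, rng.integers(0, 3, len(bins)), 3)
        fold = annotation_overlap_enrichment(
            path, {"all": [GenomicInterval("c", 0, 10_000)]}
        )
        assert fold["all"].to_numpy() == pytest.approx(np.ones(3))

    def test_disjoint_annotation_fold_zero(self):
        bins = bin_genome(GenomeDescription({"c": 1000}), 200)
        path = StatePath(bins, [0, 0, 1, 1, 1], 2)
        fold = annotation_overlap_enrichment(
            path, {"a": [GenomicInterval("c", 0, 400)]}
        )
        assert fold.loc["S2", "a"] == 0.0

    def test_three_bin_toy_manual_arithmetic(self):
        # states: S1 on [0,200), S2 on [200,600); annotation covers [100,300)
        bins = bin_genome(GenomeDescription({"c": 600}), 200)
        path = StatePath(bins, [0, 1, 1], 2)
        fold = annotation_overlap_enrichment(
            path, {"a": [GenomicInterval("c", 100, 300)]}
        )
        # S1: 100/200 inside vs genome 200/600 -> 1.5; S2: 100/400 vs 1/3 -> 0.75
        assert fold.loc["S1", "a"] == pytest.approx(1.5)
        assert fold.loc["S2", "a"] == pytest.approx(0.75)

    def test_empty_annotation_reported_missing(self):
        bins = bin_genome(GenomeDescription({"c": 600}), 200)
        path = StatePath(bins, [0, 1, 1], 2)
        fold = annotation_overlap_enrichment(path, {"a": []})
        assert fold["a"].isna().all()


class TestMethylationByState:
    def test_segment_fraction_example(self):
        bins = bin_genome(GenomeDescription({"c": 1000}), 200)
        path = StatePath(bins, [0] * 5, 1)
        peaks = [GenomicInterval("c", 100, 200), GenomicInterval("c", 500, 600)]
        per_seg, summary = state_methylation_levels(path, peaks)
        assert per_seg["fraction"].iloc[0] == pytest.approx(0.2)
        assert summary.loc[0, "n_overlapped"] == 1

    def test_state_without_peaks(self):
        bins = bin_genome(GenomeDescription({"c": 1000}), 200)
        path = StatePath(bins, [0, 0, 1, 1, 1], 2)
        peaks = [GenomicInterval("c", 0, 150)]
        per_seg, summary = state_methylation_levels(path, peaks)
        s2 = summary[summary.state == "S2"].iloc[0]
        assert s2["n_overlapped"] == 0
        assert per_seg.loc[per_seg.state == "S2", "fraction"].eq(0).all()

    def test_matches_per_base_oracle(self, rng):
        genome = GenomeDescription({"c": 10_000})
        bins = bin_genome(genome, 200)
        path = StatePath(bins, rng.integers(0, 3, len(bins)), 3)
        peaks = [
            GenomicInterval("c", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 9_500, 40), rng.integers(50, 500, 40))
        ]
        peaks = [GenomicInterval(p.chrom, p.start, min(p.end, 10_000)) for p in peaks]
        covered = np.zeros(10_000, dtype=bool)
        for p in peaks:
            covered[p.start : p.end] = True
        per_seg, _ = state_methylation_levels(path, peaks)
        for row in per_seg.itertuples():
            assert row.fraction == pytest.approx(
                covered[row.start : row.end].mean(), abs=1e-12
            )
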