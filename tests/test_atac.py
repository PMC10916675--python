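"""snATAC layer: fragment shift, QC filtering, activity, LSI, composition, tests."""

import numpy as np
import pandas as pd
import pytest

from epidiet.atac import (
    composition_change,
    differential_activity,
    gene_activity,
    load_fragments,
    qc_filter,
    tfidf_lsi,
)
from epidiet.intervals import GeneModel


def write_frag_file(tmp_path, rows):
    p = tmp_path / "frags.tsv"
    p.write_text("".join("\t".join(str(x) for x in r) + "\n" for r in rows))
    return p


class TestLoadFragments:
    def test_strand_shift(self, tmp_path):
        p = write_frag_file(tmp_path, [("chr1", 100, 200, "BC1", 1)])
        df = load_fragments(p)
        assert (df.loc[0, "start"], df.loc[0, "end"]) == (104, 195)

    def test_degenerate_after_shift_dropped(self, tmp_path):
        p = write_frag_file(
            tmp_path, [("chr1", 100, 108, "BC1", 1), ("chr1", 0, 500, "BC2", 2)]
        )
        df = load_fragments(p)
        assert list(df["barcode"]) == ["BC2"]

    def test_shift_off_unchanged(self, tmp_path):
        p = write_frag_file(tmp_path, [("chr1", 100, 200, "BC1", 1)])
        df = load_fragments(p, apply_shift=False)
        assert (df.loc[0, "start"], df.loc[0, "end"]) == (100, 200)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chr1\t1\t100\tBC1\nchr1\tx\t200\tBC2\n")
        with pytest.raises(ValueError, match=":2"):
            load_fragments(p)


class TestQcFilter:
    def qc(self, rows):
        return pd.DataFrame(
            rows, columns=["barcode", "fragments_in_peaks", "nucleosome_signal", "tss_enrichment"]
        )

    def test_four_thresholds(self):
        # a healthy population plus one boundary violator per rule
        healthy = [(f"ok{i}", 500, 1.0, 5.0) for i in range(50)]
        table = self.qc(
            healthy
            + [
                ("low_frags", 150, 1.0, 5.0),
                ("high_nuc", 500, 5.0, 5.0),
                ("low_tss", 500, 1.0, 1.5),
                ("too_many", 50_000, 1.0, 5.0),
            ]
        )
        kept, flagged = qc_filter(table)
        assert set(kept) == {f"ok{i}" for i in range(50)}
        assert not flagged.set_index("barcode")["pass"][
            ["low_frags", "high_nuc", "low_tss", "too_many"]
        ].any()

    def test_exact_boundaries_kept(self):
        table = self.qc(
            [(f"c{i}", 1000, 1.0, 5.0) for i in range(30)]
            + [("edge", 200, 4.0, 2.0)]
        )
        kept, _ = qc_filter(table)
        assert "edge" in kept  # >=200, <=cap, nucleosome <=4, TSS >=2

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        table = self.qc(
            [
                (f"c{i}", int(f), n, t)
                for i, (f, n, t) in enumerate(
                    zip(
                        rng.lognormal(6.5, 0.6, 200),
                        rng.gamma(4, 0.5, 200),
                        rng.gamma(6, 1, 200),
                    )
                )
            ]
        )
        kept1, flagged = qc_filter(table)
        # the quantile cap is computed once on the input, so re-filtering the
        # kept cells keeps them all
        kept2, _ = qc_filter(flagged[flagged["pass"]].drop(columns="pass"))
        assert set(kept2) <= set(kept1)
        assert len(kept2) >= 0.94 * len(kept1)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            qc_filter(self.qc([]))


class TestGeneActivity:
    GENES = [
        GeneModel("gP", "chr1", "+", 10_000, 15_000),
        GeneModel("gM", "chr1", "-", 30_000, 35_000),
    ]

    def frags(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])

    def test_fragment_in_body(self):
        f = self.frags([("chr1", 12_000, 12_200, "BC1", 1)])
        act = gene_activity(f, self.GENES, normalize=False)
        assert act.loc["BC1", "gP"] == 1

    def test_fragment_upstream_within_extension(self):
        f = self.frags(
            [
                ("chr1", 9_000, 9_100, "BC1", 1),  # 1 kb upstream of + TSS
                ("chr1", 36_000, 36_100, "BC2", 1),  # 1 kb upstream of - TSS
            ]
        )
        act = gene_activity(f, self.GENES, normalize=False)
        assert act.loc["BC1", "gP"] == 1
        assert act.loc["BC2", "gM"] == 1

    def test_far_fragment_not_counted(self):
        f = self.frags([("chr1", 500, 600, "BC1", 1)])
        act = gene_activity(f, self.GENES, normalize=False)
        assert act.loc["BC1"].sum() == 0

    def test_depth_normalization_equalizes(self):
        rows = [("chr1", 12_000, 12_100, "deep", 1)] * 40 + [
            ("chr1", 12_000, 12_100, "shallow", 1)
        ] * 10
        act = gene_activity(self.frags(rows), self.GENES)
        assert act.loc["deep", "gP"] == pytest.approx(act.loc["shallow", "gP"])


class TestTfidfLsi:
    def matrix(self, rng, n_cells=60, n_genes=40):
        X = rng.poisson(3, (n_cells, n_genes)).astype(float)
        return pd.DataFrame(
            X,
            index=[f"c{i}" for i in range(n_cells)],
            columns=[f"g{j}" for j in range(n_genes)],
        )

    def test_component_orthogonality(self, rng):
        res = tfidf_lsi(self.matrix(rng), n_components=5)
        S = res.scores.to_numpy()
        G = S.T @ S
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_rank_one_input(self):
        cells = [f"c{i}" for i in range(10)]
        X = pd.DataFrame(
            np.outer(np.ones(10), np.arange(1, 9)), index=cells,
            columns=[f"g{j}" for j in range(8)],
        )
        res = tfidf_lsi(X, n_components=4, top_feature_fraction=1.0)
        s = res.singular_values
        assert (s[1:] < 1e-8 * s[0]).all()

    def test_duplicating_cells_preserves_subspace(self, rng):
        X = self.matrix(rng, n_cells=30)
        res1 = tfidf_lsi(X, n_components=4, top_feature_fraction=1.0)
        X2 = pd.concat([X, X.set_index(X.index + "_dup")])
        res2 = tfidf_lsi(X2, n_components=4, top_feature_fraction=1.0)
        got = res2.scores.to_numpy()[: len(X)]
        want = res1.scores.to_numpy()
        # same column spans up to sign/rotation: compare projection operators;
        # IDF depends weakly on the cell count, so the match is approximate
        def proj(M):
            Q, _ = np.linalg.qr(M)
            return Q @ Q.T
        assert np.abs(proj(got) - proj(want)).max() < 1e-2

    def test_top_fraction_feature_selection(self, rng):
        X = self.matrix(rng)
        res = tfidf_lsi(X, n_components=3, top_feature_fraction=0.25)
        assert len(res.features) == 10

    def test_all_zero_rejected(self):
        X = pd.DataFrame(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            tfidf_lsi(X)


class TestCompositionChange:
    def make(self, spec):
        types, conds = [], []
        for cond, counts in spec.items():
            for t, n in counts.items():
                types += [t] * n
                conds += [cond] * n
        return types, conds

    def test_fifty_percent_increase(self):
        types, conds = self.make(
            {"chow": {"a": 10, "b": 90}, "hfd": {"a": 15, "b": 85}}
        )
        out = composition_change(types, conds, "chow", "hfd")
        assert out.loc["a", "relative_change_pct"] == pytest.approx(50.0)

    def test_no_change(self):
        types, conds = self.make({"chow": {"a": 10, "b": 10}, "hfd": {"a": 5, "b": 5}})
        out = composition_change(types, conds, "chow", "hfd")
        assert out["relative_change_pct"].to_numpy() == pytest.approx([0.0, 0.0])

    def test_reported_astrocyte_arithmetic(self):
        # shares 12.5% -> 5.3% is a 57.6% relative decrease
        types, conds = self.make(
            {"chow": {"ac": 125, "rest": 875}, "hfd": {"ac": 53, "rest": 947}}
        )
        out = composition_change(types, conds, "chow", "hfd")
        assert out.loc["ac", "relative_change_pct"] == pytest.approx(-57.6)

    def test_shares_sum_to_100(self, rng):
        types = list(rng.choice(list("abcd"), 500))
        conds = list(rng.choice(["x", "y"], 500))
        out = composition_change(types, conds, "x", "y")
        assert out["share_baseline"].sum() == pytest.approx(100.0, abs=1e-9)
        assert out["share_treatment"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_type_absent_from_baseline_missing(self):
        types, conds = self.make({"chow": {"a": 10}, "hfd": {"a": 5, "b": 5}})
        out = composition_change(types, conds, "chow", "hfd")
        assert np.isnan(out.loc["b", "relative_change_pct"])


class TestDifferentialActivity:
    def build(self, rng, n_genes=50, n_cells=40, shift_genes=(), shift=0.0):
        cells = [f"c{i}" for i in range(n_cells)]
        types = pd.Series("neuron", index=cells)
        conds = pd.Series(
            ["chow"] * (n_cells // 2) + ["hfd"] * (n_cells - n_cells // 2), index=cells
        )
        X = rng.normal(0, 1, (n_cells, n_genes))
        genes = [f"g{j}" for j in range(n_genes)]
        M = pd.DataFrame(X, index=cells, columns=genes)
        for g in shift_genes:
            M.loc[conds == "hfd", g] += shift
        return M, types, conds

    def test_planted_shift_detected(self, rng):
        M, types, conds = self.build(
            rng, n_cells=100, shift_genes=["g0", "g1"], shift=2.0
        )
        res = differential_activity(M, types, conds, "neuron", "chow", "hfd")
        assert (res.loc[["g0", "g1"], "call"] == "up").all()

    def test_constant_gene_p_one(self, rng):
        M, types, conds = self.build(rng)
        M["g0"] = 3.14
        res = differential_activity(M, types, conds, "neuron", "chow", "hfd")
        assert res.loc["g0", "p"] == 1.0 and res.loc["g0", "call"] == "ns"

    def test_direction_sign(self, rng):
        M, types, conds = self.build(rng, n_cells=100, shift_genes=["g0"], shift=-2.0)
        res = differential_activity(M, types, conds, "neuron", "chow", "hfd")
        assert res.loc["g0", "call"] == "down"

    def test_requires_three_cells_per_group(self, rng):
        M, types, conds = self.build(rng, n_cells=4)
        with pytest.raises(ValueError):
            differential_activity(M, types, conds, "neuron", "chow", "hfd")
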