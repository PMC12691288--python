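"""TMM normalization, Poisson differential transcripts, BH FDR, switch calls."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest

from scarnakit import (
    CountMatrix,
    SimConfig,
    call_switches,
    classify_directions,
    fdr_step_up,
    gen_counts,
    read_counts_tsv,
    tmm_factors,
    transcript_de,
    write_counts_tsv,
)
from scarnakit.synthetic_data import CountsSim


def matrix(data, groups, genes=None):
    df = pd.DataFrame(data)
    genes = genes or {t: f"g_{t}" for t in df.index}
    return CountMatrix(counts=df, gene_of=pd.Series(genes), sample_groups=groups)


def quiet_de(cm, factors=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return transcript_de(cm, factors)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(40, size=200)
        cm = matrix({"a": col, "b": col, "c": col},
                    {"a": "control", "b": "control", "c": "clone"})
        assert np.allclose(tmm_factors(cm), 1.0)

    def test_pure_depth_difference_cancels(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(40, size=500) + 1
        cm = matrix({"a": col, "b": 2 * col}, {"a": "control", "b": "clone"})
        assert np.allclose(tmm_factors(cm), 1.0, atol=1e-12)

    def test_untrimmed_factor_matches_hand_oracle(self):
        """4 x 2 toy with one 8-fold spike; trimming disabled."""
        counts = pd.DataFrame({"s1": [100, 50, 25, 25], "s2": [800, 50, 25, 25]})
        cm = matrix(counts, {"s1": "control", "s2": "clone"})
        f = tmm_factors(cm, trim_m=0.0, trim_a=0.0, ref_sample="s1")
        n1, n2 = 200.0, 900.0
        m = np.log2((counts["s2"] / n2) / (counts["s1"] / n1))
        w = 1.0 / ((n2 - counts["s2"]) / (n2 * counts["s2"]) + (n1 - counts["s1"]) / (n1 * counts["s1"]))
        raw = {"s1": 1.0, "s2": 2.0 ** (np.sum(m * w) / np.sum(w))}
        expected = pd.Series(raw) / np.exp(np.mean(np.log(pd.Series(raw))))
        assert f["s2"] == pytest.approx(expected["s2"], rel=1e-12)

    def test_matches_edger_reference_implementation(self):
        """Independent cross-check against edgeR::calcNormFactors via Rscript."""
        cm, _ = gen_counts(SimConfig(seed=7, counts=CountsSim(n_genes=100, n_switch=5)))
        ours = tmm_factors(cm)
        import tempfile

        with tempfile.TemporaryDirectory() as d:
            cm.counts.to_csv(f"{d}/c.tsv", sep="\t")
            res = subprocess.run(
                ["Rscript", "-e",
                 f'suppressMessages(library(edgeR)); x <- as.matrix(read.delim("{d}/c.tsv", row.names=1)); '
                 'cat(calcNormFactors(x, method="TMM"), sep="\\n")'],
                capture_output=True, text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        theirs = np.array([float(v) for v in res.stdout.split()])
        np.testing.assert_allclose(ours.to_numpy(), theirs, atol=1e-5)

    def test_disjoint_support_raises(self):
        cm = matrix({"a": [5, 5, 0, 0], "b": [0, 0, 5, 5]}, {"a": "control", "b": "clone"})
        with pytest.raises(ValueError, match="shares no expressed"):
            tmm_factors(cm, ref_sample="a")


class TestTranscriptDe:
    def test_equal_groups_give_null_result(self):
        cm = matrix({"a": [50, 10], "b": [50, 10], "c": [50, 10], "d": [50, 10]},
                    {"a": "control", "b": "control", "c": "clone", "d": "clone"})
        de = quiet_de(cm, pd.Series(1.0, index=cm.counts.columns)).set_index("transcript_id")
        assert de["lrt"].max() == pytest.approx(0.0, abs=1e-8)
        assert de["p_value"].min() > 0.99

    def test_single_sample_counts_10_vs_30(self):
        """Closed-form check: LRT = 2[10 ln(1/2) + 30 ln(3/2)] with equal offsets."""
        m = pd.DataFrame({"a": [10, 90], "b": [30, 70]}, index=["t", "filler"])
        cm = CountMatrix(counts=m, gene_of=pd.Series({"t": "g", "filler": "g"}),
                         sample_groups={"a": "control", "b": "clone"})
        de = quiet_de(cm, pd.Series(1.0, index=m.columns)).set_index("transcript_id")
        assert de.loc["t", "lrt"] == pytest.approx(10.46, abs=0.01)
        assert de.loc["t", "p_value"] == pytest.approx(0.0012, abs=0.0001)
        assert de.loc["t", "rate_ratio"] == pytest.approx(3.0, rel=1e-4)

    def test_lrt_matches_closed_form_on_random_equal_offset_cases(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.poisson(30, size=(6, 4)) + 1
            total = y.sum(axis=0).max() + rng.integers(1, 50)
            y = np.vstack([y, total - y.sum(axis=0)])  # equalize library sizes
            cm = matrix({s: y[:, j] for j, s in enumerate("abcd")},
                        {"a": "control", "b": "control", "c": "clone", "d": "clone"})
            de = quiet_de(cm, pd.Series(1.0, index=cm.counts.columns))
            for _, row in de.iterrows():
                i = list(cm.counts.index).index(row["transcript_id"])
                y1, y2 = y[i, :2].sum(), y[i, 2:].sum()
                o1 = o2 = 2 * total
                yy, oo = y1 + y2, o1 + o2

                def term(a, b):
                    return a * np.log(a / b) if a > 0 else 0.0

                closed = 2 * (term(y1, o1) + term(y2, o2) - term(yy, oo))
                assert row["lrt"] == pytest.approx(closed, abs=1e-5)

    def test_label_permutation_within_group_changes_nothing(self):
        cm, _ = gen_counts(SimConfig(seed=5, counts=CountsSim(n_genes=40, n_switch=4)))
        de1 = quiet_de(cm)
        swapped = dict(cm.sample_groups)
        cm2 = CountMatrix(counts=cm.counts[["ctrl_2", "ctrl_1", "ctrl_3",
                                            "clone_3", "clone_2", "clone_1"]],
                          gene_of=cm.gene_of, sample_groups=swapped)
        de2 = quiet_de(cm2)
        pd.testing.assert_frame_equal(de1, de2)

    def test_doubled_library_size_leaves_fold_changes_calibrated(self):
        """Sequencing one sample twice as deep must not shift fold changes."""
        base = CountsSim(n_genes=200, n_switch=10, baseline_log_mean=4.5)
        deep = CountsSim(n_genes=200, n_switch=10, baseline_log_mean=4.5,
                         lib_size_factors=(1.0, 1.0, 1.0, 2.0, 1.0, 1.0))
        cm, truth = gen_counts(SimConfig(seed=6, counts=deep))
        de = quiet_de(cm).set_index("transcript_id")
        switch_t = {f"{g}.t1" for g in truth["switch_genes"]}
        null_t = [t for t in de.index if de.loc[t, "gene_id"] not in set(truth["switch_genes"])]
        # planted 3-fold swaps estimated near +3, null transcripts near unity
        for t in switch_t:
            assert de.loc[t, "rate_ratio"] == pytest.approx(3.0, rel=0.35)
        assert np.median(np.abs(de.loc[null_t, "fold_change"])) < 1.25

    def test_all_zero_transcripts_are_excluded(self):
        cm = matrix({"a": [5, 0], "b": [7, 0]}, {"a": "control", "b": "clone"})
        de = quiet_de(cm, pd.Series(1.0, index=cm.counts.columns))
        assert len(de) == 1

    def test_single_sample_per_group_warns(self):
        cm = matrix({"a": [5, 9], "b": [7, 3]}, {"a": "control", "b": "clone"})
        with pytest.warns(UserWarning, match="single sample"):
            transcript_de(cm, pd.Series(1.0, index=cm.counts.columns))

    def test_null_p_values_approximately_uniform(self):
        """Planted-null matrix: Kolmogorov distance of LRT p-values < 0.05."""
        cm, _ = gen_counts(SimConfig(seed=19, counts=CountsSim(n_genes=1000, n_switch=0)))
        de = quiet_de(cm)
        p = np.sort(de["p_value"].to_numpy())
        grid = np.arange(1, p.size + 1) / p.size
        assert np.max(np.abs(p - grid)) < 0.05


class TestFdrStepUp:
    def test_worked_example(self):
        q = fdr_step_up([0.002, 0.01, 0.03, 0.04])
        assert q == pytest.approx([0.008, 0.02, 0.04, 0.04])

    def test_all_ones_and_singleton(self):
        assert fdr_step_up([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        assert fdr_step_up([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_step_up([0.5, 1.2])

    def test_matches_min_over_tails_oracle(self):
        """BH q_i = min over j >= i (sorted) of N p_(j) / j, capped at 1."""
        rng = np.random.default_rng(10)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 80)))
            order = np.argsort(p)
            n = p.size
            expected = np.empty(n)
            for rank, idx in enumerate(order, start=1):
                tail = [n * p[j] / (list(order).index(j) + 1) for j in order[rank - 1:]]
                expected[idx] = min(1.0, min(tail))
            np.testing.assert_allclose(fdr_step_up(p), expected, atol=1e-12)


class TestSwitchCalls:
    def de_frame(self, rows):
        df = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "fold_change", "q_value"])
        df["direction"] = "ns"
        sig = df["q_value"] < 0.05
        df.loc[sig & (df["fold_change"] > 1.5), "direction"] = "up"
        df.loc[sig & (df["fold_change"] < -1.5), "direction"] = "down"
        return df

    def test_reciprocal_gene_called(self):
        de = self.de_frame([("t1", "g1", 2.0, 0.01), ("t2", "g1", -2.0, 0.01)])
        calls = call_switches(de)
        assert [c.gene for c in calls] == ["g1"]
        assert calls[0].up_transcripts == ("t1",) and calls[0].down_transcripts == ("t2",)

    def test_one_direction_only_not_called(self):
        de = self.de_frame([("t1", "g1", 2.0, 0.01), ("t2", "g1", 3.0, 0.01)])
        assert call_switches(de) == []

    def test_direction_labels_respect_alpha_and_threshold(self):
        cm, _ = gen_counts(SimConfig(seed=21, counts=CountsSim(n_genes=60, n_switch=6)))
        de = classify_directions(quiet_de(cm))
        assert (de["q_value"] >= de["p_value"] - 1e-12).all()
        up = de["direction"] == "up"
        assert ((de.loc[up, "q_value"] < 0.05) & (de.loc[up, "fold_change"] > 1.5)).all()
        ns = de["direction"] == "ns"
        assert ((de.loc[ns, "q_value"] >= 0.05) | (de.loc[ns, "fold_change"].abs() <= 1.5)).all()


class TestIO:
    def test_counts_tsv_round_trip(self, tmp_path):
        cm, _ = gen_counts(SimConfig(seed=2, counts=CountsSim(n_genes=20, n_switch=2)))
        write_counts_tsv(cm, tmp_path / "c.tsv", tmp_path / "g.tsv")
        back = read_counts_tsv(tmp_path / "c.tsv", tmp_path / "g.tsv")
        pd.testing.assert_frame_equal(back.counts, cm.counts)
        assert back.sample_groups == cm.sample_groups
        assert (back.gene_of == cm.gene_of.reindex(back.gene_of.index)).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            matrix({"a": [-1, 2], "b": [1, 2]}, {"a": "control", "b": "clone"})
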