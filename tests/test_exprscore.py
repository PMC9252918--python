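"""Transcriptomic scores: z-scoring, ssGSEA, PI, CGA, panels, correlations."""

import numpy as np
import pandas as pd
import pytest

from mmclonetrack.exprscore import (
    GeneSet,
    classify_cga_change,
    classify_pi_change,
    count_expressed_cgas,
    default_panels,
    fold_change,
    panel_index,
    proliferation_index,
    read_gmt,
    spearman_panel,
    ssgsea_score,
    write_gmt,
    zscore_across_samples,
)


# -- independent brute-force ssGSEA oracle ----------------------------------


def ssgsea_oracle(z: pd.DataFrame, genes: set, exponent: float) -> dict:
    """Literal running-sum transcription, loop-based and independent."""
    out = {}
    for sample in z.columns:
        ranked = sorted(z.index, key=lambda g: (-z.at[g, sample], g))
        n = len(ranked)
        n_in = sum(g in genes for g in ranked)
        w_total = sum(abs(z.at[g, sample]) ** exponent for g in ranked if g in genes)
        p_in = p_out = 0.0
        score = 0.0
        for g in ranked:
            if g in genes:
                if w_total > 0:
                    p_in += abs(z.at[g, sample]) ** exponent / w_total
                else:
                    p_in += 1.0 / n_in
            else:
                p_out += 1.0 / (n - n_in)
            score += p_in - p_out
        out[sample] = score
    return out


class TestZscore:
    def test_hand_zscore(self):
        m = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]}, index=["g"])
        z = zscore_across_samples(m, log_transform=False)
        sd = np.std([1, 2, 3])
        np.testing.assert_allclose(z.loc["g"], np.array([-1, 0, 1]) / sd)

    def test_constant_gene_flagged_zero(self):
        m = pd.DataFrame({"a": [5.0], "b": [5.0], "c": [5.0]}, index=["g"])
        z = zscore_across_samples(m, log_transform=False)
        assert (z.loc["g"] == 0).all()
        assert z.attrs["zero_variance_genes"] == ["g"]

    def test_idempotent_on_standardized_input(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 6)), columns=list("abcdef"))
        z1 = zscore_across_samples(m, log_transform=False)
        z2 = zscore_across_samples(z1, log_transform=False)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)

    def test_single_sample_error(self):
        with pytest.raises(ValueError, match="2 samples"):
            zscore_across_samples(pd.DataFrame({"a": [1.0]}, index=["g"]))


class TestSsgsea:
    def test_matches_oracle_small_unweighted(self):
        z = pd.DataFrame(
            {"s1": [5.0, 4.0, 3.0, 2.0, 1.0]}, index=["g1", "g2", "g3", "g4", "g5"]
        )
        z["s2"] = z["s1"]  # two identical samples
        gs = GeneSet("top2", frozenset({"g1", "g2"}))
        got = ssgsea_score(z, gs, exponent=0)
        want = ssgsea_oracle(z, gs.genes, exponent=0)
        for s in z.columns:
            assert got[s] == pytest.approx(want[s], abs=1e-12)

    def test_matches_oracle_random_matrices(self, rng):
        """Vectorized implementation equals the loop oracle to 1e-9."""
        genes = [f"g{i:02d}" for i in range(20)]
        for rep in range(25):
            z = pd.DataFrame(
                rng.normal(size=(20, 3)), index=genes, columns=["a", "b", "c"]
            )
            members = frozenset(rng.choice(genes, size=int(rng.integers(2, 9)), replace=False))
            gs = GeneSet(f"set{rep}", members)
            for expo in (0.0, 0.25, 1.0):
                got = ssgsea_score(z, gs, exponent=expo)
                want = ssgsea_oracle(z, set(members), exponent=expo)
                for s in z.columns:
                    assert got[s] == pytest.approx(want[s], abs=1e-9)

    def test_rank_only_invariant_to_monotone_transform(self, rng):
        genes = [f"g{i}" for i in range(15)]
        z = pd.DataFrame(rng.normal(size=(15, 4)), index=genes)
        gs = GeneSet("s", frozenset(genes[:5]))
        a = ssgsea_score(z, gs, exponent=0)
        b = ssgsea_score(np.tanh(z) * 3 + 0.1, gs, exponent=0)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_promoting_members_increases_score(self):
        genes = [f"g{i}" for i in range(10)]
        bottom = pd.DataFrame({"s": np.arange(10, 0, -1, dtype=float)}, index=genes)
        gs = GeneSet("s", frozenset(genes[-3:]))  # members at the bottom
        low = ssgsea_score(bottom, gs, exponent=0)["s"]
        top = bottom.copy()
        top.loc[genes[-3:], "s"] += 100  # move members to the top ranks
        high = ssgsea_score(top, gs, exponent=0)["s"]
        assert high > low

    def test_sample_order_irrelevant(self, rng):
        genes = [f"g{i}" for i in range(12)]
        z = pd.DataFrame(rng.normal(size=(12, 4)), index=genes, columns=list("abcd"))
        gs = GeneSet("s", frozenset(genes[:4]))
        a = ssgsea_score(z, gs)
        b = ssgsea_score(z[["d", "b", "a", "c"]], gs)
        for s in "abcd":
            assert a[s] == pytest.approx(b[s])

    def test_empty_intersection_and_full_cover_errors(self, rng):
        z = pd.DataFrame(rng.normal(size=(4, 3)), index=list("wxyz"))
        with pytest.raises(ValueError, match="no genes"):
            ssgsea_score(z, GeneSet("none", frozenset({"absent"})))
        with pytest.raises(ValueError, match="complement"):
            ssgsea_score(z, GeneSet("all", frozenset("wxyz")))


class TestProliferationIndex:
    @pytest.fixture()
    def pi_panel(self):
        return default_panels()["PI"]

    def test_sample_at_cohort_mean_scores_zero(self, pi_panel, rng):
        genes = sorted(pi_panel.genes)
        log = pd.DataFrame(
            rng.uniform(0, 6, size=(11, 3)), index=genes, columns=list("abc")
        )
        # if d equals the mean of a,b,c per gene, it also equals the
        # four-sample mean, so every z value of d is 0
        log["d"] = log[["a", "b", "c"]].mean(axis=1)
        m = 2**log - 1
        pi = proliferation_index(m, pi_panel)
        assert pi["d"] == pytest.approx(0.0, abs=1e-9)

    def test_plus_one_sd_everywhere_scores_eleven(self, pi_panel):
        """A sample exactly +1 sd in every panel gene has PI = 11 (sum mode)."""
        genes = sorted(pi_panel.genes)
        base = np.tile([1.0, 2.0, 3.0], (11, 1))  # per-gene sd fixed by construction
        m = pd.DataFrame(base, index=genes, columns=["a", "b", "c"])
        z = zscore_across_samples(m, log_transform=False)
        pi = proliferation_index(m, pi_panel, log_transform=False)
        # sample 'c' sits at +(1/sd)*[3-2] = +1.2247 sd per gene -> PI = 11 * z_c
        assert pi["c"] == pytest.approx(11 * z.iloc[0]["c"])
        assert pi["b"] == pytest.approx(0.0, abs=1e-12)

    def test_mean_mode(self, pi_panel):
        genes = sorted(pi_panel.genes)
        m = pd.DataFrame(
            np.tile([1.0, 2.0, 3.0], (11, 1)), index=genes, columns=["a", "b", "c"]
        )
        s = proliferation_index(m, pi_panel, mode="sum", log_transform=False)
        mn = proliferation_index(m, pi_panel, mode="mean", log_transform=False)
        np.testing.assert_allclose(mn.to_numpy() * 11, s.to_numpy())

    def test_too_few_genes_error(self, pi_panel):
        genes = sorted(pi_panel.genes)[:4]
        m = pd.DataFrame(np.ones((4, 3)), index=genes, columns=list("abc"))
        with pytest.raises(ValueError, match="missing"):
            proliferation_index(m, pi_panel)

    def test_gene_and_sample_order_invariance(self, pi_panel, rng):
        genes = sorted(pi_panel.genes)
        m = pd.DataFrame(rng.uniform(1, 30, (11, 5)), index=genes, columns=list("abcde"))
        a = proliferation_index(m, pi_panel)
        b = proliferation_index(m.iloc[::-1][list("edcba")], pi_panel)
        for s in "abcde":
            assert a[s] == pytest.approx(b[s])


class TestPiChangeClassification:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (1.2, "high increase"),
            (1.01, "high increase"),
            (1.0, "increase"),
            (0.41, "increase"),
            (0.4, "no change"),
            (0.39, "no change"),
            (-0.4, "no change"),
            (-0.41, "decrease"),
        ],
    )
    def test_threshold_boundaries(self, delta, expected):
        assert classify_pi_change(0.0, delta).cls == expected

    def test_partition_of_real_line(self, rng):
        for delta in rng.uniform(-5, 5, 500):
            assert classify_pi_change(0.0, float(delta)).cls in {
                "high increase", "increase", "decrease", "no change",
            }


class TestCga:
    def test_strict_tpm_threshold(self):
        m = pd.DataFrame(
            {"s": [1.9, 2.0, 2.1, 50.0]}, index=["CGA1", "CGA2", "CGA3", "CGA4"]
        )
        gs = GeneSet("CGA", frozenset(m.index))
        counts = count_expressed_cgas(m, gs, tpm_threshold=2.0)
        assert counts["s"] == 2  # strictly greater than 2

    def test_all_zero_sample(self):
        m = pd.DataFrame({"s": [0.0, 0.0]}, index=["CGA1", "CGA2"])
        gs = GeneSet("CGA", frozenset(m.index))
        assert count_expressed_cgas(m, gs)["s"] == 0

    @pytest.mark.parametrize(
        "early,late,expected",
        [(4, 7, "increased"), (4, 6, "no change"), (7, 4, "decreased"), (0, 3, "increased")],
    )
    def test_change_rule(self, early, late, expected):
        assert classify_cga_change(early, late).cls == expected


class TestPanelIndex:
    def test_single_gene_panel_equals_z(self, tiny_tpm):
        z = zscore_across_samples(tiny_tpm)
        idx = panel_index(tiny_tpm, GeneSet("p", frozenset({"g2"})))
        np.testing.assert_allclose(idx.to_numpy(), z.loc["g2"].to_numpy())

    def test_disjoint_panels_cancel_across_samples(self, tiny_tpm):
        """Each gene's z-scores sum to 0 across samples, so the size-weighted
        combination of two complementary panel indices sums to 0 over the
        cohort (constant genes contribute 0 everywhere)."""
        a = GeneSet("a", frozenset({"g1", "g2"}))
        b = GeneSet("b", frozenset({"g3", "g4", "g5"}))
        ia, ib = panel_index(tiny_tpm, a), panel_index(tiny_tpm, b)
        combined = (2 * ia + 3 * ib) / 5
        assert combined.sum() == pytest.approx(0.0, abs=1e-9)

    def test_missing_panel_error(self, tiny_tpm):
        with pytest.raises(ValueError, match="no genes"):
            panel_index(tiny_tpm, GeneSet("p", frozenset({"nope"})))


class TestFoldChange:
    def test_arithmetic(self, tiny_tpm):
        fc, flags = fold_change(tiny_tpm, "g1", "s1", "s2", pseudocount=1.0)
        # g1: 1 -> 2 with c=1: (2+1)/(1+1) = 1.5 (not strictly greater)
        assert fc == pytest.approx(1.5)
        assert not flags["fc_gt_1_5"]

    def test_spec_values(self):
        m = pd.DataFrame({"e": [10.0], "l": [15.0]}, index=["g"])
        fc, flags = fold_change(m, "g", "e", "l")
        assert fc == pytest.approx(16 / 11)
        assert not flags["fc_gt_1_5"] and not flags["fc_gt_3"]

    def test_zero_zero_guard(self):
        m = pd.DataFrame({"e": [0.0], "l": [0.0]}, index=["g"])
        fc, flags = fold_change(m, "g", "e", "l")
        assert fc == 1.0 and not any(flags.values())

    def test_missing_gene(self, tiny_tpm):
        with pytest.raises(KeyError):
            fold_change(tiny_tpm, "nope", "s1", "s2")


class TestSpearmanPanel:
    def test_self_correlation(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20)})
        df["y"] = df["x"]
        out = spearman_panel(df, [("x", "y")])
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_monotone_transform_rank_invariance(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30)})
        df["y"] = np.exp(df["x"])
        out = spearman_panel(df, [("x", "y")])
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_planted_correlation_recovered(self, rng):
        n = 50
        x = rng.normal(size=n)
        y = 0.7 * x + np.sqrt(1 - 0.49) * rng.normal(size=n)
        out = spearman_panel(pd.DataFrame({"x": x, "y": y}), [("x", "y")])
        assert out.loc[0, "rho"] == pytest.approx(0.7, abs=0.15)

    def test_insufficient_overlap_skipped(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [1.0, 2, 3]})
        out = spearman_panel(df, [("x", "y")], min_overlap=5)
        assert np.isnan(out.loc[0, "rho"])


class TestGmt:
    def test_round_trip(self, tmp_path):
        sets = [GeneSet("A", frozenset({"g1", "g2"})), GeneSet("B", frozenset({"g3"}))]
        path = tmp_path / "x.gmt"
        write_gmt(sets, path)
        back = read_gmt(path)
        assert back["A"].genes == sets[0].genes and back["B"].genes == sets[1].genes

    def test_default_panels_shapes(self):
        panels = default_panels()
        assert len(panels["PI"]) == 11
        assert len(panels["CGA"]) == 27
        for key in ("NFKB_index", "HLA_I", "HLA_II", "ABC_transporters", "Exportins"):
            assert key in panels
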