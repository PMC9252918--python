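"""CCF transform, paired clustering, evolution classification, RAS shifts."""

import numpy as np
import pytest

from mmclonetrack.clonevo import (
    CcfClusterSolution,
    CopyNumberSegment,
    classify_evolution,
    cluster_pair,
    cn_locus_flags,
    compute_ccf,
    detect_ras_shift,
    expressed_fraction,
    segment_for,
)

from conftest import make_mut


def ccf_oracle(vaf, purity, cnt, cap=1.5):
    """Independent spreadsheet-style transcription of the CCF closed form."""
    denom = purity * cnt + (1 - purity) * 2
    mult = min(max(round(vaf / purity * denom), 1), max(cnt, 1))
    return min(vaf * denom / (purity * mult), cap), mult


DIPLOID = CopyNumberSegment("chr1", 1, 10**9, 2, 1)


class TestComputeCcf:
    def test_clonal_heterozygous_limit(self):
        m = make_mut(alt_reads=50, total_reads=100)
        est = compute_ccf(m, DIPLOID, purity=1.0)
        assert est.multiplicity == 1 and est.ccf == pytest.approx(1.0)

    def test_half_clonal_limit(self):
        m = make_mut(alt_reads=25, total_reads=100)
        est = compute_ccf(m, DIPLOID, purity=1.0)
        assert est.ccf == pytest.approx(0.5)

    def test_matches_closed_form_on_grid(self):
        """50-case grid over vaf x purity x copy number vs the oracle."""
        cases = [
            (vaf, purity, cnt)
            for vaf in (0.05, 0.15, 0.3, 0.45, 0.6)
            for purity in (0.8, 0.9)
            for cnt in (1, 2, 3, 4, 6)
        ]
        assert len(cases) == 50
        for vaf, purity, cnt in cases:
            m = make_mut(alt_reads=int(vaf * 1000), total_reads=1000)
            seg = CopyNumberSegment("chr1", 1, 10**9, cnt, 0)
            est = compute_ccf(m, seg, purity)
            expected_ccf, expected_mult = ccf_oracle(m.vaf, purity, cnt)
            assert est.ccf == pytest.approx(expected_ccf, abs=1e-12)
            assert est.multiplicity == expected_mult

    def test_monotone_in_vaf(self):
        prev = -1.0
        for alt in range(1, 50):
            m = make_mut(alt_reads=alt, total_reads=100)
            est = compute_ccf(m, DIPLOID, purity=0.9)
            if est.multiplicity == 1:  # fixed multiplicity branch
                assert est.ccf > prev
                prev = est.ccf

    def test_missing_segment_falls_back_diploid(self):
        m = make_mut(alt_reads=45, total_reads=100)
        est = compute_ccf(m, None, purity=0.9)
        assert "no_covering_segment" in est.flags and est.tumor_cn == 2

    def test_cap_flagged(self):
        m = make_mut(alt_reads=95, total_reads=100)
        est = compute_ccf(m, DIPLOID, purity=0.5)
        assert est.ccf == 1.5 and "ccf_capped" in est.flags

    def test_invalid_purity(self):
        with pytest.raises(ValueError, match="purity"):
            compute_ccf(make_mut(), DIPLOID, purity=0.0)

    def test_segment_lookup(self):
        segs = [CopyNumberSegment("chr1", 1, 100, 3, 1), CopyNumberSegment("chr2", 1, 100, 2, 1)]
        assert segment_for(segs, "chr1", 50).total_cn == 3
        assert segment_for(segs, "chr3", 50) is None


class TestClusterPair:
    def test_single_tight_cluster_selects_k1(self, rng):
        e = 1.0 + rng.normal(0, 0.02, 120)
        l = 1.0 + rng.normal(0, 0.02, 120)
        sol = cluster_pair(e, l, seed=0)
        assert sol.k == 1
        assert sol.clusters[0][0] == pytest.approx(1.0, abs=0.05)

    def test_two_planted_clusters_recovered(self, rng):
        e = np.concatenate([rng.normal(0.9, 0.05, 100), rng.normal(0.1, 0.05, 100)])
        l = np.concatenate([rng.normal(0.1, 0.05, 100), rng.normal(0.9, 0.05, 100)])
        sol = cluster_pair(e, l, seed=1)
        assert sol.k == 2
        means = sorted((c[0], c[1]) for c in sol.clusters)
        assert means[0][0] == pytest.approx(0.1, abs=0.05)
        assert means[0][1] == pytest.approx(0.9, abs=0.05)
        assert means[1][0] == pytest.approx(0.9, abs=0.05)
        assert means[1][1] == pytest.approx(0.1, abs=0.05)

    def test_emerging_cluster_recovered(self, rng):
        e = np.concatenate([rng.normal(1.0, 0.05, 100), np.zeros(60)])
        l = np.concatenate([rng.normal(1.0, 0.05, 100), rng.normal(0.5, 0.05, 60)])
        sol = cluster_pair(e, l, seed=2)
        assert sol.k == 2
        low = min(sol.clusters, key=lambda c: c[0])
        assert low[0] == pytest.approx(0.0, abs=0.05)
        assert low[1] == pytest.approx(0.5, abs=0.06)

    def test_degraded_mode_below_min_variants(self):
        sol = cluster_pair([1.0] * 5, [1.0] * 5)
        assert sol.k == 1 and sol.warnings

    def test_too_few_variants_error(self):
        with pytest.raises(ValueError):
            cluster_pair([1.0], [1.0])


def solution(clusters):
    return CcfClusterSolution(
        clusters=[(e, l, 1 / len(clusters), 10) for (e, l) in clusters],
        assignments=np.zeros(1, dtype=int),
        model_score=0.0,
        k=len(clusters),
    )


class TestClassifyEvolution:
    @pytest.mark.parametrize(
        "clusters,expected",
        [
            ([(1.0, 1.0)], "stable"),
            ([(0.8, 0.05), (0.05, 0.85)], "differential"),
            ([(1.0, 1.0), (0.0, 0.4)], "linear"),
            ([(1.0, 1.0), (0.5, 0.45)], "stable"),
            # vanish + emerge without symmetric +-tau_shift moves
            ([(1.0, 1.0), (0.28, 0.02), (0.02, 0.27)], "differential"),
            # rise without any fall: linear-style emergence wins over stable
            ([(1.0, 1.0), (0.05, 0.9)], "linear"),
        ],
    )
    def test_rule_table(self, clusters, expected):
        assert classify_evolution(solution(clusters)).pattern == expected

    def test_rule_table_oracle_enumeration(self):
        """Exhaustive delta grid agrees with an independent rule transcription."""
        grid = np.round(np.linspace(0, 1, 6), 2)
        tau_shift, tau_new, tau_minor = 0.3, 0.25, 0.1

        def oracle(clusters):
            falls = [c for c in clusters if c[1] - c[0] <= -tau_shift]
            rises = [c for c in clusters if c[1] - c[0] >= tau_shift]
            van = [c for c in clusters if c[0] >= tau_new and c[1] < tau_minor]
            eme = [c for c in clusters if c[0] < tau_minor and c[1] >= tau_new]
            if (falls and rises) or (van and eme and set(van) != set(eme)):
                return "differential"
            if eme:
                return "linear"
            return "stable"

        for e1 in grid:
            for l1 in grid:
                for e2 in grid:
                    for l2 in grid:
                        clusters = [(float(e1), float(l1)), (float(e2), float(l2))]
                        got = classify_evolution(solution(clusters)).pattern
                        assert got == oracle(clusters), clusters

    def test_every_solution_gets_exactly_one_pattern(self, rng):
        for _ in range(200):
            k = int(rng.integers(1, 5))
            clusters = [(float(rng.uniform(0, 1.2)), float(rng.uniform(0, 1.2))) for _ in range(k)]
            call = classify_evolution(solution(clusters))
            assert call.pattern in ("stable", "linear", "differential")

    def test_evidence_nonempty_unless_stable(self):
        call = classify_evolution(solution([(0.8, 0.05), (0.05, 0.85)]))
        assert call.evidence


class TestRasShift:
    def test_no_ras_mutations(self):
        assert detect_ras_shift([]) == (False, {"falling": [], "rising": []})

    def test_shift_detected(self):
        shift, detail = detect_ras_shift(
            [("KRAS p.G12D", 0.8, 0.05), ("NRAS p.Q61K", 0.0, 0.7)]
        )
        assert shift
        assert detail["falling"] == ["KRAS p.G12D"]
        assert detail["rising"] == ["NRAS p.Q61K"]

    def test_stable_single_mutation(self):
        shift, _ = detect_ras_shift([("KRAS p.G12V", 0.9, 0.9)])
        assert not shift

    def test_same_mutation_cannot_shift_itself(self):
        # a lone rising mutation is not a replacement
        shift, _ = detect_ras_shift([("NRAS p.Q61K", 0.0, 0.8)])
        assert not shift

    def test_rule_oracle_grid(self):
        """Enumerated trajectory grid vs independent rule transcription."""
        levels = [0.0, 0.05, 0.3, 0.6, 0.9]
        tau_shift, tau_new, tau_minor = 0.3, 0.25, 0.1
        for e1 in levels:
            for l1 in levels:
                for e2 in levels:
                    for l2 in levels:
                        traj = [("A", e1, l1), ("B", e2, l2)]
                        got, _ = detect_ras_shift(traj)
                        falls = {
                            n
                            for n, e, l in traj
                            if e - l >= tau_shift or (e >= tau_new and l < tau_minor)
                        }
                        rises = {n for n, e, l in traj if l - e >= tau_new}
                        # a mutation cannot fall and rise at once, so a shift
                        # needs one of each (necessarily different mutations)
                        expected = bool(falls) and bool(rises)
                        assert got == expected, traj


class TestExpressedFraction:
    def test_hand_count(self):
        muts = [make_mut(pos=i + 1, rna_alt_reads=r) for i, r in enumerate([0, 0, 3, 5])]
        frac, flags = expressed_fraction(muts, min_rna_alt=2)
        assert frac == pytest.approx(0.5)
        assert flags == [False, False, True, True]

    def test_all_missing_rna_is_undefined(self):
        muts = [make_mut(pos=1), make_mut(pos=2)]
        frac, flags = expressed_fraction(muts)
        assert frac is None and flags == [None, None]

    def test_zero_threshold_vacuous(self):
        muts = [make_mut(pos=i + 1, rna_alt_reads=0) for i in range(4)]
        frac, _ = expressed_fraction(muts, min_rna_alt=0)
        assert frac == 1.0

    def test_records_without_rna_excluded_from_denominator(self):
        muts = [make_mut(pos=1, rna_alt_reads=5), make_mut(pos=2)]
        frac, _ = expressed_fraction(muts, min_rna_alt=1)
        assert frac == 1.0


class TestCnFlags:
    LOCI = {"1q21": ("chr1", 1000, 2000), "17p": ("chr17", 1, 500)}

    def test_gain_vs_amp_vs_del(self):
        segs = [
            CopyNumberSegment("chr1", 900, 2100, 3, 1),
            CopyNumberSegment("chr17", 1, 600, 1, 0),
        ]
        flags = cn_locus_flags(segs, self.LOCI)
        assert flags == {"gain1q": True, "amp1q21": False, "del17p": True}
        segs[0] = CopyNumberSegment("chr1", 900, 2100, 5, 1)
        assert cn_locus_flags(segs, self.LOCI)["amp1q21"]

    def test_diploid_everywhere(self):
        segs = [CopyNumberSegment("chr1", 1, 10**6, 2, 1)]
        assert cn_locus_flags(segs, self.LOCI) == {
            "gain1q": False, "amp1q21": False, "del17p": False,
        }
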