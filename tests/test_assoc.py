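import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cnvmap.core import AnnotationTrack, CNVCall, CnvmapError, Interval, PhenotypeTable
from cnvmap import assoc
from helpers import bh_stepup


def probe_map(*rows):
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])


SIMPLE_MAP = probe_map(("p1", "1", 150), ("p2", "1", 250), ("p3", "2", 100))


class TestAssignProbeCN:
    def test_probe_inside_call_gets_call_cn(self):
        calls = [CNVCall("A1", "1", 100, 201, cn=1)]
        m = assoc.assign_probe_cn(calls, SIMPLE_MAP, ["A1"])
        assert m.cn[0, 0] == 1  # p1 at 150 covered
        assert m.cn[1, 0] == 2  # p2 at 250 not covered
        assert m.cn[2, 0] == 2  # other chromosome

    def test_deviation_fraction(self):
        samples = [f"S{i}" for i in range(10)]
        calls = [CNVCall(s, "1", 100, 200, cn=3) for s in samples[:3]]
        m = assoc.assign_probe_cn(calls, SIMPLE_MAP, samples)
        assert m.deviation_fraction[0] == pytest.approx(0.3)
        assert m.deviation_fraction[1] == 0.0

    def test_overlapping_same_sample_calls_rejected(self):
        calls = [
            CNVCall("A1", "1", 100, 200, cn=1),
            CNVCall("A1", "1", 140, 300, cn=3),
        ]
        with pytest.raises(CnvmapError, match="A1") as err:
            assoc.assign_probe_cn(calls, SIMPLE_MAP, ["A1"])
        assert "p1" in str(err.value)  # probe in the overlapped stretch named


class TestSelectVariableProbes:
    def _matrix(self, dev_counts, n=100):
        pm = probe_map(*[(f"p{i}", "1", 100 * (i + 1)) for i in range(len(dev_counts))])
        cn = np.full((len(dev_counts), n), 2, dtype=np.int8)
        for i, k in enumerate(dev_counts):
            cn[i, :k] = 3
        return assoc.ProbeCNMatrix(pm, [f"S{j}" for j in range(n)], cn)

    def test_five_percent_boundary_inclusive(self):
        m = self._matrix([5, 4, 50])  # 0.05, 0.04, 0.50
        assert list(assoc.select_variable_probes(m)) == [0, 2]

    def test_all_diploid_gives_empty_selection(self):
        m = self._matrix([0, 0])
        assert len(assoc.select_variable_probes(m)) == 0


class TestProbeAssociation:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        cn = rng.choice([1, 2, 3], size=20).astype(np.int8)
        y = 2.0 * cn
        res = assoc.probe_association(cn, y)
        assert res.beta == pytest.approx(2.0)
        assert res.p_value < 1e-12
        assert res.n_used == 20

    def test_constant_cn_flagged_degenerate(self):
        res = assoc.probe_association(np.full(10, 3, np.int8), np.arange(10.0))
        assert res.degenerate and res.p_value == 1.0 and res.beta == 0.0

    def test_missing_phenotypes_dropped_pairwise(self):
        cn = np.array([1, 2, 3, 1, 2, 3], np.int8)
        y = np.array([1.0, 2.0, 3.0, np.nan, np.nan, np.nan])
        res = assoc.probe_association(cn, y)
        assert res.n_used == 3

    def test_matches_statsmodels_ols(self):
        rng = np.random.default_rng(1)
        cn = rng.choice([0, 1, 2, 3, 4], size=50).astype(np.int8)
        y = 0.5 * cn + rng.normal(size=50)
        res = assoc.probe_association(cn, y)
        fit = sm.OLS(y, sm.add_constant(cn.astype(float))).fit()
        assert res.beta == pytest.approx(fit.params[1])
        assert res.se == pytest.approx(fit.bse[1])
        assert res.p_value == pytest.approx(fit.pvalues[1])

    def test_permutation_p_tracks_analytic_p(self):
        rng = np.random.default_rng(6)
        cn = rng.choice([1, 2, 3], size=60).astype(np.int8)
        y = 0.4 * cn + rng.normal(size=60)
        analytic = assoc.probe_association(cn, y)
        empirical = assoc.probe_association(
            cn, y, n_perm=999, rng=np.random.default_rng(0)
        )
        assert empirical.p_value >= 1 / 1000
        assert empirical.beta == analytic.beta
        # both should call a real effect of this size significant
        assert analytic.p_value < 0.05 and empirical.p_value < 0.05

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(2)
        hits = 0
        n_probes, n = 1000, 50
        for _ in range(n_probes):
            cn = rng.choice([1, 2, 3], size=n).astype(np.int8)
            y = rng.normal(size=n)
            if assoc.probe_association(cn, y).p_value < 0.05:
                hits += 1
        lo, hi = 0.05 * n_probes - 3 * np.sqrt(n_probes * 0.05 * 0.95), \
                 0.05 * n_probes + 3 * np.sqrt(n_probes * 0.05 * 0.95)
        assert lo <= hits <= hi


class TestBuildSegments:
    def _matrix(self, cols, chroms=None, n=100):
        """cols: list of per-probe carrier counts; probes share carriers
        from the left so adjacent identity = 1 - |k_i - k_j|/n."""
        k = len(cols)
        chroms = chroms or ["1"] * k
        pm = probe_map(*[(f"p{i}", chroms[i], 100 * (i + 1)) for i in range(k)])
        cn = np.full((k, n), 2, dtype=np.int8)
        for i, carriers in enumerate(cols):
            cn[i, :carriers] = 3
        return assoc.ProbeCNMatrix(pm, [f"S{j}" for j in range(n)], cn)

    def test_high_identity_probes_chain(self):
        m = self._matrix([50, 46])  # identical in 96/100 samples
        segs = assoc.build_segments(np.array([0, 1]), m)
        assert len(segs) == 1 and segs[0].probe_ids == ["p0", "p1"]

    def test_low_identity_probes_split(self):
        m = self._matrix([50, 44])  # identical in 94/100
        segs = assoc.build_segments(np.array([0, 1]), m)
        assert [s.probe_ids for s in segs] == [["p0"], ["p1"]]

    def test_chromosome_break_always_splits(self):
        m = self._matrix([50, 50], chroms=["1", "2"])
        segs = assoc.build_segments(np.array([0, 1]), m)
        assert len(segs) == 2

    def test_singleton_probe(self):
        m = self._matrix([50])
        (seg,) = assoc.build_segments(np.array([0]), m)
        assert seg.probe_ids == ["p0"] and seg.n_probes == 1

    def test_segments_partition_selected_probes(self):
        rng = np.random.default_rng(3)
        m = self._matrix(list(rng.integers(5, 95, size=30)))
        selected = np.arange(30)
        segs = assoc.build_segments(selected, m)
        chained = [i for s in segs for i in s.probe_indices]
        assert chained == list(selected)

    def test_lowering_identity_never_increases_segments(self):
        rng = np.random.default_rng(4)
        m = self._matrix(list(rng.integers(5, 95, size=40)))
        selected = np.arange(40)
        counts = [
            len(assoc.build_segments(selected, m, identity_frac=f))
            for f in (1.0, 0.95, 0.8, 0.5, 0.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestScoreSegments:
    def _scored(self, pvals):
        pm = probe_map(*[(f"p{i}", "1", 100 * (i + 1)) for i in range(len(pvals))])
        cn = np.full((len(pvals), 10), 2, np.int8)
        cn[:, :3] = 3
        m = assoc.ProbeCNMatrix(pm, [f"S{j}" for j in range(10)], cn)
        seg = assoc.CNVSegment("SEG_1", "1", 100, 100 * len(pvals) + 1,
                               [f"p{i}" for i in range(len(pvals))],
                               list(range(len(pvals))))
        assocs = {
            f"p{i}": assoc.ProbeAssoc(f"p{i}", 1.0, 0.1, 10.0, p, 10)
            for i, p in enumerate(pvals)
        }
        return assoc.score_segments([seg], assocs, m)[0]

    def test_most_significant_probe_representative(self):
        seg = self._scored([0.2, 0.01, 0.05])
        assert seg.representative_probe == "p1" and seg.p_value == 0.01

    def test_tie_goes_to_leftmost(self):
        seg = self._scored([0.01, 0.01])
        assert seg.representative_probe == "p0"

    def test_state_counts_at_representative(self):
        seg = self._scored([0.5])
        assert seg.state_counts == {2: 7, 3: 3}


class TestFDR:
    def test_hand_computed_example(self):
        assert assoc.fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert assoc.fdr_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_one(self):
        assert assoc.fdr_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(CnvmapError):
            assoc.fdr_adjust([0.5, 0.0])
        with pytest.raises(CnvmapError):
            assoc.fdr_adjust([0.5, 1.5])

    def test_matches_textbook_stepup_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 60)))
            assert assoc.fdr_adjust(p) == pytest.approx(bh_stepup(p))


class TestAnnotateNeighbors:
    def _segment(self):
        return assoc.CNVSegment("SEG_1", "1", 1_000_000, 1_010_000, ["p1"], [0])

    def _genes(self, *ivs):
        return AnnotationTrack("genes", [Interval(*args) for args in ivs])

    def test_gene_100kb_upstream_included(self):
        seg = self._segment()
        track = self._genes(("1", 880_000, 900_000, "g"))  # ends 100 kb before
        assoc.annotate_neighbors([seg], track)
        assert [g.name for g, _ in seg.neighbor_genes] == ["g"]

    def test_gene_with_451kb_gap_excluded(self):
        seg = self._segment()
        track = self._genes(("1", 500_000, 549_000, "far"))  # gap 451 kb
        assoc.annotate_neighbors([seg], track)
        assert seg.neighbor_genes == []

    def test_overlapping_gene_at_distance_zero_and_ordering(self):
        seg = self._segment()
        track = self._genes(
            ("1", 900_000, 950_000, "near"),
            ("1", 1_005_000, 1_006_000, "inside"),
        )
        assoc.annotate_neighbors([seg], track)
        assert [(g.name, d) for g, d in seg.neighbor_genes] == [
            ("inside", 0),
            ("near", 50_001),
        ]


class TestModelInterface:
    def _dataset(self, seed=0, beta=1.5, n=120):
        rng = np.random.default_rng(seed)
        pm = probe_map(*[(f"p{i}", "1", 1000 * (i + 1)) for i in range(30)])
        samples = [f"S{i}" for i in range(n)]
        calls = []
        causal_carriers = rng.random(n) < 0.3
        for i, s in enumerate(samples):
            if causal_carriers[i]:  # covers probes p10..p12
                calls.append(CNVCall(s, "1", 10_500, 13_500, cn=3))
            if rng.random() < 0.2:  # an unrelated locus p20..p21
                calls.append(CNVCall(s, "1", 20_500, 22_500, cn=1))
        dosage = np.where(causal_carriers, 1.0, 0.0)
        y = beta * dosage + rng.normal(size=n)
        phenos = PhenotypeTable(dict(zip(samples, map(float, y))))
        return calls, pm, phenos, samples

    def test_causal_segment_attains_minimum_q(self):
        calls, pm, phenos, samples = self._dataset()
        res = assoc.CNVStateGWAS(calls, pm, phenos, samples=samples).fit()
        table = res.table
        best = table.loc[table["fdr_q"].idxmin()]
        assert best["fdr_q"] < 0.05
        assert best["start"] <= 11_000 <= best["end"] + 1000

    def test_permuted_phenotype_rarely_significant(self):
        clean = 0
        for seed in range(8):
            calls, pm, phenos, samples = self._dataset(seed=seed, beta=1.5)
            rng = np.random.default_rng(100 + seed)
            vals = list(phenos.values.values())
            rng.shuffle(vals)
            permuted = PhenotypeTable(dict(zip(phenos.values.keys(), vals)))
            res = assoc.CNVStateGWAS(calls, pm, permuted, samples=samples).fit()
            if len(res.significant(0.05)) == 0:
                clean += 1
        assert clean >= 7

    def test_empty_selection_gives_empty_table(self):
        pm = probe_map(("p1", "1", 100))
        phenos = PhenotypeTable({"S1": 1.0, "S2": 2.0})
        res = assoc.CNVStateGWAS([], pm, phenos, samples=["S1", "S2"]).fit()
        assert len(res.table) == 0

    def test_summary_and_run_cnv_gwas_wrapper(self):
        calls, pm, phenos, samples = self._dataset()
        res = assoc.CNVStateGWAS(calls, pm, phenos, samples=samples).fit()
        text = res.summary()
        assert "segments" in text and "q < 0.05" in text
        table = assoc.run_cnv_gwas(calls, pm, phenos, samples=samples)
        pd.testing.assert_frame_equal(table, res.table)

    def test_state_counts_sum_to_phenotyped_samples(self):
        calls, pm, phenos, samples = self._dataset()
        res = assoc.CNVStateGWAS(calls, pm, phenos, samples=samples).fit()
        for seg in res.segments:
            assert sum(seg.state_counts.values()) == len(samples)
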