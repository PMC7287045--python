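"""Graph dedup, stitching, LCNV clustering, generic merge — vs brute force."""

import numpy as np
import pytest

from conftest import make_matrix, make_record
from oracles import dedup_speedseq_oracle, lcnv_oracle, merge_generic_oracle, ro_oracle
from svharmony.model_io import GenotypeMatrix
from svharmony.redundancy import (
    cluster_lcnv,
    dedup_genomestrip,
    dedup_speedseq,
    merge_generic,
    reciprocal_overlap,
    stitch_genomestrip,
    validate_stitch,
)


class TestReciprocalOverlap:
    def test_identical_and_disjoint(self):
        assert reciprocal_overlap(("c", 100, 200), ("c", 100, 200)) == (1.0, 1.0)
        assert reciprocal_overlap(("c", 100, 200), ("c", 300, 400)) == (0.0, 0.0)
        assert reciprocal_overlap(("c1", 100, 200), ("c2", 100, 200)) == (0.0, 0.0)

    def test_half_overlap_arithmetic(self):
        assert reciprocal_overlap(("c", 100, 200), ("c", 150, 250)) == (0.5, 0.5)

    def test_matches_oracle_on_random_intervals(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            s1, s2 = rng.integers(0, 1000, size=2)
            a = ("c", s1, s1 + rng.integers(1, 500))
            b = ("c", s2, s2 + rng.integers(1, 500))
            assert reciprocal_overlap(a, b) == ro_oracle(a, b)


def _ab_matrix(site_ids, ab_rows):
    ab = np.asarray(ab_rows, dtype=float)
    gt = np.zeros_like(ab, dtype=np.int16)
    return GenotypeMatrix(site_ids, [f"s{j}" for j in range(ab.shape[1])],
                          gt=gt, ab=np.clip(ab, 0, 1))


class TestDedupSpeedseq:
    def test_correlated_overlap_collapses_to_max_msq(self):
        a = make_record("a", start=1000, end=2000, quality={"MSQ": 80})
        b = make_record("b", start=1400, end=2400, quality={"MSQ": 60})
        ab = _ab_matrix(["a", "b"], [[0.0, 0.5, 1.0, 0.5, 0.0],
                                     [0.02, 0.48, 0.97, 0.5, 0.01]])
        clusters, kept = dedup_speedseq([a, b], ab)
        assert len(clusters) == 1
        assert clusters[0].primary_id == "a"
        assert [r.site_id for r in kept] == ["a"]

    def test_uncorrelated_overlap_keeps_both(self):
        a = make_record("a", start=1000, end=2000, quality={"MSQ": 80})
        b = make_record("b", start=1400, end=2400, quality={"MSQ": 60})
        ab = _ab_matrix(["a", "b"], [[0.0, 0.5, 1.0, 0.5, 0.0],
                                     [1.0, 0.0, 0.1, 0.2, 0.9]])
        clusters, kept = dedup_speedseq([a, b], ab)
        assert clusters == []
        assert {r.site_id for r in kept} == {"a", "b"}

    def test_containment_rule_with_ab_half_correlation(self):
        outer = make_record("outer", start=1000, end=5000, quality={"MSQ": 90})
        inner = make_record("inner", start=2000, end=3000, quality={"MSQ": 40})
        # RO of inner in outer is 1.0 vs 0.25 for outer -> no 50% RO edge
        ab = _ab_matrix(["outer", "inner"], [[0.0, 0.5, 1.0, 0.5, 0.0],
                                             [0.0, 0.5, 1.0, 0.5, 0.0]])
        clusters, kept = dedup_speedseq([outer, inner], ab)
        assert len(clusters) == 1
        assert [r.site_id for r in kept] == ["outer"]

    def test_matches_bruteforce_oracle_on_random_sets(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            n = int(rng.integers(5, 40))
            recs, rows = [], []
            for i in range(n):
                start = int(rng.integers(0, 20_000))
                length = int(rng.integers(200, 3000))
                recs.append(make_record(f"r{i:03d}", start=start, end=start + length,
                                        quality={"MSQ": float(rng.integers(10, 200))}))
                base = rng.choice([0.0, 0.5, 1.0], size=8)
                rows.append(np.clip(base + rng.normal(0, 0.2, 8), 0, 1))
            gm = _ab_matrix([r.site_id for r in recs], rows)
            clusters, kept = dedup_speedseq(recs, gm)
            comps, survivors = dedup_speedseq_oracle(recs, gm)
            got_comps = sorted([sorted(c.members) for c in clusters]
                               + [[r.site_id] for r in kept
                                  if all(r.site_id not in c.members for c in clusters)],
                               key=lambda c: c[0])
            assert got_comps == comps
            assert {r.site_id for r in kept} == survivors


def _cn_matrix(site_ids, cn_rows, gt_rows=None):
    cn = np.asarray(cn_rows, dtype=float)
    gt = (np.asarray(gt_rows, dtype=np.int16) if gt_rows is not None
          else np.zeros_like(cn, dtype=np.int16))
    return GenotypeMatrix(site_ids, [f"s{j}" for j in range(cn.shape[1])],
                          gt=gt, cn=cn)


class TestDedupGenomestrip:
    def _two_sets(self, coords_b, cn_b, qual_a=30.0, qual_b=20.0):
        a = make_record("a1", caller="genomestrip", start=1000, end=3000,
                        quality={"GSCNQUAL": qual_a})
        b = make_record("b1", caller="genomestrip", start=coords_b[0], end=coords_b[1],
                        quality={"GSCNQUAL": qual_b})
        cn_a = [1, 1, 2, 2, 2, 1, 2, 2]
        gm_a = _cn_matrix(["a1"], [cn_a])
        gm_b = _cn_matrix(["b1"], cn_b)
        return [a], [b], gm_a, gm_b

    def test_exact_overlap_resolved_by_quality_sum(self):
        sa, sb, gm_a, gm_b = self._two_sets((1000, 3000), [[1, 1, 2, 2, 2, 1, 2, 2]])
        clusters, kept = dedup_genomestrip(sa, sb, gm_a, gm_b, gm_a.sample_ids)
        assert len(clusters) == 1
        assert clusters[0].primary_id == "a1"
        assert clusters[0].provenance == "gs_dedup_exact"
        assert [r.site_id for r in kept] == ["a1"]

    def test_cn_correlation_below_threshold_not_redundant(self):
        sa, sb, gm_a, gm_b = self._two_sets((1200, 3200), [[2, 1, 1, 2, 2, 2, 1, 2]])
        clusters, kept = dedup_genomestrip(sa, sb, gm_a, gm_b, gm_a.sample_ids)
        assert clusters == []
        assert len(kept) == 2

    def test_nonmode_difference_blocks_merge(self):
        # perfectly correlated shapes but >5% of non-mode genotypes differ
        cn_a = [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 2, 2, 2, 2, 2, 2, 2, 2, 2]
        cn_b = [1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 2, 2, 2, 2, 2, 2, 2, 2, 2]
        a = make_record("a1", caller="genomestrip", start=1000, end=3000,
                        quality={"GSCNQUAL": 30})
        b = make_record("b1", caller="genomestrip", start=1100, end=3100,
                        quality={"GSCNQUAL": 20})
        gm_a = _cn_matrix(["a1"], [cn_a])
        gm_b = _cn_matrix(["b1"], [cn_b])
        r = np.corrcoef(cn_a, cn_b)[0, 1]
        clusters, kept = dedup_genomestrip([a], [b], gm_a, gm_b, gm_a.sample_ids)
        if r > 0.95:
            assert clusters == []  # blocked by the non-mode difference rule
        assert len(kept) == 2

    def test_empty_non_ipsc_rejected(self):
        sa, sb, gm_a, gm_b = self._two_sets((1000, 3000), [[1, 1, 2, 2, 2, 1, 2, 2]])
        with pytest.raises(ValueError, match="non-iPSC"):
            dedup_genomestrip(sa, sb, gm_a, gm_b, [])


class TestStitching:
    def _identical_rows(self, n_sites, n_samples=24, seed=0):
        rng = np.random.default_rng(seed)
        row = rng.choice([1, 1, 2, 2, 2, 3], size=n_samples).astype(float)
        if np.unique(row).size == 1:
            row[0] += 1
        return np.tile(row, (n_sites, 1))

    def test_adjacent_identical_genotypes_stitched(self):
        a = make_record("a", caller="genomestrip", start=1000, end=2000,
                        quality={"GSCNQUAL": 20})
        b = make_record("b", caller="genomestrip", start=2500, end=3500,
                        quality={"GSCNQUAL": 20})
        gm = _cn_matrix(["a", "b"], self._identical_rows(2))
        out = stitch_genomestrip([a, b], gm)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (1000, 3500)
        assert out[0].constituents == ["a", "b"]

    def test_gap_over_30kb_not_stitched(self):
        a = make_record("a", caller="genomestrip", start=1000, end=2000,
                        quality={"GSCNQUAL": 20})
        b = make_record("b", caller="genomestrip", start=33_001, end=34_000,
                        quality={"GSCNQUAL": 20})
        gm = _cn_matrix(["a", "b"], self._identical_rows(2))
        assert stitch_genomestrip([a, b], gm) == []

    def test_low_concordance_not_stitched(self):
        # correlated overall but only ~70% concordant among non-mode samples
        base = np.array([1, 1, 1, 1, 1, 1, 1, 0, 0, 0] + [2] * 20, dtype=float)
        other = base.copy()
        other[7:10] = 1  # three of ten non-mode samples disagree
        r = np.corrcoef(base, other)[0, 1]
        assert r > 0.9
        a = make_record("a", caller="genomestrip", start=1000, end=2000,
                        quality={"GSCNQUAL": 20})
        b = make_record("b", caller="genomestrip", start=2500, end=3500,
                        quality={"GSCNQUAL": 20})
        gm = _cn_matrix(["a", "b"], np.vstack([base, other]))
        assert stitch_genomestrip([a, b], gm) == []

    def test_containing_cnv_is_preexisting_breakpoint(self):
        big = make_record("big", caller="genomestrip", start=1000, end=9000,
                          quality={"GSCNQUAL": 20})
        small = make_record("small", caller="genomestrip", start=2000, end=3000,
                            quality={"GSCNQUAL": 20})
        gm = _cn_matrix(["big", "small"], self._identical_rows(2))
        out = stitch_genomestrip([big, small], gm)
        assert len(out) == 1
        assert out[0].is_preexisting_breakpoint
        assert (out[0].start, out[0].end) == (1000, 9000)

    def test_validate_stitch_rules(self):
        row = np.array([1, 2, 2, 1, 2, 2, 3, 2], dtype=float)
        assert validate_stitch(row, [row, row], lq_fraction=0.0) == "stitched"
        noisy = np.array([2, 1, 2, 2, 1, 2, 2, 3], dtype=float)
        assert validate_stitch(noisy, [row, row], lq_fraction=0.0) == "unstitched"
        assert validate_stitch(row, [row], lq_fraction=0.11) == "filtered"
        flat = np.full(8, 2.0)
        assert validate_stitch(flat, [row], lq_fraction=0.0) == "filtered"


class TestClusterLCNV:
    def test_three_way_merge_spans_union(self):
        recs = [make_record(f"x{i}", caller="gs_lcnv", start=100_000 + i * 1000,
                            end=300_000 + i * 1000) for i in range(3)]
        merged, clusters = cluster_lcnv(recs)
        assert len(merged) == 1
        assert merged[0]["start"] == 100_000
        assert merged[0]["end"] == 302_000
        assert len(clusters) == 1

    def test_ro_below_80pct_stays_separate(self):
        a = make_record("a", caller="gs_lcnv", start=100_000, end=200_000)
        b = make_record("b", caller="gs_lcnv", start=170_000, end=270_000)  # RO 0.3
        merged, clusters = cluster_lcnv([a, b])
        assert len(merged) == 2
        assert clusters == []

    def test_singleton_passes_through(self):
        a = make_record("solo", caller="gs_lcnv", start=100_000, end=200_000)
        merged, clusters = cluster_lcnv([a])
        assert merged[0]["site_id"] == "solo"
        assert merged[0]["members"] == ["solo"]

    def test_cn_rounded_to_integers(self):
        a = make_record("a", caller="gs_lcnv", start=100_000, end=200_000)
        gm = _cn_matrix(["a"], [[2.4, 2.6, np.nan, 1.2]])
        cluster_lcnv([a], gm)
        assert np.allclose(gm.cn[0], [2, 3, np.nan, 1], equal_nan=True)

    def test_matches_oracle_on_random_sets(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            recs = []
            for i in range(n):
                start = int(rng.integers(0, 2_000_000))
                recs.append(make_record(f"v{i:03d}", caller="gs_lcnv", start=start,
                                        end=start + int(rng.integers(100_000, 400_000))))
            merged, _ = cluster_lcnv(recs)
            got = sorted((m["start"], m["end"], tuple(sorted(m["members"]))) for m in merged)
            want = [(s, e, tuple(m)) for s, e, m in lcnv_oracle(recs)]
            assert got == want


class TestMergeGeneric:
    def test_cross_caller_support_count(self):
        w = make_record("w1", caller="wham", start=1000, end=2000, quality={"QUAL": 300})
        m = make_record("m1", caller="manta", start=1100, end=2100, quality={"QUAL": 300})
        merged = merge_generic({"wham": [w], "manta": [m]})
        assert len(merged) == 1
        assert merged[0]["support"] == 2
        assert (merged[0]["start"], merged[0]["end"]) == (1000, 2100)

    def test_class_mismatch_blocks_edge(self):
        w = make_record("w1", caller="wham", start=1000, end=2000)
        m = make_record("m1", caller="manta", start=1000, end=2000, svtype="DUP")
        merged = merge_generic({"wham": [w], "manta": [m]})
        assert len(merged) == 2

    def test_transitive_chain_single_component(self):
        a = make_record("a", caller="wham", start=0 + 1, end=1001)
        b = make_record("b", caller="manta", start=500, end=1500)
        c = make_record("c", caller="genomestrip", start=1000, end=2000)
        fa_ac = reciprocal_overlap(a.interval(), c.interval())
        assert min(fa_ac) < 0.5  # a-c alone would not connect
        merged = merge_generic({"wham": [a], "manta": [b], "genomestrip": [c]})
        assert len(merged) == 1
        assert merged[0]["members"] == ["a", "b", "c"]

    def test_matches_oracle_on_random_sets(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            recs = {"wham": [], "manta": []}
            for i in range(int(rng.integers(4, 30))):
                caller = "wham" if rng.random() < 0.5 else "manta"
                start = int(rng.integers(0, 50_000))
                svtype = "DEL" if rng.random() < 0.7 else "DUP"
                recs[caller].append(
                    make_record(f"{caller}_{i:03d}", caller=caller, start=start,
                                end=start + int(rng.integers(200, 4000)), svtype=svtype)
                )
            merged = merge_generic(recs)
            got = sorted([sorted(m["members"]) for m in merged], key=lambda c: c[0])
            want = merge_generic_oracle(recs["wham"] + recs["manta"])
            assert got == want


class TestClusterRecoveryOnPlantedDuplicates:
    def test_planted_duplicates_recovered_exactly(self):
        """With small jitter, within-caller duplicates collapse onto their
        planted truth sites (adjusted Rand index 1 on duplicated sites)."""
        from svharmony import SimConfig, simulate_bundle

        cfg = SimConfig(seed=41, n_donors=60, n_twin_pairs=5, n_fib_ipsc_pairs=5,
                        duplicate_prob=1.0, n_false_positives=0,
                        fragmentation_prob=0.0, jitter_bound=5,
                        uniform_error=0.0, site_counts={"DEL": 30})
        b = simulate_bundle(cfg)
        recs, gm = b.views["speedseq"]
        clusters, kept = dedup_speedseq(recs, gm)
        truth_of = b.provenance.set_index("site_id")["truth_id"]
        for c in clusters:
            assert len({truth_of[m] for m in c.members}) == 1
        # each truth site ends with exactly one surviving record
        survivors = [truth_of[r.site_id] for r in kept]
        assert len(survivors) == len(set(survivors))
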