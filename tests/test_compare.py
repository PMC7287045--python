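"""External comparison: co-discovery rules, AF concordance, LD, IRS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_record
from oracles import co_discovery_oracle, max_r2_oracle
from svharmony import SimConfig, simulate_cohort, simulate_truth
from svharmony.compare import (
    af_concordance,
    co_discovery,
    co_discovery_insertions,
    irs_test,
    ld_tagging,
    match_pair,
    residualize,
)
from svharmony.model_io import GenotypeMatrix
from svharmony.synthgen import emit_probe_intensities, emit_snp_panel


class TestCoDiscoveryRules:
    def test_25pct_reciprocal_overlap_matches(self):
        q = make_record("q", start=0 + 1, end=1001)
        t = make_record("t", start=201, end=1101)
        m = match_pair(q, t)
        assert m is not None and m.rule_used == "reciprocal"

    def test_boundary_exact_quarter_overlap(self):
        # overlap 250 of len 1000 -> fractions exactly 0.25
        q = make_record("q", start=1000, end=2000)
        t = make_record("t", start=1750, end=2750)
        assert match_pair(q, t) is not None
        t2 = make_record("t2", start=1751, end=2751)
        assert match_pair(q, t2) is None

    def test_containment_20pct_boundary(self):
        q = make_record("q", start=1000, end=2000)
        inside_ok = make_record("a", start=1200, end=1400)   # 20% of larger
        inside_no = make_record("b", start=1200, end=1390)   # 19%
        assert match_pair(q, inside_ok).rule_used == "containment"
        assert match_pair(q, inside_no) is None

    def test_inversions_need_80pct(self):
        q = make_record("q", svtype="INV", start=1000, end=2000)
        half = make_record("h", svtype="INV", start=1500, end=2500)
        tight = make_record("t", svtype="INV", start=1100, end=2050)
        assert match_pair(q, half) is None
        m = match_pair(q, tight)
        assert m is not None

    def test_breakends_within_50bp(self):
        q = make_record("q", svtype="BND", start=1000)
        at50 = make_record("a", svtype="BND", start=1050)
        at51 = make_record("b", svtype="BND", start=1051)
        assert match_pair(q, at50).distance == 50
        assert match_pair(q, at51) is None

    def test_mcnv_matches_del_and_dup_only(self):
        m = make_record("m", svtype="mCNV", start=1000, end=2000)
        for other, want in (("DEL", True), ("DUP", True), ("INV", False), ("rMEI", False)):
            t = make_record("t", svtype=other, start=1000, end=2000)
            assert (match_pair(m, t) is not None) is want

    def test_matches_exhaustive_oracle_on_random_sets(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            def random_set(prefix, n):
                out = []
                for i in range(n):
                    svtype = str(rng.choice(["DEL", "DUP", "mCNV", "INV", "BND"]))
                    start = int(rng.integers(0, 40_000))
                    out.append(make_record(f"{prefix}{i:03d}", svtype=svtype,
                                           start=start,
                                           end=start + int(rng.integers(100, 4000))))
                return out

            query, target = random_set("q", 30), random_set("t", 30)
            matches, _ = co_discovery(query, target)
            got = {(m.query_id, m.target_id) for m in matches}
            assert got == co_discovery_oracle(query, target)

    def test_captured_fraction_counts_clusters_once(self):
        q1 = make_record("q1", start=1000, end=2000)
        q2 = make_record("q2", start=1010, end=2010)  # same cluster as q1
        q3 = make_record("q3", start=9000, end=9900)
        t = make_record("t", start=1000, end=2000)
        matches, summary = co_discovery(
            [q1, q2, q3], [t],
            query_nmaf={"q1": 0.2, "q2": 0.2, "q3": 0.2},
            clusters={"q1": "c1", "q2": "c1"},
        )
        all_row = summary[summary["bin"] == "all"].iloc[0]
        assert all_row["n_sites"] == 2  # c1 + q3
        assert all_row["captured_fraction"] == pytest.approx(0.5)


class TestInsertionMatching:
    def test_distance_and_fold_rules(self):
        q = make_record("q", svtype="ALU", start=1000, sv_len=300)
        near = make_record("a", svtype="ALU", start=1030, sv_len=400)
        farlen = make_record("b", svtype="ALU", start=1030, sv_len=601)
        far = make_record("c", svtype="ALU", start=1051, sv_len=300)
        assert len(co_discovery_insertions([q], [near])) == 1
        assert co_discovery_insertions([q], [farlen]) == []  # ratio > 2
        assert co_discovery_insertions([q], [far]) == []  # 51 bp away

    def test_exact_twofold_excluded(self):
        q = make_record("q", svtype="ALU", start=1000, sv_len=300)
        double = make_record("d", svtype="ALU", start=1000, sv_len=600)
        assert co_discovery_insertions([q], [double]) == []


class TestAFConcordance:
    def test_identical_afs_r_one(self):
        from svharmony.compare import OverlapMatch

        matches = [OverlapMatch(f"q{i}", f"t{i}", "reciprocal") for i in range(5)]
        afs = {f"q{i}": 0.1 * (i + 1) for i in range(5)}
        tfs = {f"t{i}": 0.1 * (i + 1) for i in range(5)}
        r, table = af_concordance(matches, afs, tfs)
        assert r == pytest.approx(1.0)

    def test_two_pairs_na(self):
        from svharmony.compare import OverlapMatch

        matches = [OverlapMatch("q0", "t0", "reciprocal"),
                   OverlapMatch("q1", "t1", "reciprocal")]
        r, _ = af_concordance(matches, {"q0": 0.1, "q1": 0.4}, {"t0": 0.1, "t1": 0.4})
        assert np.isnan(r)

    def test_shared_truth_sampling_noise_high_r(self):
        """Two binomial resamplings of the same AFs stay correlated > 0.9."""
        rng = np.random.default_rng(31)
        from svharmony.compare import OverlapMatch

        true_af = rng.uniform(0.05, 0.5, size=200)
        n_a, n_b = 400, 400
        af_a = rng.binomial(n_a, true_af) / n_a
        af_b = rng.binomial(n_b, true_af) / n_b
        matches = [OverlapMatch(f"q{i}", f"t{i}", "reciprocal") for i in range(200)]
        r, _ = af_concordance(matches,
                              {f"q{i}": af_a[i] for i in range(200)},
                              {f"t{i}": af_b[i] for i in range(200)})
        assert r > 0.9


class TestLDTagging:
    def _setup(self, eps, seed=8):
        cfg = SimConfig(seed=seed, n_donors=80, n_twin_pairs=2, n_fib_ipsc_pairs=2,
                        snp_flip_eps=eps, site_counts={"DEL": 6, "DUP": 4})
        samples, _ = simulate_cohort(cfg)
        truth = simulate_truth(cfg, samples)
        snp_gt, positions = emit_snp_panel(truth, cfg)
        recs, gt_rows = [], []
        for t in truth.sites:
            recs.append(make_record(t.truth_id, svtype=t.svtype, chrom=t.chrom,
                                    start=t.start, end=t.end))
            gt_rows.append(t.gt)
        gm = GenotypeMatrix([r.site_id for r in recs], truth.sample_ids,
                            gt=np.asarray(gt_rows, dtype=np.int16))
        return recs, gm, snp_gt, positions

    def test_perfect_tag_gives_r2_one(self):
        recs, gm, snp_gt, positions = self._setup(eps=0.0)
        results = {r.sv_id: r for r in ld_tagging(recs, gm, snp_gt, positions)}
        for rec in recs:
            if gm.gt_row(rec.site_id).std() == 0:
                continue
            assert results[rec.site_id].max_r2 == pytest.approx(1.0)

    def test_no_snp_in_window_is_na(self):
        rec = make_record("lonely", chrom="chr3", start=5_000_000, end=5_001_000)
        gm = GenotypeMatrix(["lonely"], ["a", "b", "c"],
                            gt=np.array([[0, 1, 2]], dtype=np.int16))
        positions = pd.DataFrame({"snp_id": ["s1"], "chrom": ["chr1"], "pos": [100]})
        out = ld_tagging([rec], gm, np.array([[0, 1, 2]]), positions)
        assert np.isnan(out[0].max_r2)
        assert out[0].n_partners == 0

    def test_matches_exhaustive_oracle(self):
        recs, gm, snp_gt, positions = self._setup(eps=0.1, seed=10)
        results = {r.sv_id: r for r in ld_tagging(recs, gm, snp_gt, positions)}
        chroms = positions["chrom"].to_numpy()
        poss = positions["pos"].to_numpy()
        for rec in recs:
            dosage = gm.gt_row(rec.site_id).astype(float)
            want = max_r2_oracle(dosage, snp_gt, poss, chroms, rec.chrom,
                                 rec.start, rec.end, 50_000)
            got = results[rec.site_id].max_r2
            if want is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)


class TestIRS:
    def _bundle(self, sigma, seed=14):
        cfg = SimConfig(seed=seed, n_donors=60, n_twin_pairs=2, n_fib_ipsc_pairs=2,
                        probe_sigma=sigma, site_counts={"DEL": 15, "DUP": 10})
        samples, _ = simulate_cohort(cfg)
        truth = simulate_truth(cfg, samples)
        probe_df, matrix, covariates = emit_probe_intensities(truth, samples, cfg)
        recs, gt_rows = [], []
        for t in truth.sites:
            recs.append(make_record(t.truth_id, svtype=t.svtype, chrom=t.chrom,
                                    start=t.start, end=t.end))
            gt_rows.append(t.gt)
        gm = GenotypeMatrix([r.site_id for r in recs], truth.sample_ids,
                            gt=np.asarray(gt_rows, dtype=np.int16))
        return recs, gm, probe_df, matrix, covariates

    def test_perfect_separation_fdr_zero(self):
        recs, gm, probe_df, matrix, covariates = self._bundle(sigma=1e-6)
        table, fdr = irs_test(recs, gm, matrix, probe_df, covariates)
        tested = table[table["p"].notna()]
        assert len(tested) > 5
        # singleton-carrier sites bottom out at the discrete minimum ~1/(n+1)
        assert (tested["p"] < 0.05).all()
        assert fdr == 0.0

    def test_sites_with_too_few_probes_skipped(self):
        recs, gm, probe_df, matrix, covariates = self._bundle(sigma=0.2)
        short = make_record("tiny", start=10, end=100)
        gm2 = GenotypeMatrix(gm.site_ids + ["tiny"], gm.sample_ids,
                             gt=np.vstack([gm.gt, np.ones((1, len(gm.sample_ids)),
                                                          np.int16)]))
        table, _ = irs_test(recs + [short], gm2, matrix, probe_df, covariates)
        row = table.set_index("site_id").loc["tiny"]
        assert row["skipped"] == "too_few_probes"
        assert np.isnan(row["p"])

    def test_permuted_genotypes_give_uniform_p(self):
        recs, gm, probe_df, matrix, covariates = self._bundle(sigma=0.3, seed=20)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(gm.sample_ids))
        gm_perm = GenotypeMatrix(gm.site_ids, gm.sample_ids, gt=gm.gt[:, perm])
        table, fdr = irs_test(recs, gm_perm, matrix, probe_df, covariates)
        ps = table["p"].dropna().to_numpy()
        assert len(ps) > 10
        # null p-values should not pile up near zero
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        assert fdr > 0.5

    def test_residualization_recovers_batch_offsets(self):
        """Planted batch/plate offsets vanish after least-squares removal."""
        rng = np.random.default_rng(5)
        n = 120
        batch = rng.integers(0, 3, n)
        offsets = np.array([0.0, 1.0, -1.0])
        matrix = offsets[batch] + rng.normal(0, 0.01, (10, n))
        cov = pd.DataFrame({"sample_id": [f"s{j}" for j in range(n)], "batch": batch})
        resid = residualize(matrix, cov)
        for b in range(3):
            assert abs(resid[:, batch == b].mean()) < 0.01
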