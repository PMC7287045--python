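"""Comparison against external call sets, LD tagging, and array-intensity
(IRS) validation.

Co-discovery matching rules: interval classes need >= 25% reciprocal overlap
or full containment with the inner variant spanning >= 20% of the larger;
inversions need 80% reciprocal overlap; breakends match within 50 bp;
insertions match within 50 bp and less than a twofold length difference.
Classes must be equal except that mCNVs may match deletions or duplications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_io import MISSING_GT, GenotypeMatrix
from .redundancy import contains, reciprocal_overlap


@dataclass
class OverlapMatch:
    query_id: str
    target_id: str
    rule_used: str  # reciprocal | containment | breakend_distance | insertion_distance
    frac_query: float = np.nan
    frac_target: float = np.nan
    distance: float = np.nan


@dataclass
class LDResult:
    sv_id: str
    best_partner_id: str | None
    max_r2: float  # nan when no partner in window
    n_partners: int


_POINT = frozenset({"BND"})
_INSERTION = frozenset({"INS", "ALU", "LINE1", "SVA"})
_CNV_LIKE = frozenset({"DEL", "DUP", "mCNV", "rMEI"})


def _class_compatible(a: str, b: str) -> bool:
    if a == b:
        return True
    pair = frozenset({a, b})
    return "mCNV" in pair and (pair & {"DEL", "DUP"})


def match_pair(q, t, min_ro=0.25, containment_frac=0.2, inv_ro=0.8, bnd_dist=50):
    """Test one query/target record pair under the class-appropriate rule.

    Returns an OverlapMatch or None.
    """
    if not _class_compatible(q.svtype, t.svtype):
        return None
    if q.svtype in _POINT or t.svtype in _POINT:
        if q.chrom != t.chrom:
            return None
        d = abs(q.start - t.start)
        if d <= bnd_dist:
            return OverlapMatch(q.site_id, t.site_id, "breakend_distance", distance=d)
        return None
    if q.svtype == "INV":
        fa, fb = reciprocal_overlap(q.interval(), t.interval())
        if min(fa, fb) >= inv_ro:
            return OverlapMatch(q.site_id, t.site_id, "reciprocal", fa, fb)
        return None
    fa, fb = reciprocal_overlap(q.interval(), t.interval())
    if min(fa, fb) >= min_ro:
        return OverlapMatch(q.site_id, t.site_id, "reciprocal", fa, fb)
    if contains(q.interval(), t.interval()) or contains(t.interval(), q.interval()):
        small_len = min(q.length, t.length)
        large_len = max(q.length, t.length)
        if small_len >= containment_frac * large_len:
            return OverlapMatch(q.site_id, t.site_id, "containment", fa, fb)
    return None


def co_discovery(query_set, target_set, query_nmaf=None, clusters=None,
                 min_ro=0.25, containment_frac=0.2, inv_ro=0.8, bnd_dist=50,
                 nmaf_split=0.05):
    """All-pairs co-discovery matching plus captured fractions by NMAF bin.

    ``clusters`` optionally maps query site_id -> cluster id so that
    redundancy clusters count as a single site in the captured fraction.
    Returns (matches, summary DataFrame with common/rare captured fractions).
    """
    matches = []
    matched_queries = set()
    for q in query_set:
        for t in target_set:
            m = match_pair(q, t, min_ro, containment_frac, inv_ro, bnd_dist)
            if m is not None:
                matches.append(m)
                matched_queries.add(q.site_id)
    cluster_of = clusters or {}
    units = {}
    for q in query_set:
        unit = cluster_of.get(q.site_id, q.site_id)
        hit = q.site_id in matched_queries
        af = query_nmaf.get(q.site_id, np.nan) if query_nmaf else np.nan
        if unit in units:
            units[unit] = (units[unit][0] or hit, units[unit][1])
        else:
            units[unit] = (hit, af)
    rows = []
    for bin_name in ("common", "rare", "all"):
        if bin_name == "common":
            sel = [(h, a) for h, a in units.values() if np.isfinite(a) and a > nmaf_split]
        elif bin_name == "rare":
            sel = [(h, a) for h, a in units.values() if np.isfinite(a) and a < nmaf_split]
        else:
            sel = list(units.values())
        n = len(sel)
        rows.append({"bin": bin_name, "n_sites": n,
                     "captured_fraction": (sum(h for h, _ in sel) / n) if n else np.nan})
    return matches, pd.DataFrame(rows, columns=["bin", "n_sites", "captured_fraction"])


def co_discovery_insertions(query_points, target_points, max_dist=50, max_fold=2.0):
    """Insertion matching: breakpoints within 50 bp and < twofold length
    difference."""
    matches = []
    for q in query_points:
        if q.sv_len <= 0:
            raise ValueError(f"insertion {q.site_id} has non-positive length")
        for t in target_points:
            if t.sv_len <= 0:
                raise ValueError(f"insertion {t.site_id} has non-positive length")
            if q.chrom != t.chrom:
                continue
            d = abs(q.start - t.start)
            if d > max_dist:
                continue
            fold = max(q.sv_len, t.sv_len) / min(q.sv_len, t.sv_len)
            if fold < max_fold:
                matches.append(OverlapMatch(q.site_id, t.site_id, "insertion_distance",
                                            distance=d))
    return matches


def af_concordance(matches, query_af, target_af):
    """Pearson r of allele frequencies across matched pairs (nan if < 3)."""
    pairs = [(query_af[m.query_id], target_af[m.target_id]) for m in matches
             if m.query_id in query_af and m.target_id in target_af]
    table = pd.DataFrame(pairs, columns=["query_af", "target_af"])
    if len(table) < 3 or table["query_af"].std() == 0 or table["target_af"].std() == 0:
        return np.nan, table
    r = float(np.corrcoef(table["query_af"], table["target_af"])[0, 1])
    return r, table


# ---------------------------------------------------------------------------
# LD tagging


def _sv_dosage(rec, gmatrix: GenotypeMatrix):
    if rec.svtype == "mCNV":
        return gmatrix.cn_row(rec.site_id)
    g = gmatrix.gt_row(rec.site_id).astype(float)
    g[g == MISSING_GT] = np.nan
    return g


def ld_tagging(sv_records, sv_gmatrix: GenotypeMatrix, snp_gt, snp_positions,
               window=50_000, sample_cols=None, site_filter=None):
    """Maximum R^2 between each SV/STR dosage and SNP dosages within the
    window around the SV boundaries.

    snp_gt : SNPs x samples alt-allele count matrix (columns aligned to
        sv_gmatrix.sample_ids). snp_positions : DataFrame with snp_id, chrom,
        pos. Returns a list of LDResult.
    """
    snp_gt = np.asarray(snp_gt, dtype=float)
    snp_chrom = snp_positions["chrom"].to_numpy()
    snp_pos = snp_positions["pos"].to_numpy()
    snp_ids = snp_positions["snp_id"].to_numpy()
    results = []
    for rec in sv_records:
        if site_filter is not None and rec.site_id not in site_filter:
            continue
        dosage = _sv_dosage(rec, sv_gmatrix)
        if sample_cols is not None:
            dosage = dosage[sample_cols]
        in_win = (snp_chrom == rec.chrom) & (snp_pos >= rec.start - window) & (snp_pos <= rec.end + window)
        idx = np.nonzero(in_win)[0]
        if idx.size == 0:
            results.append(LDResult(rec.site_id, None, np.nan, 0))
            continue
        finite = np.isfinite(dosage)
        if not finite.any() or np.nanstd(dosage) == 0:
            results.append(LDResult(rec.site_id, None, np.nan, int(idx.size)))
            continue
        best_r2, best_id = -1.0, None
        for k in idx:
            snp = snp_gt[k]
            if sample_cols is not None:
                snp = snp[sample_cols]
            ok = finite & np.isfinite(snp) & (snp != MISSING_GT)
            if ok.sum() < 2:
                continue
            x, y = dosage[ok], snp[ok]
            if x.std() == 0 or y.std() == 0:
                continue
            r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
            if r2 > best_r2:
                best_r2, best_id = r2, str(snp_ids[k])
        if best_id is None:
            results.append(LDResult(rec.site_id, None, np.nan, int(idx.size)))
        else:
            results.append(LDResult(rec.site_id, best_id, best_r2, int(idx.size)))
    return results


# ---------------------------------------------------------------------------
# intensity rank-sum (IRS) validation


def residualize(matrix, covariates: pd.DataFrame):
    """Regress batch/plate (categorical) out of each probe row by least
    squares and return residuals."""
    n = matrix.shape[1]
    design = [np.ones(n)]
    for col in covariates.columns:
        if col == "sample_id":
            continue
        values = covariates[col].to_numpy()
        for level in np.unique(values)[1:]:  # drop first level
            design.append((values == level).astype(float))
    X = np.column_stack(design)
    beta, *_ = np.linalg.lstsq(X, matrix.T, rcond=None)
    return matrix - (X @ beta).T


def irs_site_p(probe_rows, carriers, direction):
    """One-sided rank-sum p for one site.

    Each probe's residual intensities are ranked across samples and the ranks
    summed into one score per sample; carrier scores are then compared to
    non-carrier scores with a one-sided Mann-Whitney test. Summing ranks
    before the test keeps the null exact even though probes within a site
    share sample-level noise. ``direction`` is -1 for deletions (carriers
    lower) and +1 for duplications.
    """
    n1 = int(carriers.sum())
    if n1 == 0 or n1 == probe_rows.shape[1]:
        return np.nan
    scores = np.zeros(probe_rows.shape[1])
    for row in probe_rows:
        scores += stats.rankdata(row)
    alternative = "less" if direction < 0 else "greater"
    res = stats.mannwhitneyu(scores[carriers], scores[~carriers],
                             alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def irs_test(cnv_records, gmatrix: GenotypeMatrix, probe_matrix, probe_positions,
             covariates=None, min_probes=3, fdr_cut=0.5, fdr_factor=2.0):
    """Per-site IRS p-values and a call-set FDR estimate.

    Probe intensities are residualized on covariates, then each site with
    >= 3 overlapping probes is tested by a one-sided pooled carrier rank-sum
    (deletions: carriers lower; duplications: carriers higher; mCNVs use the
    sign of the mean carrier copy-number deviation). FDR estimate =
    ``fdr_factor`` x fraction of tested sites with p >= ``fdr_cut``.

    Returns (per-site DataFrame, fdr_estimate).
    """
    probe_matrix = np.asarray(probe_matrix, dtype=float)
    if covariates is not None:
        probe_matrix = residualize(probe_matrix, covariates)
    chrom = probe_positions["chrom"].to_numpy()
    pos = probe_positions["pos"].to_numpy()
    rows = []
    for rec in cnv_records:
        in_site = (chrom == rec.chrom) & (pos >= rec.start) & (pos < rec.end)
        idx = np.nonzero(in_site)[0]
        if idx.size < min_probes:
            rows.append({"site_id": rec.site_id, "p": np.nan, "n_probes": int(idx.size),
                         "skipped": "too_few_probes"})
            continue
        if rec.svtype == "mCNV":
            cn = gmatrix.cn_row(rec.site_id)
            finite = np.isfinite(cn)
            vals, cts = np.unique(cn[finite], return_counts=True)
            mode = vals[np.argmax(cts)] if finite.any() else np.nan
            carriers = finite & (cn != mode)
            direction = 1 if np.nanmean(cn[carriers]) > mode else -1
        else:
            g = gmatrix.gt_row(rec.site_id)
            carriers = g > 0
            direction = -1 if rec.svtype in ("DEL", "rMEI") else 1
        if not carriers.any() or carriers.all():
            rows.append({"site_id": rec.site_id, "p": np.nan, "n_probes": int(idx.size),
                         "skipped": "no_carriers"})
            continue
        p = irs_site_p(probe_matrix[idx], np.asarray(carriers, bool), direction)
        rows.append({"site_id": rec.site_id, "p": p, "n_probes": int(idx.size),
                     "skipped": ""})
    table = pd.DataFrame(rows, columns=["site_id", "p", "n_probes", "skipped"])
    tested = table["p"].dropna()
    fdr = float(fdr_factor * np.mean(tested >= fdr_cut)) if len(tested) else np.nan
    return table, fdr
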