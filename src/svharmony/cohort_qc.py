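"""Cohort-level QC: batch-effect and Hardy-Weinberg tests, allele-frequency
summaries, and calls-per-sample diagnostics.

Both tests are plain chi-squared tests without continuity correction,
Bonferroni-corrected over the number of sites actually tested in the family.
The batch test compares full allele/genotype category distributions between
the two studies, with missing genotypes included as their own category; the
HWE test compares observed biallelic genotype counts to those expected from
the estimated allele frequency (df = 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .model_io import MISSING_GT, GenotypeMatrix


def batch_allele_test(counts_a, counts_b, m: int = 1):
    """Chi-squared comparison of two category-count vectors (same categories).

    Categories with zero total count across both groups are dropped (their
    expected count is zero). Returns (statistic, p, flagged) where flagged
    means p < 0.05 / m.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must share categories")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.size == 0 or a.sum() == 0 or b.sum() == 0:
        return np.nan, np.nan, False
    if a.size == 1:
        return 0.0, 1.0, False
    table = np.vstack([a, b])
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p), bool(p < 0.05 / m)


def hwe_test(genotype_counts, m: int = 1):
    """Chi-squared HWE test on (n_rr, n_ra, n_aa) biallelic genotype counts.

    Expected counts come from the estimated allele frequency; df = 1.
    Monomorphic sites give statistic 0. Zero-expected cells contribute 0
    (observed is then necessarily 0 as well under a consistent estimate).
    """
    n_rr, n_ra, n_aa = (float(x) for x in genotype_counts)
    n = n_rr + n_ra + n_aa
    if n == 0:
        return np.nan, np.nan, False
    p_alt = (2 * n_aa + n_ra) / (2 * n)
    q = 1 - p_alt
    expected = np.array([q * q * n, 2 * p_alt * q * n, p_alt * p_alt * n])
    observed = np.array([n_rr, n_ra, n_aa])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    stat = float(terms.sum())
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p, bool(p < 0.05 / m)


def genotype_counts_by_study(gmatrix: GenotypeMatrix, metadata, include_missing=True):
    """Per-site category counts for each study (categories = gt values,
    plus a missing category when requested). Returns dict study -> sites x
    categories DataFrame."""
    meta = {s.sample_id: s for s in metadata}
    out = {}
    cats = [0, 1, 2] + ([MISSING_GT] if include_missing else [])
    for study in ("iPSCORE", "HipSci"):
        cols = [j for j, sid in enumerate(gmatrix.sample_ids)
                if sid in meta and meta[sid].study == study]
        sub = gmatrix.gt[:, cols]
        counts = np.stack([np.sum(sub == c, axis=1) for c in cats], axis=1)
        out[study] = pd.DataFrame(counts, index=gmatrix.site_ids,
                                  columns=[str(c) for c in cats])
    return out


def batch_test_all(gmatrix: GenotypeMatrix, metadata, site_ids=None) -> pd.DataFrame:
    """Run the study batch test per site with Bonferroni m = sites tested."""
    counts = genotype_counts_by_study(gmatrix, metadata)
    if site_ids is None:
        site_ids = gmatrix.site_ids
    m = len(site_ids)
    rows = []
    for sid in site_ids:
        stat, p, flag = batch_allele_test(
            counts["iPSCORE"].loc[sid].to_numpy(),
            counts["HipSci"].loc[sid].to_numpy(),
            m=m,
        )
        rows.append({"site_id": sid, "statistic": stat, "p": p, "flagged": flag})
    return pd.DataFrame(rows, columns=["site_id", "statistic", "p", "flagged"])


def hwe_test_all(gmatrix: GenotypeMatrix, metadata, unrelated_mask=None,
                 site_ids=None) -> pd.DataFrame:
    """HWE test per biallelic site on unrelated blood/fibroblast samples."""
    meta = {s.sample_id: s for s in metadata}
    cols = []
    for j, sid in enumerate(gmatrix.sample_ids):
        info = meta.get(sid)
        if info is None or info.cell_type == "iPSC":
            continue
        if unrelated_mask is not None and not unrelated_mask.get(sid, True):
            continue
        cols.append(j)
    if site_ids is None:
        site_ids = gmatrix.site_ids
    m = len(site_ids)
    rows = []
    for sid in site_ids:
        g = gmatrix.gt[gmatrix.site_row(sid), cols]
        g = g[g != MISSING_GT]
        counts = (int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2)))
        stat, p, flag = hwe_test(counts, m=m)
        rows.append({"site_id": sid, "statistic": stat, "p": p, "flagged": flag})
    return pd.DataFrame(rows, columns=["site_id", "statistic", "p", "flagged"])


def calls_per_sample(records, gmatrix: GenotypeMatrix, metadata) -> pd.DataFrame:
    """Non-reference and missing call counts per sample, with study/cell
    type/superpopulation annotations. Non-reference means gt > 0, or copy
    number different from the site mode for mCNV records."""
    meta = {s.sample_id: s for s in metadata}
    nonref = np.zeros(len(gmatrix.sample_ids), dtype=int)
    missing = np.zeros(len(gmatrix.sample_ids), dtype=int)
    for rec in records:
        i = gmatrix.site_row(rec.site_id)
        if rec.svtype == "mCNV":
            cn = gmatrix.cn[i]
            finite = np.isfinite(cn)
            if finite.any():
                vals, cts = np.unique(cn[finite], return_counts=True)
                mode = vals[np.argmax(cts)]
                nonref += (finite & (cn != mode)).astype(int)
            missing += (~finite).astype(int)
        else:
            g = gmatrix.gt[i]
            nonref += (g > 0).astype(int)
            missing += (g == MISSING_GT).astype(int)
    rows = []
    for j, sid in enumerate(gmatrix.sample_ids):
        info = meta.get(sid)
        rows.append(
            {"sample_id": sid, "n_nonref": int(nonref[j]), "n_missing": int(missing[j]),
             "study": info.study if info else "",
             "cell_type": info.cell_type if info else "",
             "superpopulation": info.superpopulation if info else ""}
        )
    return pd.DataFrame(rows, columns=["sample_id", "n_nonref", "n_missing",
                                       "study", "cell_type", "superpopulation"])


def nmaf(values, channel="gt"):
    """Non-mode allele frequency: 1 - frequency of the modal category."""
    values = np.asarray(values, dtype=float)
    if channel == "gt":
        ok = values != MISSING_GT
    else:
        ok = np.isfinite(values)
    v = values[ok]
    if v.size == 0:
        return np.nan
    _, counts = np.unique(v, return_counts=True)
    return float(1.0 - counts.max() / v.size)


def af_by_study(gmatrix: GenotypeMatrix, metadata, unrelated_mask=None):
    """Per-study NMAF summary plus Pearson r between study NMAFs.

    Frequencies are computed on unrelated samples per study (all samples when
    no mask is supplied), over sites polymorphic in either study.
    """
    meta = {s.sample_id: s for s in metadata}
    cols = {"iPSCORE": [], "HipSci": []}
    for j, sid in enumerate(gmatrix.sample_ids):
        info = meta.get(sid)
        if info is None:
            continue
        if unrelated_mask is not None and not unrelated_mask.get(sid, True):
            continue
        cols[info.study].append(j)
    for study, c in cols.items():
        if not c:
            raise ValueError(f"study {study} has zero (unrelated) samples")
    rows = []
    for i, sid in enumerate(gmatrix.site_ids):
        row = {"site_id": sid}
        for study, c in cols.items():
            row[f"nmaf_{study}"] = nmaf(gmatrix.gt[i, c])
        rows.append(row)
    summary = pd.DataFrame(rows, columns=["site_id", "nmaf_iPSCORE", "nmaf_HipSci"])
    poly = summary[(summary["nmaf_iPSCORE"] > 0) | (summary["nmaf_HipSci"] > 0)]
    if len(poly) >= 3 and poly["nmaf_iPSCORE"].std() > 0 and poly["nmaf_HipSci"].std() > 0:
        r = float(np.corrcoef(poly["nmaf_iPSCORE"], poly["nmaf_HipSci"])[0, 1])
    else:
        r = np.nan
    return summary, r
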