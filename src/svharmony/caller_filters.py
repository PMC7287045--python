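"""Per-caller hard filters with configurable thresholds.

Each filter returns a :class:`FilterReport` accounting for every input record
exactly once with an ordered list of failed-rule reason codes. Comparison
directions follow the published rules literally: MSQ thresholds are strict
(``MSQ > t``), GSCNQUAL minima are inclusive (``GSCNQUAL >= t``), wham/manta
QUAL is inclusive (``>= 250``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_io import MISSING_GT, FilterConfig, GenotypeMatrix


@dataclass
class FilterReport:
    """Kept/removed status and ordered reason codes per record."""

    kept: list = field(default_factory=list)  # site_ids kept
    removed: dict = field(default_factory=dict)  # site_id -> [reason codes]

    def record(self, site_id: str, reasons) -> None:
        reasons = list(reasons)
        if reasons:
            self.removed[site_id] = reasons
        else:
            self.kept.append(site_id)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def reason_counts(self) -> pd.Series:
        from collections import Counter

        c = Counter()
        for reasons in self.removed.values():
            for r in reasons:
                c[r] += 1
        return pd.Series(dict(c), dtype=int).sort_index()

    def to_frame(self) -> pd.DataFrame:
        rows = [{"site_id": s, "kept": True, "reasons": ""} for s in self.kept]
        rows += [
            {"site_id": s, "kept": False, "reasons": ";".join(r)}
            for s, r in self.removed.items()
        ]
        return pd.DataFrame(rows, columns=["site_id", "kept", "reasons"])

    def apply(self, records):
        keep = set(self.kept)
        return [r for r in records if r.site_id in keep]


def _cfg(config, caller):
    if config is None:
        config = FilterConfig.default()
    return config[caller]


def filter_speedseq(records, gmatrix: GenotypeMatrix, config=None) -> FilterReport:
    """Read-pair caller hard filters, applied in published order.

    1. deletions < 418 bp require split-read support;
    2. non-BND variants must be >= 50 bp;
    3. BND calls require 25% of supporting evidence from split or
       paired-end reads;
    4. inversions with QUAL > 100 require >= 10% split/paired-end evidence;
    5. site missing rate must be <= 10%;
    6. class-specific MSQ minima (DEL/rMEI > 20, DUP > 100, INV/BND > 90).
    """
    cfg = _cfg(config, "speedseq")
    report = FilterReport()
    for rec in records:
        if rec.caller != "speedseq":
            raise ValueError(f"filter_speedseq given record from {rec.caller!r}")
        reasons = []
        q = rec.quality
        sr, pe, su = q.get("SR"), q.get("PE"), q.get("SU")
        if rec.svtype == "DEL" and rec.sv_len < cfg["del_min_len_without_sr"]:
            if sr is None:
                reasons.append("missing_key:SR")
            elif sr == 0:
                reasons.append("short_del_no_split_read")
        if rec.svtype != "BND" and rec.sv_len < cfg["min_sv_len"]:
            reasons.append("below_min_sv_len")
        if rec.svtype == "BND":
            if su is None or sr is None or pe is None:
                reasons.append("missing_key:SU/SR/PE")
            elif su == 0 or (sr + pe) / su < cfg["bnd_min_evidence_frac"]:
                reasons.append("bnd_low_evidence_fraction")
        if rec.svtype == "INV" and q.get("QUAL", 0) > cfg["inv_qual_gate"]:
            if su is None or sr is None or pe is None:
                reasons.append("missing_key:SU/SR/PE")
            elif su == 0 or (sr + pe) / su < cfg["inv_min_evidence_frac"]:
                reasons.append("inv_low_evidence_fraction")
        if gmatrix.missing_rate(rec.site_id) > cfg["max_missing_rate"]:
            reasons.append("high_missing_rate")
        msq_min = cfg["msq"].get(rec.svtype)
        if msq_min is not None:
            if "MSQ" not in q:
                reasons.append("missing_key:MSQ")
            elif not q["MSQ"] > msq_min:  # strict >
                reasons.append("low_msq")
        report.record(rec.site_id, reasons)
    return report


def filter_melt(records, config=None) -> FilterReport:
    """MEI hard filters: no exclusion flag, and evidence tranche ASSESS = 5."""
    cfg = _cfg(config, "melt")
    exclude = frozenset(cfg["exclude_flags"])
    report = FilterReport()
    for rec in records:
        reasons = []
        hit = sorted(rec.melt_flags & exclude)
        reasons += [f"flag:{f}" for f in hit]
        if rec.quality.get("ASSESS") != cfg["assess_required"]:
            reasons.append("assess_below_5")
        report.record(rec.site_id, reasons)
    return report


def filter_genomestrip(records, gmatrix: GenotypeMatrix, config=None,
                       non_ipsc_samples=None) -> FilterReport:
    """Read-depth CNV filters: GSCNQUAL class minima (DEL >= 2, mCNV >= 12,
    DUP >= 14), removal of cohort-monoallelic sites, and removal of sites
    with > 10% low-quality genotypes among non-iPSC samples."""
    cfg = _cfg(config, "genomestrip")
    if not non_ipsc_samples:
        raise ValueError("non-iPSC sample set must be non-empty")
    cols = [gmatrix.sample_col(s) for s in non_ipsc_samples]
    report = FilterReport()
    for rec in records:
        reasons = []
        qmin = cfg["gscnqual"].get(rec.svtype)
        if qmin is not None:
            if "GSCNQUAL" not in rec.quality:
                reasons.append("missing_key:GSCNQUAL")
            elif rec.quality["GSCNQUAL"] < qmin:  # minimum required -> >=
                reasons.append("low_gscnqual")
        cn = gmatrix.cn_row(rec.site_id)
        finite = cn[np.isfinite(cn)]
        if finite.size and np.unique(finite).size == 1:
            reasons.append("monoallelic")
        lq_frac = float(gmatrix.lq[gmatrix.site_row(rec.site_id), cols].mean())
        if lq_frac > cfg["max_lq_frac"]:
            reasons.append("high_lq_fraction")
        report.record(rec.site_id, reasons)
    return report


def filter_lcnv(records, gmatrix: GenotypeMatrix, config=None, centromeres=None) -> FilterReport:
    """Large-CNV filters: NBINS >= 10, SCORE >= 1000, centromere containment
    (either direction), and carrier copy number > 2.75 (DUP) or < 1.25 (DEL).

    ``centromeres`` is an iterable of (chrom, start, end); when absent the
    centromere rule is skipped with a warning reason-free pass.
    """
    cfg = _cfg(config, "gs_lcnv")
    cent_by_chrom = {}
    if centromeres:
        for chrom, s, e in centromeres:
            cent_by_chrom.setdefault(chrom, []).append((s, e))
    else:
        import warnings

        warnings.warn("no centromere track supplied; centromere rule skipped")
    report = FilterReport()
    for rec in records:
        reasons = []
        if rec.quality.get("NBINS", 0) < cfg["min_nbins"]:
            reasons.append("too_few_bins")
        if rec.quality.get("SCORE", 0) < cfg["min_score"]:
            reasons.append("low_score")
        for cs, ce in cent_by_chrom.get(rec.chrom, ()):
            inside = rec.start >= cs and rec.end <= ce
            contains = rec.start <= cs and rec.end >= ce
            if inside or contains:
                reasons.append("centromere_overlap")
                break
        cn = gmatrix.cn_row(rec.site_id)
        carriers = cn[np.isfinite(cn)]
        if carriers.size:
            if rec.svtype == "DUP" and not (carriers.max() > cfg["dup_min_cn"]):
                reasons.append("cn_not_above_2.75")
            if rec.svtype == "DEL" and not (carriers.min() < cfg["del_max_cn"]):
                reasons.append("cn_not_below_1.25")
        report.record(rec.site_id, reasons)
    return report


def filter_hipstr(gmatrix: GenotypeMatrix, config=None, subsets=None, call_metrics=None):
    """STR genotype- and site-level filters.

    Per-call thresholds (call quality >= 0.9, flank-indel fraction <= 0.15,
    stutter fraction <= 0.15, allele bias >= -2, strand bias >= -2) convert
    failing genotypes to missing; site-level, every designated sample subset
    must retain > 80% call rate.

    Parameters
    ----------
    subsets : mapping name -> list of sample ids covering all samples.
    call_metrics : mapping metric name (call_qual, flank_indel, stutter,
        allele_bias, strand_bias) -> sites x samples array.

    Returns (FilterReport, masked GenotypeMatrix).
    """
    cfg = _cfg(config, "hipstr")
    if subsets is None:
        subsets = {"all": list(gmatrix.sample_ids)}
    covered = set()
    for ids in subsets.values():
        covered.update(ids)
    if covered != set(gmatrix.sample_ids):
        missing = sorted(set(gmatrix.sample_ids) - covered)
        raise ValueError(f"subsets do not cover all samples, e.g. {missing[:3]}")
    gt = gmatrix.gt.copy()
    call_metrics = call_metrics or {}
    checks = [
        ("call_qual", lambda m: m < cfg["min_call_qual"]),
        ("flank_indel", lambda m: m > cfg["max_call_flank_indel"]),
        ("stutter", lambda m: m > cfg["max_call_stutter"]),
        ("allele_bias", lambda m: m < cfg["min_call_allele_bias"]),
        ("strand_bias", lambda m: m < cfg["min_call_strand_bias"]),
    ]
    for name, fails in checks:
        if name in call_metrics:
            mat = np.asarray(call_metrics[name], dtype=float)
            with np.errstate(invalid="ignore"):
                gt[fails(mat)] = MISSING_GT
    masked = GenotypeMatrix(gmatrix.site_ids, gmatrix.sample_ids, gt=gt,
                            cn=gmatrix.cn, ab=gmatrix.ab, lq=gmatrix.lq)
    subset_cols = {name: [masked.sample_col(s) for s in ids] for name, ids in subsets.items()}
    report = FilterReport()
    for i, site_id in enumerate(masked.site_ids):
        reasons = []
        for name in sorted(subset_cols):
            cols = subset_cols[name]
            rate = float(np.mean(gt[i, cols] != MISSING_GT))
            if not rate > cfg["min_call_rate"]:
                reasons.append(f"low_call_rate:{name}")
        report.record(site_id, reasons)
    return report, masked


def filter_qual(records, config=None, caller="wham") -> FilterReport:
    """wham/manta site filter: QUAL score of at least 250."""
    cfg = _cfg(config, caller)
    report = FilterReport()
    for rec in records:
        reasons = []
        if "QUAL" not in rec.quality:
            reasons.append("missing_key:QUAL")
        elif rec.quality["QUAL"] < cfg["min_qual"]:  # at least -> >=
            reasons.append("low_qual")
        report.record(rec.site_id, reasons)
    return report
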