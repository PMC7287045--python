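"""Synthetic cohorts and multi-caller call-set views with planted truth.

The generator emulates the structure of a two-study iPSC cohort: genetic
replicates (monozygotic twin pairs and fibroblast-iPSC pairs) sharing one
donor genome, SV loci with Hardy-Weinberg genotypes, and per-caller "views"
of those loci with breakpoint jitter, fragmentation, quality-linked genotype
error, allele-balance and copy-number signals, caller flags, array probe
intensities, and SNPs in LD with SVs. Every emitted record maps to exactly
one truth site (or is a labelled false positive), so cluster recovery and
filter behaviour can be scored exactly.

Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .model_io import (
    MISSING_GT,
    GenotypeMatrix,
    ReplicatePair,
    SampleInfo,
    SVRecord,
)

#: point classes emitted by MELT / insertion callers
_MEI_CLASSES = ("ALU", "LINE1", "SVA")


@dataclass
class SimConfig:
    """Study-design and noise parameters for the synthetic cohort.

    Defaults mirror the study design this package targets: 477 donors across
    two studies with 25 MZ twin pairs and 152 fibroblast-iPSC pairs; loci on
    a desk-scale contig set (3 x 10 Mb).
    """

    seed: int
    n_donors: int = 477
    n_twin_pairs: int = 25
    n_fib_ipsc_pairs: int = 152
    # fraction of the remaining (non-replicate) donors assigned to iPSCORE;
    # default reproduces the 273/204 study split
    ipscore_extra_fraction: float = 248 / 300
    contigs: tuple = (("chr1", 10_000_000), ("chr2", 10_000_000), ("chr3", 10_000_000))
    site_counts: dict = field(
        default_factory=lambda: {
            "DEL": 80, "DUP": 40, "mCNV": 25, "INV": 20, "BND": 20,
            "rMEI": 25, "ALU": 40, "LINE1": 12, "SVA": 8,
        }
    )
    af_range: tuple = (0.05, 0.5)
    # genotype error: e(q) = error_max * expit(-steepness * (q - 0.5)) for
    # site quality q in [0,1]; uniform_error overrides with a flat rate
    genotype_error_max: float = 0.2
    error_steepness: float = 8.0
    uniform_error: float | None = None
    jitter_bound: int = 20
    fragmentation_prob: float = 0.15
    frag_max_pieces: int = 5
    frag_max_gap: int = 5_000
    duplicate_prob: float = 0.10
    n_false_positives: int = 10
    melt_flag_probs: dict = field(
        default_factory=lambda: {"lc": 0.15, "s25": 0.05, "rSD": 0.05, "hDP": 0.05}
    )
    flagged_extra_error: float = 0.25
    lq_prob: float = 0.01
    n_hwe_violating: int = 0
    n_batch_skewed: int = 0
    hwe_inbreeding: float = 0.6
    batch_af_shift: float = 0.3
    # array emulation
    probe_spacing: int = 2_000
    probe_sigma: float = 0.25
    probe_alpha: float = 1.0
    n_batches: int = 4
    n_plates: int = 8
    batch_sd: float = 0.2
    plate_sd: float = 0.1
    # LD panel
    snp_flip_eps: float = 0.02
    n_background_snps: int = 5
    ld_window: int = 50_000

    def validate(self) -> None:
        if self.n_donors <= 0:
            raise ValueError("cohort must contain at least one donor")
        if self.n_twin_pairs + self.n_fib_ipsc_pairs > self.n_donors:
            raise ValueError(
                f"n_donors={self.n_donors} cannot host "
                f"{self.n_twin_pairs} twin + {self.n_fib_ipsc_pairs} fibroblast-iPSC pairs"
            )
        for name in ("fragmentation_prob", "duplicate_prob", "snp_flip_eps"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.uniform_error is not None and not 0 <= self.uniform_error <= 1:
            raise ValueError("uniform_error must be in [0,1]")


@dataclass
class TruthSite:
    """A planted variant locus with per-sample true genotypes."""

    truth_id: str
    chrom: str
    start: int
    end: int
    svtype: str
    af: float
    gt: np.ndarray  # per sample, alt-allele count (biallelic) or 0
    cn: np.ndarray  # per sample, true integer copy number
    detectable_by: tuple
    fragments: tuple  # ((start, end), ...) for genomestrip fragmentation, or ()
    label: str = ""  # "", "hwe_violating", "batch_skewed"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    sites: list
    sample_ids: list


@dataclass
class SyntheticBundle:
    """Cohort + truth + per-caller views with provenance, from one seed."""

    config: SimConfig
    samples: list
    pairs: list
    truth: TruthSet
    views: dict  # caller -> (records, GenotypeMatrix)
    provenance: pd.DataFrame  # site_id, caller, truth_id, is_false_positive, is_fragment


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(config: SimConfig):
    """Build SampleInfo and ReplicatePair lists for a two-study cohort.

    Twin-pair donors contribute two iPSCORE blood samples; fibroblast-iPSC
    donors contribute a HipSci fibroblast and iPSC sample; the remaining
    donors contribute one sample each.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    remaining = config.n_donors - config.n_twin_pairs - config.n_fib_ipsc_pairs
    n_ipscore_extra = int(round(remaining * config.ipscore_extra_fraction))
    n_hipsci_extra = remaining - n_ipscore_extra

    # superpopulation mix follows the study's composition
    superpops = ["EUR", "EAS", "AMR", "SAS", "AFR"]
    superpop_p = np.array([415, 34, 15, 7, 6], dtype=float)
    superpop_p /= superpop_p.sum()

    samples, pairs = [], []
    donor_no = 0

    def new_donor():
        nonlocal donor_no
        donor_no += 1
        return (
            f"D{donor_no:04d}",
            superpops[int(rng.choice(len(superpops), p=superpop_p))],
            "M" if rng.random() < 0.5 else "F",
        )

    for i in range(config.n_twin_pairs):
        donor, pop, sex = new_donor()
        a = SampleInfo(f"{donor}_twin1", donor, "iPSCORE", "blood", pop, sex)
        b = SampleInfo(f"{donor}_twin2", donor, "iPSCORE", "blood", pop, sex)
        samples += [a, b]
        pairs.append(ReplicatePair(a.sample_id, b.sample_id, "mz_twin"))
    for i in range(n_ipscore_extra):
        donor, pop, sex = new_donor()
        samples.append(SampleInfo(f"{donor}_blood", donor, "iPSCORE", "blood", pop, sex))
    for i in range(config.n_fib_ipsc_pairs):
        donor, pop, sex = new_donor()
        a = SampleInfo(f"{donor}_fib", donor, "HipSci", "fibroblast", pop, sex)
        b = SampleInfo(f"{donor}_ipsc", donor, "HipSci", "iPSC", pop, sex)
        samples += [a, b]
        pairs.append(ReplicatePair(a.sample_id, b.sample_id, "fib_ipsc"))
    for i in range(n_hipsci_extra):
        donor, pop, sex = new_donor()
        samples.append(SampleInfo(f"{donor}_fib", donor, "HipSci", "fibroblast", pop, sex))
    return samples, pairs


# ---------------------------------------------------------------------------
# truth


def _length_range(svtype: str) -> tuple[int, int]:
    if svtype in _MEI_CLASSES:
        return (300, 6_000)  # element length, record itself is a point
    if svtype == "BND":
        return (100, 1_000)
    if svtype == "mCNV":
        return (5_000, 60_000)
    if svtype in ("DEL", "DUP"):
        return (300, 60_000)
    return (500, 20_000)  # INV, rMEI


def _detectable_by(svtype: str, length: int) -> tuple:
    if svtype in _MEI_CLASSES:
        return ("melt",)
    if svtype in ("INV", "BND", "rMEI"):
        return ("speedseq",)
    callers = []
    if length <= 20_000:
        callers.append("speedseq")
    if length >= 2_000 and svtype in ("DEL", "DUP", "mCNV"):
        callers.append("genomestrip")
    if svtype == "mCNV":
        callers = ["genomestrip"]
    return tuple(callers) or ("speedseq",)


def _draw_hwe_genotypes(rng, p, donors, inbreeding=0.0):
    """Alt-allele counts per donor under HWE with optional inbreeding F."""
    q = 1 - p
    f = inbreeding
    probs = np.array([q * q + f * p * q, 2 * p * q * (1 - f), p * p + f * p * q])
    probs = probs / probs.sum()
    return rng.choice(3, size=donors, p=probs)


def simulate_truth(config: SimConfig, samples) -> TruthSet:
    """Plant truth sites with HWE genotypes copied to replicate partners.

    Genotypes are drawn per donor; all samples of a donor share the genotype
    (error is injected later, per emitted view). Optional HWE-violating and
    batch-skewed sites are planted and labelled.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    sample_ids = [s.sample_id for s in samples]
    donors = sorted({s.donor_id for s in samples})
    donor_col = {d: i for i, d in enumerate(donors)}
    sample_donor = np.array([donor_col[s.donor_id] for s in samples])
    sample_study = np.array([s.study for s in samples])

    contig_names = [c[0] for c in config.contigs]
    contig_lens = {c[0]: c[1] for c in config.contigs}

    sites = []
    idx = 0
    special = [("hwe_violating", config.n_hwe_violating), ("batch_skewed", config.n_batch_skewed)]
    plan = []
    for svtype, count in sorted(config.site_counts.items()):
        plan += [(svtype, "")] * count
    for label, count in special:
        plan += [("DEL", label)] * count

    for svtype, label in plan:
        idx += 1
        lo, hi = _length_range(svtype)
        length = int(rng.integers(lo, hi + 1))
        chrom = contig_names[int(rng.integers(len(contig_names)))]
        start = int(rng.integers(1_000, contig_lens[chrom] - length - 1_000))
        end = start + length
        af = float(rng.uniform(*config.af_range))

        if svtype == "mCNV":
            # three copy-number alleles segregating; diploid cn is the sum
            allele_vals = np.array([1, 2, 3])
            freqs = rng.dirichlet([2.0, 5.0, 2.0])
            a1 = rng.choice(allele_vals, size=len(donors), p=freqs)
            a2 = rng.choice(allele_vals, size=len(donors), p=freqs)
            donor_cn = a1 + a2
            donor_gt = (donor_cn != 4).astype(int)  # non-mode indicator
        else:
            f = config.hwe_inbreeding if label == "hwe_violating" else 0.0
            if label == "batch_skewed":
                # different allele frequency per study
                donor_gt = np.zeros(len(donors), dtype=int)
                af_by_study = {"iPSCORE": af, "HipSci": min(0.95, af + config.batch_af_shift)}
                donor_study = {}
                for s in samples:
                    donor_study[donor_col[s.donor_id]] = s.study
                for d in range(len(donors)):
                    p = af_by_study[donor_study.get(d, "iPSCORE")]
                    donor_gt[d] = _draw_hwe_genotypes(rng, p, 1)[0]
            else:
                donor_gt = _draw_hwe_genotypes(rng, af, len(donors), inbreeding=f)
            if svtype == "DEL" or svtype == "rMEI":
                donor_cn = 2 - donor_gt
            elif svtype == "DUP":
                donor_cn = 2 + donor_gt
            else:
                donor_cn = np.full(len(donors), 2)

        gt = donor_gt[sample_donor]
        cn = donor_cn[sample_donor]

        detect = _detectable_by(svtype, length)
        fragments = ()
        if (
            "genomestrip" in detect
            and svtype in ("DEL", "DUP")
            and rng.random() < config.fragmentation_prob
            and length >= 4_000
        ):
            k = int(rng.integers(2, config.frag_max_pieces + 1))
            fragments = _fragment_plan(rng, start, end, k, config.frag_max_gap)

        sites.append(
            TruthSite(
                truth_id=f"T{idx:04d}",
                chrom=chrom,
                start=start,
                end=end,
                svtype=svtype,
                af=af,
                gt=gt.astype(np.int16),
                cn=cn.astype(np.int16),
                detectable_by=detect,
                fragments=fragments,
                label=label,
            )
        )
    _ = sample_study
    return TruthSet(sites=sites, sample_ids=sample_ids)


def _fragment_plan(rng, start, end, k, max_gap):
    """Split [start, end) into k pieces separated by gaps, tiling the locus."""
    length = end - start
    k = min(k, max(2, length // 1_000))
    gaps = rng.integers(200, max(201, min(max_gap, length // (2 * k))), size=k - 1)
    total_gap = int(gaps.sum())
    seg_total = length - total_gap
    cuts = np.sort(rng.choice(np.arange(1, seg_total), size=k - 1, replace=False))
    seg_lens = np.diff(np.concatenate([[0], cuts, [seg_total]]))
    frags = []
    pos = start
    for i, sl in enumerate(seg_lens):
        frags.append((int(pos), int(pos + sl)))
        pos += sl
        if i < len(gaps):
            pos += int(gaps[i])
    return tuple(frags)


# ---------------------------------------------------------------------------
# caller views


def _site_error(config: SimConfig, q: float) -> float:
    if config.uniform_error is not None:
        return config.uniform_error
    return config.genotype_error_max * float(expit(-config.error_steepness * (q - 0.5)))


def _flip_genotypes(rng, gt, e):
    """Symmetric flip among {0,1,2} with per-cell probability e."""
    if e <= 0:
        return gt.copy()
    out = gt.copy()
    flip = rng.random(gt.shape) < e
    for i in np.nonzero(flip)[0]:
        choices = [g for g in (0, 1, 2) if g != out[i]]
        out[i] = choices[int(rng.integers(2))]
    return out


def _ab_from_gt(rng, gt):
    centers = np.array([0.02, 0.5, 0.95])
    ab = centers[np.clip(gt, 0, 2)] + rng.normal(0, 0.03, size=gt.shape)
    return np.clip(ab, 0.0, 1.0)


def _jitter(rng, start, end, bound):
    if bound <= 0:
        return start, end
    j1 = int(rng.integers(-bound, bound + 1))
    j2 = int(rng.integers(-bound, bound + 1))
    s, e = start + j1, end + j2
    if e <= s:
        e = s + 1
    return s, e


def emit_caller_views(truth: TruthSet, config: SimConfig):
    """Emit per-caller (records, GenotypeMatrix) views of the truth sites.

    Breakpoints carry jitter bounded by ``config.jitter_bound``; genotype
    errors follow the quality-linked schedule; SpeedSeq views carry AB,
    Genome STRiP views integer CN (with fragmentation of some CNVs into
    adjacent pieces with identical genotypes); MELT views carry flags and
    ASSESS tranches. Planted within- and cross-caller duplicates share the
    truth id, enabling exact cluster-recovery scoring.
    """
    rng = np.random.default_rng(config.seed + 2)
    n_samples = len(truth.sample_ids)
    per_caller = {c: {"records": [], "gt": [], "cn": [], "ab": [], "lq": []} for c in
                  ("speedseq", "genomestrip", "melt")}
    prov_rows = []
    counters = {c: 0 for c in per_caller}

    def add_record(caller, rec, gt_row, cn_row, ab_row, lq_row, truth_id, is_fp, is_frag):
        d = per_caller[caller]
        d["records"].append(rec)
        d["gt"].append(gt_row)
        d["cn"].append(cn_row)
        d["ab"].append(ab_row)
        d["lq"].append(lq_row)
        prov_rows.append(
            {"site_id": rec.site_id, "caller": caller, "truth_id": truth_id,
             "is_false_positive": is_fp, "is_fragment": is_frag}
        )

    def next_id(caller):
        counters[caller] += 1
        return f"{caller}_{counters[caller]:05d}"

    nan_row = np.full(n_samples, np.nan)

    for site in truth.sites:
        for caller in site.detectable_by:
            q = float(rng.uniform(0, 1))
            e = _site_error(config, q)
            n_copies = 1 + (1 if rng.random() < config.duplicate_prob else 0)
            for copy_i in range(n_copies):
                if caller == "speedseq":
                    s, t = _jitter(rng, site.start, site.end, config.jitter_bound)
                    gt_row = _flip_genotypes(rng, site.gt.astype(np.int16), e)
                    ab_row = _ab_from_gt(rng, gt_row)
                    su = int(rng.integers(20, 120))
                    sr = int(round(su * rng.uniform(0.3, 0.7)))
                    pe = su - sr
                    svtype = site.svtype if site.svtype != "mCNV" else ("DUP" if rng.random() < 0.5 else "DEL")
                    if svtype in ("BND",):
                        s2, t2 = s, s + 1
                    else:
                        s2, t2 = s, t
                    rec = SVRecord(
                        site_id=next_id("speedseq"), caller="speedseq", chrom=site.chrom,
                        start=s2, end=t2, svtype=svtype,
                        sv_len=site.length if svtype == "BND" else max(1, t2 - s2),
                        quality={"MSQ": round(q * 200, 2), "QUAL": round(q * 300, 2),
                                 "SU": su, "SR": sr, "PE": pe},
                    )
                    add_record("speedseq", rec, gt_row, nan_row.copy(), ab_row,
                               np.zeros(n_samples, bool), site.truth_id, False, False)
                elif caller == "genomestrip":
                    gt_row = _flip_genotypes(rng, site.gt.astype(np.int16), e)
                    if site.svtype == "DEL":
                        cn_row = (2 - gt_row).astype(float)
                    elif site.svtype == "DUP":
                        cn_row = (2 + gt_row).astype(float)
                    else:
                        cn_err = rng.random(n_samples) < e
                        cn_row = site.cn.astype(float)
                        cn_row[cn_err] += rng.choice([-1, 1], size=int(cn_err.sum()))
                        cn_row = np.clip(cn_row, 0, None)
                    lq_row = rng.random(n_samples) < config.lq_prob
                    intervals = site.fragments if (site.fragments and copy_i == 0) else ((site.start, site.end),)
                    for fi, (fs, fe) in enumerate(intervals):
                        s, t = _jitter(rng, fs, fe, config.jitter_bound)
                        rec = SVRecord(
                            site_id=next_id("genomestrip"), caller="genomestrip",
                            chrom=site.chrom, start=s, end=t, svtype=site.svtype,
                            sv_len=max(1, t - s),
                            quality={"GSCNQUAL": round(q * 50, 2)},
                        )
                        add_record("genomestrip", rec, gt_row.copy(), cn_row.copy(),
                                   nan_row.copy(), lq_row.copy(), site.truth_id,
                                   False, len(intervals) > 1)
                elif caller == "melt":
                    flags = frozenset(
                        f for f, p in config.melt_flag_probs.items() if rng.random() < p
                    )
                    if config.uniform_error is not None:
                        e_site = config.uniform_error  # flat override, flags included
                    else:
                        e_site = min(1.0, e + (config.flagged_extra_error if flags else 0.0))
                    gt_row = _flip_genotypes(rng, site.gt.astype(np.int16), e_site)
                    assess = int(np.clip(1 + math.floor(q * 5), 1, 5))
                    s = site.start + int(rng.integers(-config.jitter_bound, config.jitter_bound + 1)) \
                        if config.jitter_bound > 0 else site.start
                    rec = SVRecord(
                        site_id=next_id("melt"), caller="melt", chrom=site.chrom,
                        start=s, end=s + 1, svtype=site.svtype, sv_len=site.length,
                        quality={"ASSESS": assess}, melt_flags=flags,
                    )
                    add_record("melt", rec, gt_row, nan_row.copy(), nan_row.copy(),
                               np.zeros(n_samples, bool), site.truth_id, False, False)

    # labelled false positives: low quality, random sparse genotypes
    contig_names = [c[0] for c in config.contigs]
    contig_lens = {c[0]: c[1] for c in config.contigs}
    for caller in ("speedseq", "genomestrip", "melt"):
        for _ in range(config.n_false_positives):
            q = float(rng.uniform(0, 0.15))
            chrom = contig_names[int(rng.integers(len(contig_names)))]
            length = int(rng.integers(300, 5_000))
            start = int(rng.integers(1_000, contig_lens[chrom] - length - 1_000))
            gt_row = (rng.random(n_samples) < 0.08).astype(np.int16)
            if caller == "speedseq":
                su = int(rng.integers(4, 20))
                rec = SVRecord(
                    site_id=next_id(caller), caller=caller, chrom=chrom,
                    start=start, end=start + length, svtype="DEL", sv_len=length,
                    quality={"MSQ": round(q * 200, 2), "QUAL": round(q * 300, 2),
                             "SU": su, "SR": 0, "PE": su},
                )
                add_record(caller, rec, gt_row, nan_row.copy(), _ab_from_gt(rng, gt_row),
                           np.zeros(n_samples, bool), "", True, False)
            elif caller == "genomestrip":
                rec = SVRecord(
                    site_id=next_id(caller), caller=caller, chrom=chrom,
                    start=start, end=start + length, svtype="DEL", sv_len=length,
                    quality={"GSCNQUAL": round(q * 50, 2)},
                )
                add_record(caller, rec, gt_row, (2 - gt_row).astype(float),
                           nan_row.copy(), np.zeros(n_samples, bool), "", True, False)
            else:
                rec = SVRecord(
                    site_id=next_id(caller), caller=caller, chrom=chrom,
                    start=start, end=start + 1, svtype="ALU", sv_len=length,
                    quality={"ASSESS": int(rng.integers(1, 4))},
                    melt_flags=frozenset({"lc"} if rng.random() < 0.5 else set()),
                )
                add_record(caller, rec, gt_row, nan_row.copy(), nan_row.copy(),
                           np.zeros(n_samples, bool), "", True, False)

    views = {}
    for caller, d in per_caller.items():
        n = len(d["records"])
        gm = GenotypeMatrix(
            [r.site_id for r in d["records"]], truth.sample_ids,
            gt=np.array(d["gt"], dtype=np.int16).reshape(n, n_samples),
            cn=np.array(d["cn"]).reshape(n, n_samples),
            ab=np.array(d["ab"]).reshape(n, n_samples),
            lq=np.array(d["lq"], dtype=bool).reshape(n, n_samples),
        )
        views[caller] = (d["records"], gm)
    provenance = pd.DataFrame(prov_rows, columns=["site_id", "caller", "truth_id",
                                                  "is_false_positive", "is_fragment"])
    return views, provenance


# ---------------------------------------------------------------------------
# probe intensities and SNP panel


def emit_probe_intensities(truth: TruthSet, samples, config: SimConfig):
    """Array probe intensities ~ alpha*(cn-2)/2 + batch + plate + noise.

    Probes tile each CNV truth site densely enough that every designated
    testable CNV overlaps >= 3 probes. Returns (probe_df, intensity matrix
    probes x samples, covariate DataFrame with batch/plate per sample).
    """
    rng = np.random.default_rng(config.seed + 3)
    n = len(truth.sample_ids)
    batch = rng.integers(0, config.n_batches, size=n)
    plate = rng.integers(0, config.n_plates, size=n)
    batch_eff = rng.normal(0, config.batch_sd, size=config.n_batches)
    plate_eff = rng.normal(0, config.plate_sd, size=config.n_plates)
    covariates = pd.DataFrame(
        {"sample_id": truth.sample_ids, "batch": batch, "plate": plate}
    )

    probe_rows, intensities = [], []
    pid = 0
    for site in truth.sites:
        if site.svtype not in ("DEL", "DUP", "mCNV") or site.length < 3 * config.probe_spacing:
            continue
        positions = range(site.start + config.probe_spacing // 2, site.end, config.probe_spacing)
        dosage = (site.cn.astype(float) - 2.0) / 2.0
        for pos in positions:
            pid += 1
            probe_rows.append({"probe_id": f"P{pid:06d}", "chrom": site.chrom, "pos": int(pos)})
            signal = (
                config.probe_alpha * dosage
                + batch_eff[batch]
                + plate_eff[plate]
                + rng.normal(0, config.probe_sigma, size=n)
            )
            intensities.append(signal)
    probe_df = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos"])
    matrix = np.array(intensities).reshape(len(probe_rows), n) if probe_rows else np.empty((0, n))
    return probe_df, matrix, covariates


def emit_snp_panel(truth: TruthSet, config: SimConfig):
    """SNP panel with one tagging SNP per designated SV plus background SNPs.

    The tagging SNP sits within the LD window and copies the SV dosage with
    per-sample flip probability ``snp_flip_eps``; background SNPs carry
    independent HWE genotypes. Returns (snp gt matrix, positions DataFrame).
    """
    rng = np.random.default_rng(config.seed + 4)
    n = len(truth.sample_ids)
    rows, meta = [], []
    sid = 0
    contig_lens = {c[0]: c[1] for c in config.contigs}
    for site in truth.sites:
        if site.svtype in ("mCNV",):
            dosage = np.abs(site.cn.astype(np.int16) - 4)
            dosage = np.clip(dosage, 0, 2)
        else:
            dosage = site.gt.astype(np.int16)
        # tagging SNP
        sid += 1
        offset = int(rng.integers(500, config.ld_window))
        pos = max(1, min(site.start - offset, contig_lens[site.chrom] - 1))
        tag = dosage.copy()
        flip = rng.random(n) < config.snp_flip_eps
        for i in np.nonzero(flip)[0]:
            choices = [g for g in (0, 1, 2) if g != tag[i]]
            tag[i] = choices[int(rng.integers(2))]
        rows.append(tag)
        meta.append({"snp_id": f"S{sid:06d}", "chrom": site.chrom, "pos": pos,
                     "tags": site.truth_id})
        # background SNPs
        for _ in range(config.n_background_snps):
            sid += 1
            pos_b = int(rng.integers(max(1, site.start - config.ld_window),
                                     min(contig_lens[site.chrom], site.end + config.ld_window)))
            p = float(rng.uniform(0.1, 0.5))
            rows.append(_draw_hwe_genotypes(rng, p, n).astype(np.int16))
            meta.append({"snp_id": f"S{sid:06d}", "chrom": site.chrom, "pos": pos_b, "tags": ""})
    gt = np.array(rows, dtype=np.int16).reshape(len(rows), n) if rows else np.empty((0, n), np.int16)
    positions = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos", "tags"])
    return gt, positions


def simulate_bundle(config: SimConfig) -> SyntheticBundle:
    """One-call convenience: cohort + truth + caller views."""
    samples, pairs = simulate_cohort(config)
    truth = simulate_truth(config, samples)
    views, provenance = emit_caller_views(truth, config)
    return SyntheticBundle(
        config=config, samples=samples, pairs=pairs, truth=truth,
        views=views, provenance=provenance,
    )


def default_config(seed: int, **overrides) -> SimConfig:
    return replace(SimConfig(seed=seed), **overrides)
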