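"""Domain types and readers/writers for per-caller VCF dialects and cohort metadata.

Internal coordinates are 0-based half-open; VCF I/O converts to/from the
1-based inclusive POS..END convention. Breakends and insertions are stored as
1-bp point intervals (their matching semantics are distance-based, see
:mod:`svharmony.compare`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

CALLERS = (
    "speedseq",
    "genomestrip",
    "gs_lcnv",
    "melt",
    "hipstr",
    "wham",
    "manta",
    "external",
)

SVTYPES = (
    "DEL",
    "DUP",
    "mCNV",
    "INV",
    "BND",
    "rMEI",
    "ALU",
    "LINE1",
    "SVA",
    "INS",
    "STR",
)

#: point-like classes matched by breakpoint distance, stored as 1-bp intervals
POINT_TYPES = frozenset({"BND", "INS", "ALU", "LINE1", "SVA"})

QUALITY_KEYS = ("MSQ", "GSCNQUAL", "QUAL", "SU", "SR", "PE", "ASSESS", "NBINS", "SCORE")

MELT_FLAGS = frozenset({"lc", "s25", "rSD", "hDP"})

STUDIES = ("iPSCORE", "HipSci")
CELL_TYPES = ("blood", "fibroblast", "iPSC")
SUPERPOPS = ("EUR", "AFR", "EAS", "SAS", "AMR")

MISSING_GT = -1


class VCFDialectError(ValueError):
    """Raised when a VCF line cannot be interpreted under the declared dialect."""


@dataclass
class SVRecord:
    """One called site with caller provenance, interval, class and quality metrics."""

    site_id: str
    caller: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    svtype: str
    sv_len: int
    quality: dict = field(default_factory=dict)
    melt_flags: frozenset = frozenset()
    filter_status: str = "pass"

    def __post_init__(self) -> None:
        if self.caller not in CALLERS:
            raise ValueError(f"unknown caller {self.caller!r}")
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r} at site {self.site_id}")
        if self.end <= self.start:
            raise ValueError(f"site {self.site_id}: end must exceed start")
        if self.svtype in POINT_TYPES and self.end != self.start + 1:
            raise ValueError(f"site {self.site_id}: {self.svtype} must be a point record")
        if self.sv_len <= 0:
            raise ValueError(f"site {self.site_id}: sv_len must be positive")
        if not set(self.melt_flags) <= MELT_FLAGS:
            raise ValueError(f"site {self.site_id}: unknown MELT flags")
        self.melt_flags = frozenset(self.melt_flags)

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class GenotypeMatrix:
    """Sites x samples genotype container.

    gt: integer alt-allele count, ``-1`` for missing.
    cn: copy number (float; nan missing). ab: allele-balance fraction in [0,1]
    (nan missing). lq: boolean low-quality flag.
    """

    def __init__(self, site_ids, sample_ids, gt=None, cn=None, ab=None, lq=None):
        self.site_ids = list(site_ids)
        self.sample_ids = list(sample_ids)
        n, m = len(self.site_ids), len(self.sample_ids)
        self.gt = np.full((n, m), MISSING_GT, dtype=np.int16) if gt is None else np.asarray(gt, dtype=np.int16)
        self.cn = np.full((n, m), np.nan) if cn is None else np.asarray(cn, dtype=float)
        self.ab = np.full((n, m), np.nan) if ab is None else np.asarray(ab, dtype=float)
        self.lq = np.zeros((n, m), dtype=bool) if lq is None else np.asarray(lq, dtype=bool)
        for name in ("gt", "cn", "ab", "lq"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, m)}")
        with np.errstate(invalid="ignore"):
            bad = (self.ab < 0) | (self.ab > 1)
        if bad.any():
            raise ValueError("allele balance outside [0,1]")
        with np.errstate(invalid="ignore"):
            if (self.cn < 0).any():
                raise ValueError("negative copy number")
        self._site_index = {s: i for i, s in enumerate(self.site_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        if len(self._site_index) != n:
            raise ValueError("duplicate site ids")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.site_ids), len(self.sample_ids))

    def site_row(self, site_id: str) -> int:
        return self._site_index[site_id]

    def sample_col(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def gt_row(self, site_id: str) -> np.ndarray:
        return self.gt[self.site_row(site_id)]

    def cn_row(self, site_id: str) -> np.ndarray:
        return self.cn[self.site_row(site_id)]

    def ab_row(self, site_id: str) -> np.ndarray:
        return self.ab[self.site_row(site_id)]

    def missing_rate(self, site_id: str) -> float:
        row = self.gt_row(site_id)
        return float(np.mean(row == MISSING_GT))

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        cols = [self._sample_index[s] for s in sample_ids]
        return GenotypeMatrix(
            self.site_ids, list(sample_ids),
            gt=self.gt[:, cols], cn=self.cn[:, cols],
            ab=self.ab[:, cols], lq=self.lq[:, cols],
        )

    def subset_sites(self, site_ids) -> "GenotypeMatrix":
        rows = [self._site_index[s] for s in site_ids]
        return GenotypeMatrix(
            list(site_ids), self.sample_ids,
            gt=self.gt[rows], cn=self.cn[rows], ab=self.ab[rows], lq=self.lq[rows],
        )


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    donor_id: str
    study: str
    cell_type: str
    superpopulation: str
    sex: str

    def __post_init__(self):
        if self.study not in STUDIES:
            raise ValueError(f"unknown study {self.study!r} for sample {self.sample_id}")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r} for sample {self.sample_id}")
        if self.superpopulation not in SUPERPOPS:
            raise ValueError(f"unknown superpopulation {self.superpopulation!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass(frozen=True)
class ReplicatePair:
    """Two samples sharing one donor genome (MZ twins, or fibroblast-iPSC)."""

    sample_a: str
    sample_b: str
    pair_type: str  # mz_twin | fib_ipsc

    def __post_init__(self):
        if self.sample_a == self.sample_b:
            raise ValueError("replicate pair members must differ")
        if self.pair_type not in ("mz_twin", "fib_ipsc"):
            raise ValueError(f"unknown pair type {self.pair_type!r}")


# Per-caller, per-class hard-filter thresholds. The numeric defaults are the
# published filtering strategy for each caller; every value is overridable.
DEFAULT_FILTER_CONFIG = {
    "speedseq": {
        "del_min_len_without_sr": 418,
        "min_sv_len": 50,
        "bnd_min_evidence_frac": 0.25,
        "inv_qual_gate": 100,
        "inv_min_evidence_frac": 0.10,
        "max_missing_rate": 0.10,
        "msq": {"DEL": 20, "rMEI": 20, "DUP": 100, "INV": 90, "BND": 90},
    },
    "melt": {"exclude_flags": ["lc", "s25", "rSD", "hDP"], "assess_required": 5},
    "genomestrip": {
        "gscnqual": {"DEL": 2, "mCNV": 12, "DUP": 14},
        "max_lq_frac": 0.10,
    },
    "gs_lcnv": {
        "min_nbins": 10,
        "min_score": 1000,
        "dup_min_cn": 2.75,
        "del_max_cn": 1.25,
    },
    "hipstr": {
        "min_call_qual": 0.9,
        "max_call_flank_indel": 0.15,
        "max_call_stutter": 0.15,
        "min_call_allele_bias": -2,
        "min_call_strand_bias": -2,
        "min_call_rate": 0.8,
    },
    "wham": {"min_qual": 250},
    "manta": {"min_qual": 250},
}


class FilterConfig(dict):
    """Nested per-caller threshold mapping; missing keys fall back to defaults."""

    @classmethod
    def default(cls) -> "FilterConfig":
        return cls(json.loads(json.dumps(DEFAULT_FILTER_CONFIG)))

    @classmethod
    def from_json(cls, path) -> "FilterConfig":
        cfg = cls.default()
        with open(path) as fh:
            user = json.load(fh)
        for caller, overrides in user.items():
            for key, val in overrides.items():
                if isinstance(val, dict):
                    cfg.setdefault(caller, {}).setdefault(key, {}).update(val)
                else:
                    cfg.setdefault(caller, {})[key] = val
        return cfg

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# VCF I/O

_VCF_HEADER_LINES = [
    ('INFO', 'SVTYPE', '1', 'String', 'Structural variant class'),
    ('INFO', 'END', '1', 'Integer', 'End position (1-based inclusive)'),
    ('INFO', 'SVLEN', '1', 'Integer', 'Variant length in bp'),
    ('INFO', 'CALLER', '1', 'String', 'Calling algorithm'),
    ('INFO', 'CLUSTER_ID', '1', 'String', 'Redundancy cluster id'),
    ('INFO', 'PRIMARY', '0', 'Flag', 'Primary member of its cluster'),
    ('INFO', 'MSQ', '1', 'Float', 'Median sample quality'),
    ('INFO', 'GSCNQUAL', '1', 'Float', 'Copy-number quality score'),
    ('INFO', 'SU', '1', 'Integer', 'Total supporting evidence'),
    ('INFO', 'SR', '1', 'Integer', 'Split-read support'),
    ('INFO', 'PE', '1', 'Integer', 'Paired-end support'),
    ('INFO', 'ASSESS', '1', 'Integer', 'Insertion evidence tranche 1-5'),
    ('INFO', 'NBINS', '1', 'Integer', 'Read-depth bins spanned'),
    ('INFO', 'SCORE', '1', 'Float', 'Read-depth call score'),
    ('FORMAT', 'GT', '1', 'String', 'Genotype'),
    ('FORMAT', 'CN', '1', 'Float', 'Copy number'),
    ('FORMAT', 'AB', '1', 'Float', 'Allele balance'),
    ('FORMAT', 'FT', '1', 'String', 'Per-genotype filter (LQ = low quality)'),
]

_INFO_QUALITY_KEYS = ("MSQ", "GSCNQUAL", "SU", "SR", "PE", "ASSESS", "NBINS", "SCORE")
_INT_QUALITY = {"SU", "SR", "PE", "ASSESS", "NBINS"}


def _build_header(sample_ids, contigs) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(name, length=length)
    for kind, key, number, vtype, desc in _VCF_HEADER_LINES:
        header.add_meta(
            kind,
            items=[("ID", key), ("Number", number), ("Type", vtype), ("Description", desc)],
        )
    for flag in sorted(MELT_FLAGS):
        header.filters.add(flag, None, None, f"Caller flag {flag}")
    for s in sample_ids:
        header.add_sample(s)
    return header


#: classes where htslib derives END from POS + SVLEN (VCF 4.4 symbolic-CNV
#: semantics); for these we write POS at the padding base before the event
#: and SVLEN equal to the span, the canonical SV-VCF layout.
_PADDED_TYPES = frozenset({"DEL", "DUP", "INV"})


def write_sv_vcf(path, records, gmatrix, contigs=None) -> None:
    """Write records + genotypes as VCF 4.2 (1-based inclusive POS..END).

    DEL/DUP/INV records place POS on the padding base before the event with
    SVLEN = span (END = POS + SVLEN); other classes carry an explicit END.
    MELT flags are carried in the FILTER column; per-caller quality keys in
    INFO; a record-level QUAL score in the QUAL column.
    """
    if contigs is None:
        seen = {}
        for r in records:
            seen[r.chrom] = max(seen.get(r.chrom, 0), r.end + 1000)
        contigs = sorted(seen.items())
    header = _build_header(gmatrix.sample_ids, contigs)
    order = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].start, records[i].site_id))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in order:
            rec = records[i]
            row = gmatrix.site_row(rec.site_id)
            padded = rec.svtype in _PADDED_TYPES
            if padded and rec.start < 1:
                raise ValueError(
                    f"site {rec.site_id}: {rec.svtype} needs a padding base (start >= 1)"
                )
            pos = rec.start - 1 if padded else rec.start
            v = out.new_record(
                contig=rec.chrom,
                start=pos,
                stop=pos + 1,  # placeholder; END finalized below
                alleles=("N", f"<{rec.svtype}>"),
                id=rec.site_id,
            )
            v.info["SVTYPE"] = rec.svtype
            v.info["SVLEN"] = rec.end - rec.start if padded else rec.sv_len
            v.info["CALLER"] = rec.caller
            if not padded:
                v.stop = rec.end  # htslib honors explicit END for these classes
            for key in _INFO_QUALITY_KEYS:
                if key in rec.quality:
                    val = rec.quality[key]
                    v.info[key] = int(val) if key in _INT_QUALITY else float(val)
            if "QUAL" in rec.quality:
                v.qual = float(rec.quality["QUAL"])
            if rec.melt_flags:
                for flag in sorted(rec.melt_flags):
                    v.filter.add(flag)
            else:
                v.filter.add("PASS")
            for j, s in enumerate(gmatrix.sample_ids):
                cell = v.samples[s]
                g = int(gmatrix.gt[row, j])
                if g < 0:
                    cell["GT"] = (None, None)
                else:
                    cell["GT"] = (min(g, 1), 1 if g >= 2 else 0)
                if np.isfinite(gmatrix.cn[row, j]):
                    cell["CN"] = float(gmatrix.cn[row, j])
                if np.isfinite(gmatrix.ab[row, j]):
                    cell["AB"] = float(gmatrix.ab[row, j])
                if gmatrix.lq[row, j]:
                    cell["FT"] = "LQ"
            out.write(v)


def _info_get(v, key, default=None):
    # pysam raises on keys absent from the header; treat them as missing
    try:
        return v.info.get(key, default)
    except (KeyError, ValueError):
        return default


def read_sv_vcf(path, caller: str):
    """Read a caller's VCF into (records, GenotypeMatrix).

    VCF POS/END (1-based inclusive) become 0-based half-open internally.
    Records with an unknown SVTYPE are collected and reported in one error at
    the end rather than silently dropped.
    """
    if caller not in CALLERS:
        raise ValueError(f"unknown caller {caller!r}")
    records, rows = [], []
    bad = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for line_no, v in enumerate(vcf, start=1):
            svtype = _info_get(v, "SVTYPE")
            if svtype not in SVTYPES:
                bad.append((line_no, v.id, svtype))
                continue
            if svtype in _PADDED_TYPES and _info_get(v, "SVLEN") is not None:
                # padding-base layout (the one we write): POS sits on the
                # base before the event and END = POS + SVLEN
                start = v.start + 1
            else:
                start = v.start  # plain POS-1 convention
            end = v.stop
            quality = {}
            for key in _INFO_QUALITY_KEYS:
                val = _info_get(v, key)
                if val is not None:
                    # htslib stores floats as float32; round away the excess digits
                    quality[key] = int(val) if key in _INT_QUALITY else round(float(val), 4)
            if v.qual is not None:
                quality["QUAL"] = round(float(v.qual), 4)
            flags = frozenset(f for f in v.filter.keys() if f in MELT_FLAGS)
            rec = SVRecord(
                site_id=v.id,
                caller=_info_get(v, "CALLER", caller),
                chrom=v.chrom,
                start=start,
                end=end,
                svtype=svtype,
                sv_len=abs(int(_info_get(v, "SVLEN", end - start))),
                quality=quality,
                melt_flags=flags,
            )
            records.append(rec)
            gt_row = np.full(len(sample_ids), MISSING_GT, dtype=np.int16)
            cn_row = np.full(len(sample_ids), np.nan)
            ab_row = np.full(len(sample_ids), np.nan)
            lq_row = np.zeros(len(sample_ids), dtype=bool)
            for j, s in enumerate(sample_ids):
                cell = v.samples[s]
                alleles = cell.get("GT")
                if alleles is not None and None not in alleles:
                    gt_row[j] = sum(alleles)
                if cell.get("CN") is not None:
                    cn_row[j] = float(cell["CN"])
                if cell.get("AB") is not None:
                    ab_row[j] = float(cell["AB"])
                if cell.get("FT") == "LQ":
                    lq_row[j] = True
            rows.append((gt_row, cn_row, ab_row, lq_row))
    if bad:
        detail = "; ".join(f"record {n} ({rid}): SVTYPE={st!r}" for n, rid, st in bad[:5])
        raise VCFDialectError(f"{len(bad)} records with unknown SVTYPE: {detail}")
    site_ids = [r.site_id for r in records]
    gm = GenotypeMatrix(
        site_ids, sample_ids,
        gt=np.array([r[0] for r in rows]).reshape(len(site_ids), len(sample_ids)),
        cn=np.array([r[1] for r in rows]).reshape(len(site_ids), len(sample_ids)),
        ab=np.array([r[2] for r in rows]).reshape(len(site_ids), len(sample_ids)),
        lq=np.array([r[3] for r in rows]).reshape(len(site_ids), len(sample_ids)),
    )
    return records, gm


# ---------------------------------------------------------------------------
# Manifest I/O

MANIFEST_COLUMNS = ["sample_id", "donor_id", "study", "cell_type", "superpopulation", "sex"]
PAIR_COLUMNS = ["sample_a", "sample_b", "pair_type"]


def write_manifest(path, samples, pairs) -> None:
    df = pd.DataFrame([vars(s) for s in samples])[MANIFEST_COLUMNS]
    pdf = pd.DataFrame([vars(p) for p in pairs], columns=PAIR_COLUMNS)
    with open(path, "w") as fh:
        df.to_csv(fh, sep="\t", index=False)
        fh.write("#PAIRS\n")
        pdf.to_csv(fh, sep="\t", index=False)


def read_manifest(path):
    """Read the sample + replicate-pair manifest TSV; validates all invariants."""
    with open(path) as fh:
        text = fh.read()
    if "#PAIRS" in text:
        sample_part, pair_part = text.split("#PAIRS\n")
    else:
        sample_part, pair_part = text, ""
    import io

    sdf = pd.read_csv(io.StringIO(sample_part), sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(sdf.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    if sdf["sample_id"].duplicated().any():
        dups = sdf.loc[sdf["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids {dups}")
    samples = []
    for row_no, row in enumerate(sdf.itertuples(index=False), start=2):
        try:
            samples.append(SampleInfo(*[getattr(row, c) for c in MANIFEST_COLUMNS]))
        except ValueError as exc:
            raise ValueError(f"manifest row {row_no}: {exc}") from exc
    by_id = {s.sample_id: s for s in samples}
    pairs = []
    if pair_part.strip():
        pdf = pd.read_csv(io.StringIO(pair_part), sep="\t", dtype=str)
        for row_no, row in enumerate(pdf.itertuples(index=False), start=2):
            try:
                pair = ReplicatePair(row.sample_a, row.sample_b, row.pair_type)
            except ValueError as exc:
                raise ValueError(f"pair row {row_no}: {exc}") from exc
            for sid in (pair.sample_a, pair.sample_b):
                if sid not in by_id:
                    raise ValueError(f"pair row {row_no}: unknown sample {sid!r}")
            if pair.pair_type == "fib_ipsc":
                if by_id[pair.sample_a].donor_id != by_id[pair.sample_b].donor_id:
                    raise ValueError(
                        f"pair row {row_no}: fib_ipsc pair spans donors "
                        f"{by_id[pair.sample_a].donor_id!r} and {by_id[pair.sample_b].donor_id!r}"
                    )
            pairs.append(pair)
    return samples, pairs
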