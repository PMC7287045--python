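"""End-to-end orchestration: simulate -> filter -> dedup -> stitch -> unify ->
QC -> RR annotation, with deterministic seeds and reproducible outputs.

Stage order follows the harmonization flow: per-caller hard filters, then
within-caller dedup, Genome STRiP stitching, cross-caller unification, and
finally cohort QC flags and replication-rate annotation (QC flags annotate;
they never remove records).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import caller_filters, cohort_qc, redundancy, replication, synthgen, unify
from .model_io import FilterConfig, write_manifest, write_sv_vcf


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    sim: synthgen.SimConfig = None
    filters: FilterConfig = field(default_factory=FilterConfig.default)
    unify_rule: unify.UnifyRule = field(default_factory=unify.UnifyRule)

    def __post_init__(self):
        if self.sim is None:
            self.sim = synthgen.SimConfig(seed=self.seed)

    def config_hash(self) -> str:
        blob = json.dumps(
            {"seed": self.seed, "sim": _jsonable(asdict(self.sim)),
             "filters": self.filters, "unify": asdict(self.unify_rule)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-bundle pipeline; returns a result dict and
    writes TSV/VCF outputs under ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    log = [f"config_hash\t{cfg_hash}", f"seed\t{config.seed}"]

    bundle = synthgen.simulate_bundle(config.sim)
    write_manifest(out_dir / "manifest.tsv", bundle.samples, bundle.pairs)
    non_ipsc = [s.sample_id for s in bundle.samples if s.cell_type != "iPSC"]

    # stage 1: per-caller hard filters
    ss_records, ss_gm = bundle.views["speedseq"]
    gs_records, gs_gm = bundle.views["genomestrip"]
    melt_records, melt_gm = bundle.views["melt"]
    ss_report = caller_filters.filter_speedseq(ss_records, ss_gm, config.filters)
    gs_report = caller_filters.filter_genomestrip(gs_records, gs_gm, config.filters,
                                                  non_ipsc_samples=non_ipsc)
    melt_report = caller_filters.filter_melt(melt_records, config.filters)
    ss_f = ss_report.apply(ss_records)
    gs_f = gs_report.apply(gs_records)
    melt_f = melt_report.apply(melt_records)
    log.append(f"filter_speedseq\t{len(ss_records)} -> {len(ss_f)}")
    log.append(f"filter_genomestrip\t{len(gs_records)} -> {len(gs_f)}")
    log.append(f"filter_melt\t{len(melt_records)} -> {len(melt_f)}")

    # stage 2: within-caller dedup
    ss_clusters, ss_nr = redundancy.dedup_speedseq(ss_f, ss_gm)
    log.append(f"dedup_speedseq\t{len(ss_f)} -> {len(ss_nr)}")

    # stage 3: Genome STRiP stitching (fragment reconstruction)
    stitches = redundancy.stitch_genomestrip(gs_f, gs_gm)
    constituents = {sid for st in stitches for sid in st.constituents}
    gs_nr = [r for r in gs_f if r.site_id not in constituents]
    from .model_io import SVRecord

    for k, st in enumerate(stitches, start=1):
        rep = next(r for r in gs_f if r.site_id == st.constituents[0])
        gs_nr.append(SVRecord(
            site_id=f"stitch_{k:04d}", caller="genomestrip", chrom=st.chrom,
            start=st.start, end=st.end, svtype=rep.svtype, sv_len=st.end - st.start,
            quality=dict(rep.quality),
        ))
    # stitch breakpoints share the genotype row of their first constituent
    gs_nr_ids = [r.site_id for r in gs_nr]
    rows = []
    for r in gs_nr:
        src = r.site_id
        if src.startswith("stitch_"):
            k = int(src.split("_")[1])
            src = stitches[k - 1].constituents[0]
        rows.append(gs_gm.site_row(src))
    gs_nr_gm = type(gs_gm)(
        gs_nr_ids, gs_gm.sample_ids,
        gt=gs_gm.gt[rows], cn=gs_gm.cn[rows], ab=gs_gm.ab[rows], lq=gs_gm.lq[rows],
    )
    log.append(f"stitch_genomestrip\t{len(stitches)} stitch clusters; {len(gs_f)} -> {len(gs_nr)}")

    # stage 4: cross-caller unification
    clusters = unify.build_unify_graph(gs_nr, ss_nr, gs_nr_gm, ss_gm, config.unify_rule)
    final_cnv = unify.assemble_nonredundant(gs_nr, ss_nr, clusters)
    log.append(f"unify\t{len(gs_nr) + len(ss_nr)} -> {len(final_cnv)} (+{len(melt_f)} MEI)")

    # stage 5: cohort QC flags (annotate, never remove)
    biallelic_ss = [r.site_id for r in ss_nr if r.svtype in ("DEL", "DUP")]
    hwe = cohort_qc.hwe_test_all(ss_gm, bundle.samples, site_ids=biallelic_ss)
    batch = cohort_qc.batch_test_all(ss_gm, bundle.samples, site_ids=biallelic_ss)

    # stage 6: RR annotation on the final set
    rr_ss = replication.rr_table(ss_nr, ss_gm, bundle.pairs)
    rr_gs = replication.rr_table(gs_nr, gs_nr_gm, bundle.pairs)
    rr_melt = replication.rr_table(melt_f, melt_gm, bundle.pairs)
    rr = pd.concat([rr_ss, rr_gs, rr_melt], ignore_index=True)

    # outputs (deterministic ordering everywhere)
    def _tsv(df, name):
        df.to_csv(out_dir / name, sep="\t", index=False, float_format="%.6g")

    _tsv(ss_report.to_frame().sort_values("site_id"), "filter_speedseq.tsv")
    _tsv(gs_report.to_frame().sort_values("site_id"), "filter_genomestrip.tsv")
    _tsv(melt_report.to_frame().sort_values("site_id"), "filter_melt.tsv")
    cluster_rows = []
    for i, c in enumerate(ss_clusters, start=1):
        for m in c.members:
            cluster_rows.append({"cluster_id": f"ssdedup_{i:04d}", "member": m,
                                 "role": "primary" if m == c.primary_id else "secondary",
                                 "rule": c.provenance})
    for i, c in enumerate(clusters, start=1):
        for m in c.members:
            cluster_rows.append({"cluster_id": f"unify_{i:04d}", "member": m,
                                 "role": "primary" if m == c.primary_id else "secondary",
                                 "rule": c.provenance})
    _tsv(pd.DataFrame(cluster_rows, columns=["cluster_id", "member", "role", "rule"]),
         "clusters.tsv")
    _tsv(rr.sort_values("site_id"), "rr_table.tsv")
    _tsv(hwe, "hwe_flags.tsv")
    _tsv(batch, "batch_flags.tsv")

    final_ids = {r.site_id for r in final_cnv}
    gm_lookup = {}
    for r in final_cnv:
        gm_lookup[r.site_id] = (gs_nr_gm if r.caller == "genomestrip" else ss_gm)
    # write the final CNV call set as one VCF per source matrix
    final_gs = [r for r in final_cnv if r.caller == "genomestrip"]
    final_ss = [r for r in final_cnv if r.caller == "speedseq"]
    if final_gs:
        write_sv_vcf(out_dir / "final_genomestrip.vcf", final_gs,
                     gs_nr_gm.subset_sites([r.site_id for r in final_gs]),
                     contigs=list(config.sim.contigs))
    if final_ss:
        write_sv_vcf(out_dir / "final_speedseq.vcf", final_ss,
                     ss_gm.subset_sites([r.site_id for r in final_ss]),
                     contigs=list(config.sim.contigs))
    if melt_f:
        write_sv_vcf(out_dir / "final_melt.vcf", melt_f,
                     melt_gm.subset_sites([r.site_id for r in melt_f]),
                     contigs=list(config.sim.contigs))
    (out_dir / "run_log.tsv").write_text("\n".join(log) + "\n")

    return {
        "config_hash": cfg_hash,
        "bundle": bundle,
        "filtered": {"speedseq": ss_f, "genomestrip": gs_f, "melt": melt_f},
        "reports": {"speedseq": ss_report, "genomestrip": gs_report, "melt": melt_report},
        "dedup_clusters": ss_clusters,
        "stitches": stitches,
        "unify_clusters": clusters,
        "final_cnv": final_cnv,
        "final_mei": melt_f,
        "rr": rr,
        "hwe": hwe,
        "batch": batch,
        "n_final": len(final_cnv) + len(melt_f),
        "_final_ids": final_ids,
    }
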