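"""Per-caller hard filters, within-caller dedup, and CNV stitching.

Applies the published per-caller thresholds (MSQ, GSCNQUAL, MELT flags +
ASSESS) to a synthetic multi-caller call set, collapses redundant overlapping
calls with the reciprocal-overlap + genotype-correlation graph, and stitches
adjacent read-depth CNV fragments back into single breakpoints.
"""

from svharmony import SimConfig, simulate_bundle
from svharmony.caller_filters import filter_genomestrip, filter_melt, filter_speedseq
from svharmony.redundancy import dedup_speedseq, stitch_genomestrip

bundle = simulate_bundle(SimConfig(seed=2, fragmentation_prob=0.3))
non_ipsc = [s.sample_id for s in bundle.samples if s.cell_type != "iPSC"]

ss_records, ss_gm = bundle.views["speedseq"]
report = filter_speedseq(ss_records, ss_gm)
print(f"speedseq: {len(ss_records)} records -> {report.n_kept} kept")
print("removal reasons:", dict(report.reason_counts()))

gs_records, gs_gm = bundle.views["genomestrip"]
gs_report = filter_genomestrip(gs_records, gs_gm, non_ipsc_samples=non_ipsc)
print(f"\ngenomestrip: {len(gs_records)} -> {gs_report.n_kept} kept "
      f"({dict(gs_report.reason_counts())})")

melt_records, _ = bundle.views["melt"]
melt_report = filter_melt(melt_records)
print(f"melt: {len(melt_records)} -> {melt_report.n_kept} kept")

clusters, nonredundant = dedup_speedseq(report.apply(ss_records), ss_gm)
print(f"\nspeedseq dedup: {report.n_kept} filtered records -> "
      f"{len(nonredundant)} non-redundant ({len(clusters)} clusters collapsed)")

stitches = stitch_genomestrip(gs_report.apply(gs_records), gs_gm)
print(f"genomestrip stitching: {len(stitches)} fragment clusters merged into "
      "single breakpoints (each spans first fragment start to last fragment end)")
for st in stitches[:3]:
    print(f"  {st.chrom}:{st.start}-{st.end} from {len(st.constituents)} fragments")
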