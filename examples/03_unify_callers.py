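"""Cross-caller unification of read-depth and read-pair call sets.

Builds the two-stage unification graph (overlap/containment, then genotype-
evidence correlation) between Genome STRiP-style and SpeedSeq-style calls,
selects a primary site per cluster, and assembles the final non-redundant
call set.
"""

from svharmony import SimConfig, simulate_bundle
from svharmony.caller_filters import filter_genomestrip, filter_speedseq
from svharmony.unify import assemble_nonredundant, build_unify_graph, unify_parameter_sweep

bundle = simulate_bundle(SimConfig(seed=3, uniform_error=0.01))
non_ipsc = [s.sample_id for s in bundle.samples if s.cell_type != "iPSC"]

ss_records, ss_gm = bundle.views["speedseq"]
gs_records, gs_gm = bundle.views["genomestrip"]
ss = filter_speedseq(ss_records, ss_gm).apply(ss_records)
gs = filter_genomestrip(gs_records, gs_gm, non_ipsc_samples=non_ipsc).apply(gs_records)

clusters = build_unify_graph(gs, ss, gs_gm, ss_gm)
final = assemble_nonredundant(gs, ss, clusters)
print(f"{len(gs)} read-depth + {len(ss)} read-pair records -> "
      f"{len(clusters)} cross-caller clusters -> {len(final)} non-redundant sites")
gs_primaries = sum(1 for c in clusters if c.primary_id.startswith("genomestrip"))
print(f"primaries: {gs_primaries} Genome STRiP, {len(clusters) - gs_primaries} SpeedSeq "
      "(read-depth callers win by default; rMEI clusters keep the read-pair call)")

sweep = unify_parameter_sweep(gs, ss, gs_gm, ss_gm,
                              ro_grid=[0.1, 0.5, 0.9], r2_grid=[0.1, 0.5, 0.9])
print("\nthreshold sweep (stricter cuts combine fewer variants):")
print(sweep.to_string(index=False))
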