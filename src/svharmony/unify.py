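"""Cross-caller unification of read-depth (Genome STRiP) and read-pair
(SpeedSeq) call sets into one non-redundant set with primary-site selection.

Stage 1 connects type-compatible pairs with > 50% reciprocal overlap, or full
containment where the inner variant is at least 40% of the larger one. Stage
2 re-tests every pair inside each stage-1 component on genotype evidence
(squared Pearson correlation of copy numbers for Genome STRiP, allele balance
for SpeedSeq, cross-channel between callers) and keeps edges with R^2 above
the threshold — 0.5 in general, strictly > 0 for components that pair a
SpeedSeq duplication and deletion with a Genome STRiP mCNV. Stage-2 connected
components are the final clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .model_io import GenotypeMatrix
from .redundancy import MergeCluster, _pearson, _sorted_records, contains, reciprocal_overlap, _components


@dataclass
class UnifyRule:
    min_ro: float = 0.5
    containment_min_frac_of_larger: float = 0.4
    r2_general: float = 0.5
    r2_mcnv_mixed: float = 0.0  # strictly >

    def __post_init__(self):
        for name in ("min_ro", "containment_min_frac_of_larger", "r2_general", "r2_mcnv_mixed"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")


_COMPATIBLE = {
    frozenset({"mCNV", "DEL"}),
    frozenset({"mCNV", "DUP"}),
    frozenset({"DEL", "rMEI"}),
}


def type_compatible(a: str, b: str) -> bool:
    """Same class, mCNV with DEL/DUP, or DEL with rMEI."""
    return a == b or frozenset({a, b}) in _COMPATIBLE


def _evidence(rec, gs_cn: GenotypeMatrix, ss_ab: GenotypeMatrix):
    if rec.caller == "genomestrip":
        return gs_cn.cn_row(rec.site_id), gs_cn.sample_ids
    return ss_ab.ab_row(rec.site_id), ss_ab.sample_ids


def _evidence_r2(a, b, gs_cn, ss_ab):
    """Squared Pearson correlation of genotype evidence on shared samples."""
    va, sa = _evidence(a, gs_cn, ss_ab)
    vb, sb = _evidence(b, gs_cn, ss_ab)
    if sa is sb or sa == sb:
        xa, xb = va, vb
    else:
        shared = [s for s in sa if s in set(sb)]
        if len(shared) < 2:
            return np.nan
        idx_a = {s: i for i, s in enumerate(sa)}
        idx_b = {s: i for i, s in enumerate(sb)}
        xa = np.asarray([va[idx_a[s]] for s in shared], dtype=float)
        xb = np.asarray([vb[idx_b[s]] for s in shared], dtype=float)
    r = _pearson(xa, xb)
    return np.nan if not np.isfinite(r) else r * r


def build_unify_graph(gs_records, ss_records, gs_cn: GenotypeMatrix,
                      ss_ab: GenotypeMatrix, rule: UnifyRule = None):
    """Two-stage overlap + genotype-evidence clustering across the two
    call sets. Returns a list of MergeClusters (including singletons as
    clusters of size one is NOT done; only multi-member clusters and the
    degree map are returned via cluster.edges)."""
    rule = rule or UnifyRule()
    recs = _sorted_records(list(gs_records) + list(ss_records))
    by_id = {r.site_id: r for r in recs}
    g1 = nx.Graph()
    g1.add_nodes_from(r.site_id for r in recs)
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            if a.caller == b.caller:
                continue
            if not type_compatible(a.svtype, b.svtype):
                continue
            fa, fb = reciprocal_overlap(a.interval(), b.interval())
            edge = min(fa, fb) > rule.min_ro
            if not edge:
                if contains(a.interval(), b.interval()) or contains(b.interval(), a.interval()):
                    small, large = (a, b) if a.length <= b.length else (b, a)
                    if small.length >= rule.containment_min_frac_of_larger * large.length:
                        edge = True
            if edge:
                g1.add_edge(a.site_id, b.site_id)

    clusters = []
    for comp in _components(g1):
        if len(comp) == 1:
            continue
        members = [by_id[s] for s in comp]
        ss_types = {m.svtype for m in members if m.caller == "speedseq"}
        has_gs_mcnv = any(m.caller == "genomestrip" and m.svtype == "mCNV" for m in members)
        mixed = {"DUP", "DEL"} <= ss_types and has_gs_mcnv
        threshold = rule.r2_mcnv_mixed if mixed else rule.r2_general
        g2 = nx.Graph()
        g2.add_nodes_from(comp)
        edge_info = []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                r2 = _evidence_r2(a, b, gs_cn, ss_ab)
                if np.isfinite(r2) and r2 > threshold:
                    g2.add_edge(a.site_id, b.site_id)
                    fa, fb = reciprocal_overlap(a.interval(), b.interval())
                    edge_info.append((a.site_id, b.site_id, fa, fb, r2))
        for sub in _components(g2):
            if len(sub) == 1:
                continue
            sub_edges = [e for e in edge_info if e[0] in sub and e[1] in sub]
            cluster = MergeCluster(members=sorted(sub), primary_id=sorted(sub)[0],
                                   secondaries=[], provenance="unify", edges=sub_edges)
            cluster = select_primary(cluster, by_id)
            clusters.append(cluster)
    return clusters


def select_primary(cluster: MergeCluster, records_by_id) -> MergeCluster:
    """Designate the cluster primary.

    Per caller, the candidate is the member with the highest degree in the
    cluster graph (ties by quality score, then smaller site_id). A Genome
    STRiP deletion clustered with a SpeedSeq rMEI yields the SpeedSeq
    primary; otherwise the Genome STRiP candidate wins.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    degree = {m: 0 for m in cluster.members}
    for u, v, *_ in cluster.edges:
        degree[u] += 1
        degree[v] += 1

    def quality(sid):
        rec = records_by_id[sid]
        key = "GSCNQUAL" if rec.caller == "genomestrip" else "MSQ"
        return rec.quality.get(key, rec.quality.get("QUAL", -np.inf))

    candidates = {}
    for caller in ("genomestrip", "speedseq"):
        ids = [m for m in cluster.members if records_by_id[m].caller == caller]
        if ids:
            ids.sort(key=lambda s: (-degree[s], -quality(s), s))
            candidates[caller] = ids[0]

    has_gs_del = any(records_by_id[m].caller == "genomestrip" and records_by_id[m].svtype == "DEL"
                     for m in cluster.members)
    has_ss_rmei = any(records_by_id[m].caller == "speedseq" and records_by_id[m].svtype == "rMEI"
                      for m in cluster.members)
    if has_gs_del and has_ss_rmei and "speedseq" in candidates:
        primary = candidates["speedseq"]
    elif "genomestrip" in candidates:
        primary = candidates["genomestrip"]
    else:
        primary = candidates["speedseq"]
    cluster.primary_id = primary
    cluster.secondaries = [m for m in cluster.members if m != primary]
    return cluster


def assemble_nonredundant(gs_records, ss_records, clusters):
    """Final set = cluster primaries plus all un-clustered records."""
    clustered = set()
    primaries = []
    for c in clusters:
        clustered.update(c.members)
        primaries.append(c.primary_id)
    primary_set = set(primaries)
    out = []
    for rec in _sorted_records(list(gs_records) + list(ss_records)):
        if rec.site_id in primary_set or rec.site_id not in clustered:
            out.append(rec)
    return out


def unify_parameter_sweep(gs_records, ss_records, gs_cn, ss_ab, ro_grid, r2_grid):
    """Grid sweep over (reciprocal overlap, genotype R^2) thresholds.

    Reports, per cell, how many variants entered clusters (n_input_combined)
    and the resulting non-redundant count (n_output).
    """
    import pandas as pd

    rows = []
    n_total = len(gs_records) + len(ss_records)
    for ro in ro_grid:
        for r2 in r2_grid:
            rule = UnifyRule(min_ro=ro, r2_general=r2)
            clusters = build_unify_graph(gs_records, ss_records, gs_cn, ss_ab, rule)
            n_in = sum(len(c.members) for c in clusters)
            n_out = n_total - n_in + len(clusters)
            rows.append({"ro": ro, "r2": r2, "n_input_combined": n_in, "n_output": n_out})
    return pd.DataFrame(rows, columns=["ro", "r2", "n_input_combined", "n_output"])
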