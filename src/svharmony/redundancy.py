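"""Graph-based redundancy collapsing, CNV stitching, and generic merging.

All clustering operates on connected components of an explicit pair graph.
Correlations with zero variance in either vector are undefined and treated
as failing the threshold (a monomorphic row carries no linking evidence).
Components and pairs are processed in sorted (chrom, start, site_id) order so
output is independent of input order; quality ties break on the smaller
site_id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .model_io import GenotypeMatrix


@dataclass
class MergeCluster:
    members: list
    primary_id: str
    secondaries: list
    provenance: str
    edges: list = field(default_factory=list)  # (id_a, id_b, frac_a, frac_b, corr)

    def __post_init__(self):
        if self.primary_id not in self.members:
            raise ValueError("primary must be a cluster member")


@dataclass
class StitchCluster:
    constituents: list  # site_ids sorted by start
    chrom: str
    start: int  # min start
    end: int  # max end
    status: str  # stitched | unstitched | filtered
    is_preexisting_breakpoint: bool


def reciprocal_overlap(a, b):
    """Overlap fractions (overlap/len_a, overlap/len_b); (0,0) when the
    intervals are disjoint or on different chromosomes.

    Intervals are (chrom, start, end) half-open.
    """
    if a[0] != b[0]:
        return (0.0, 0.0)
    ov = min(a[2], b[2]) - max(a[1], b[1])
    if ov <= 0:
        return (0.0, 0.0)
    return (ov / (a[2] - a[1]), ov / (b[2] - b[1]))


def contains(outer, inner) -> bool:
    return outer[0] == inner[0] and outer[1] <= inner[1] and inner[2] <= outer[2]


def _pearson(x, y):
    """Pearson r over positions finite in both; nan if undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return np.nan
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return np.nan
    return float(np.corrcoef(xs, ys)[0, 1])


def _sorted_records(records):
    return sorted(records, key=lambda r: (r.chrom, r.start, r.site_id))


def _components(graph):
    """Connected components in deterministic order (sorted member lists,
    ordered by first member)."""
    comps = [sorted(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: c[0])


def _modal(values):
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return np.nan
    vals, counts = np.unique(finite, return_counts=True)
    return float(vals[np.argmax(counts)])


# ---------------------------------------------------------------------------
# within-caller dedup


def dedup_speedseq(records, gmatrix: GenotypeMatrix, min_ro=0.5, ab_r=0.25,
                   containment_r=0.5):
    """Collapse putatively identical read-pair calls.

    (1) edges between records with reciprocal overlap >= 50%; (2) within each
    component keep only edges whose allele-balance correlation exceeds 0.25;
    (3) per refined component the max-MSQ record is primary; (4) a record
    fully contained in another with AB correlation >= 0.5 is additionally
    collapsed onto the higher-MSQ record.

    Returns (clusters, non_redundant_records).
    """
    recs = _sorted_records(records)
    by_id = {r.site_id: r for r in recs}
    g1 = nx.Graph()
    g1.add_nodes_from(r.site_id for r in recs)
    pair_fracs = {}
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            if a.chrom != b.chrom:
                continue
            fa, fb = reciprocal_overlap(a.interval(), b.interval())
            if min(fa, fb) >= min_ro:
                g1.add_edge(a.site_id, b.site_id)
                pair_fracs[(a.site_id, b.site_id)] = (fa, fb)

    g2 = nx.Graph()
    g2.add_nodes_from(g1.nodes)
    edge_info = {}
    for u, v in sorted(g1.edges):
        r = _pearson(gmatrix.ab_row(u), gmatrix.ab_row(v))
        if np.isfinite(r) and r > ab_r:
            g2.add_edge(u, v)
            fa, fb = pair_fracs.get((u, v), pair_fracs.get((v, u), (0, 0)))
            edge_info[(u, v)] = (fa, fb, r)

    # containment rule: collapse contained pairs with AB correlation >= 0.5
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            if a.site_id == b.site_id or a.chrom != b.chrom:
                continue
            if contains(a.interval(), b.interval()) or contains(b.interval(), a.interval()):
                if g2.has_edge(a.site_id, b.site_id):
                    continue
                r = _pearson(gmatrix.ab_row(a.site_id), gmatrix.ab_row(b.site_id))
                if np.isfinite(r) and r >= containment_r:
                    g2.add_edge(a.site_id, b.site_id)
                    fa, fb = reciprocal_overlap(a.interval(), b.interval())
                    edge_info[(a.site_id, b.site_id)] = (fa, fb, r)

    clusters = []
    kept = []
    for comp in _components(g2):
        if len(comp) == 1:
            kept.append(by_id[comp[0]])
            continue
        primary = max(comp, key=lambda s: (by_id[s].quality.get("MSQ", -np.inf), s))
        # ties: higher MSQ wins, then lexicographically smaller id
        best_msq = by_id[primary].quality.get("MSQ", -np.inf)
        tied = sorted(s for s in comp if by_id[s].quality.get("MSQ", -np.inf) == best_msq)
        primary = tied[0]
        edges = [
            (u, v, *edge_info[(u, v)])
            for u, v in sorted(g2.edges)
            if u in comp and v in comp and (u, v) in edge_info
        ]
        clusters.append(MergeCluster(members=comp, primary_id=primary,
                                     secondaries=[s for s in comp if s != primary],
                                     provenance="speedseq_dedup", edges=edges))
        kept.append(by_id[primary])
    return clusters, _sorted_records(kept)


def _nonmode_diff_frac(cn_a, cn_b):
    """Fraction of genotype differences over the union of samples that are
    non-mode at either site; nan when the union is empty."""
    a = np.asarray(cn_a, dtype=float)
    b = np.asarray(cn_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        return np.nan
    mode_a, mode_b = _modal(a[ok]), _modal(b[ok])
    union = ok & ((a != mode_a) | (b != mode_b))
    if not union.any():
        return np.nan
    return float(np.mean(a[union] != b[union]))


def dedup_genomestrip(set_a, set_b, gm_a: GenotypeMatrix, gm_b: GenotypeMatrix,
                      non_ipsc, min_ro=0.5, cn_r=0.95, max_nonmode_diff=0.05):
    """Collapse redundant read-depth CNVs across two discovery sets.

    A pair is redundant when reciprocal overlap >= 50%, copy-number Pearson
    correlation among non-iPSC samples > 0.95, and < 5% of non-mode
    genotypes differ (union denominator). Exact-coordinate pairs resolve
    first to the larger GSCNQUAL sum; remaining overlaps resolve greedily by
    highest average percentage overlap within each component.

    Returns (clusters, non_redundant_records).
    """
    if not non_ipsc:
        raise ValueError("non-iPSC sample set must be non-empty")
    cols_a = [gm_a.sample_col(s) for s in non_ipsc if s in gm_a._sample_index]
    cols_b = [gm_b.sample_col(s) for s in non_ipsc if s in gm_b._sample_index]
    if not cols_a or not cols_b:
        raise ValueError("non-iPSC samples absent from a genotype matrix")

    def quality_sum(rec):
        return rec.quality.get("GSCNQUAL", 0.0)

    def cn_vec(rec):
        if rec.site_id in gm_a._site_index:
            return gm_a.cn[gm_a.site_row(rec.site_id)][cols_a]
        return gm_b.cn[gm_b.site_row(rec.site_id)][cols_b]

    all_recs = _sorted_records(list(set_a) + list(set_b))
    by_id = {r.site_id: r for r in all_recs}
    redundant_pairs = []
    for i in range(len(all_recs)):
        for j in range(i + 1, len(all_recs)):
            a, b = all_recs[i], all_recs[j]
            fa, fb = reciprocal_overlap(a.interval(), b.interval())
            if min(fa, fb) < min_ro:
                continue
            r = _pearson(cn_vec(a), cn_vec(b))
            if not (np.isfinite(r) and r > cn_r):
                continue
            diff = _nonmode_diff_frac(cn_vec(a), cn_vec(b))
            if np.isfinite(diff) and diff >= max_nonmode_diff:
                continue
            redundant_pairs.append((a.site_id, b.site_id, fa, fb, r))

    removed = set()
    clusters = []

    # pass 1: exact-coordinate pairs
    for u, v, fa, fb, r in redundant_pairs:
        a, b = by_id[u], by_id[v]
        if (a.chrom, a.start, a.end) == (b.chrom, b.start, b.end):
            if u in removed or v in removed:
                continue
            primary = max((u, v), key=lambda s: (quality_sum(by_id[s]),))
            if quality_sum(by_id[u]) == quality_sum(by_id[v]):
                primary = min(u, v)
            secondary = v if primary == u else u
            removed.add(secondary)
            clusters.append(MergeCluster(members=sorted([u, v]), primary_id=primary,
                                         secondaries=[secondary],
                                         provenance="gs_dedup_exact",
                                         edges=[(u, v, fa, fb, r)]))

    # pass 2: greedy within components by average overlap
    graph = nx.Graph()
    live_pairs = [p for p in redundant_pairs
                  if p[0] not in removed and p[1] not in removed
                  and (by_id[p[0]].chrom, by_id[p[0]].start, by_id[p[0]].end)
                  != (by_id[p[1]].chrom, by_id[p[1]].start, by_id[p[1]].end)]
    for u, v, fa, fb, r in live_pairs:
        graph.add_edge(u, v)
    for comp in _components(graph):
        comp_set = set(comp)
        comp_pairs = [p for p in live_pairs if p[0] in comp_set and p[1] in comp_set]
        # highest average overlap first; ties by quality sum then id
        comp_pairs.sort(key=lambda p: (-(p[2] + p[3]) / 2,
                                       -(quality_sum(by_id[p[0]]) + quality_sum(by_id[p[1]])),
                                       p[0], p[1]))
        members, edges, secondaries = set(), [], set()
        for u, v, fa, fb, r in comp_pairs:
            if u in secondaries or v in secondaries:
                continue
            primary = max((u, v), key=lambda s: (quality_sum(by_id[s]), ))
            if quality_sum(by_id[u]) == quality_sum(by_id[v]):
                primary = min(u, v)
            secondary = v if primary == u else u
            secondaries.add(secondary)
            members.update((u, v))
            edges.append((u, v, fa, fb, r))
        if members:
            alive = sorted(members - secondaries)
            primary = alive[0] if alive else sorted(members)[0]
            clusters.append(MergeCluster(members=sorted(members), primary_id=primary,
                                         secondaries=sorted(secondaries),
                                         provenance="gs_dedup_greedy", edges=edges))
            removed.update(secondaries)

    kept = [r for r in all_recs if r.site_id not in removed]
    return clusters, kept


# ---------------------------------------------------------------------------
# Genome STRiP stitching


def _concordance_nonmode(cn_a, cn_b):
    """Concordance of copy-number genotypes among the union of non-mode
    samples of either site; nan when the union is empty."""
    frac = _nonmode_diff_frac(cn_a, cn_b)
    return np.nan if not np.isfinite(frac) else 1.0 - frac


def stitch_genomestrip(records, gmatrix: GenotypeMatrix, max_gap=30_000,
                       min_corr=0.9, min_concordance=0.8):
    """Stitch adjacent read-depth CNV fragments into single breakpoints.

    Per chromosome, CNV pairs with copy-number correlation > 0.9 form a
    graph; within each connected component, position-sorted adjacent pairs
    merge when they additionally show >= 80% concordance among the union of
    non-mode samples and lie within ``max_gap`` of each other. The stitch
    interval spans min start to max end; a member already containing all the
    others is a pre-existing breakpoint rather than a new one.
    """
    recs = _sorted_records(records)
    by_id = {r.site_id: r for r in recs}
    out = []
    by_chrom = {}
    for r in recs:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        chrom_recs = by_chrom[chrom]
        graph = nx.Graph()
        graph.add_nodes_from(r.site_id for r in chrom_recs)
        for i in range(len(chrom_recs)):
            for j in range(i + 1, len(chrom_recs)):
                a, b = chrom_recs[i], chrom_recs[j]
                r = _pearson(gmatrix.cn_row(a.site_id), gmatrix.cn_row(b.site_id))
                if np.isfinite(r) and r > min_corr:
                    graph.add_edge(a.site_id, b.site_id)
        for comp in _components(graph):
            if len(comp) == 1:
                continue
            ordered = sorted(comp, key=lambda s: (by_id[s].start, s))
            # merge adjacent pairs passing concordance + gap rules
            merge_graph = nx.Graph()
            merge_graph.add_nodes_from(ordered)
            for a_id, b_id in zip(ordered, ordered[1:]):
                a, b = by_id[a_id], by_id[b_id]
                gap = b.start - a.end
                if gap > max_gap:
                    continue
                conc = _concordance_nonmode(gmatrix.cn_row(a_id), gmatrix.cn_row(b_id))
                if np.isfinite(conc) and conc >= min_concordance:
                    merge_graph.add_edge(a_id, b_id)
            for sub in _components(merge_graph):
                if len(sub) == 1:
                    continue
                members = sorted(sub, key=lambda s: (by_id[s].start, s))
                start = min(by_id[s].start for s in members)
                end = max(by_id[s].end for s in members)
                preexisting = any(
                    by_id[s].start == start and by_id[s].end == end for s in members
                )
                out.append(StitchCluster(constituents=members, chrom=chrom,
                                         start=start, end=end, status="stitched",
                                         is_preexisting_breakpoint=preexisting))
    return out


def validate_stitch(stitch_cn_row, constituent_cn_rows, lq_fraction,
                    min_corr=0.9, max_lq=0.1):
    """Validate a genotyped stitch breakpoint against its constituents.

    Stitched iff the mean correlation against constituents is >= 0.9, the
    low-quality genotype fraction is <= 10%, and the row is polymorphic.
    Otherwise unstitched; a newly created breakpoint failing the LQ or
    polymorphism rule is additionally marked filtered.
    """
    stitch = np.asarray(stitch_cn_row, dtype=float)
    rs = [_pearson(stitch, c) for c in constituent_cn_rows]
    rs = [r for r in rs if np.isfinite(r)]
    mean_r = float(np.mean(rs)) if rs else np.nan
    finite = stitch[np.isfinite(stitch)]
    polymorphic = finite.size > 0 and np.unique(finite).size > 1
    if np.isfinite(mean_r) and mean_r >= min_corr and lq_fraction <= max_lq and polymorphic:
        return "stitched"
    if lq_fraction > max_lq or not polymorphic:
        return "filtered"
    return "unstitched"


# ---------------------------------------------------------------------------
# cross-sample LCNV clustering and generic merging


def cluster_lcnv(records, gmatrix: GenotypeMatrix = None, min_ro=0.8):
    """Group per-sample large-CNV calls into merged sites.

    Records with reciprocal overlap >= 80% form connected components; each
    component becomes one site spanning min start to max end. Singletons pass
    through unchanged. Copy numbers, when supplied, are rounded to integers.

    Returns (merged list of dicts, clusters) where each merged entry has
    site_id, chrom, start, end, svtype, members.
    """
    recs = _sorted_records(records)
    graph = nx.Graph()
    graph.add_nodes_from(r.site_id for r in recs)
    by_id = {r.site_id: r for r in recs}
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            fa, fb = reciprocal_overlap(a.interval(), b.interval())
            if min(fa, fb) >= min_ro:
                graph.add_edge(a.site_id, b.site_id)
    merged, clusters = [], []
    if gmatrix is not None:
        gmatrix.cn = np.where(np.isfinite(gmatrix.cn), np.round(gmatrix.cn), gmatrix.cn)
    for k, comp in enumerate(_components(graph), start=1):
        members = sorted(comp, key=lambda s: (by_id[s].start, s))
        start = min(by_id[s].start for s in members)
        end = max(by_id[s].end for s in members)
        rep = by_id[members[0]]
        merged.append({"site_id": f"lcnv_merged_{k:04d}" if len(members) > 1 else members[0],
                       "chrom": rep.chrom, "start": start, "end": end,
                       "svtype": rep.svtype, "members": members})
        if len(members) > 1:
            clusters.append(MergeCluster(members=list(members), primary_id=members[0],
                                         secondaries=members[1:], provenance="lcnv_cluster"))
    return merged, clusters


def merge_generic(records_by_caller, min_ro=0.5, class_match=True):
    """Cross-caller merge by reciprocal overlap and matching classes.

    Pairs from different callers with RO >= ``min_ro`` (and equal svtype when
    ``class_match``) are edges; connected components become merged sites
    spanning min start to max end, with per-cluster caller support counts.
    """
    all_recs = []
    for caller in sorted(records_by_caller):
        all_recs.extend(records_by_caller[caller])
    all_recs = _sorted_records(all_recs)
    by_id = {r.site_id: r for r in all_recs}
    graph = nx.Graph()
    graph.add_nodes_from(r.site_id for r in all_recs)
    for i in range(len(all_recs)):
        for j in range(i + 1, len(all_recs)):
            a, b = all_recs[i], all_recs[j]
            if class_match and a.svtype != b.svtype:
                continue
            fa, fb = reciprocal_overlap(a.interval(), b.interval())
            if min(fa, fb) >= min_ro:
                graph.add_edge(a.site_id, b.site_id)
    merged = []
    for k, comp in enumerate(_components(graph), start=1):
        members = sorted(comp, key=lambda s: (by_id[s].start, s))
        start = min(by_id[s].start for s in members)
        end = max(by_id[s].end for s in members)
        callers = sorted({by_id[s].caller for s in members})
        rep = by_id[members[0]]
        merged.append({"site_id": f"merged_{k:05d}", "chrom": rep.chrom,
                       "start": start, "end": end, "svtype": rep.svtype,
                       "members": members, "callers": callers,
                       "support": len(callers)})
    return merged
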