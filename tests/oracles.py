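"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: plain loops, a hand-rolled disjoint-set (no networkx),
and direct transcriptions of each matching rule. These never import the
clustering code they check.
"""

import numpy as np

MISSING = -1


class DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def components(self):
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def rr_oracle(row, pairs, mode="strict", channel="gt"):
    """Direct transcription of the replication-rate definition."""
    row = np.asarray(row, dtype=float)
    if channel == "cn":
        finite = row[np.isfinite(row)]
        vals, cts = np.unique(finite, return_counts=True)
        ref = vals[np.argmax(cts)] if finite.size else np.nan
        is_missing = lambda v: not np.isfinite(v)
    else:
        ref = 0.0
        is_missing = lambda v: v == MISSING
    informative = matched = 0
    for ia, ib in pairs:
        a, b = row[ia], row[ib]
        if is_missing(a) or is_missing(b):
            continue
        if a == ref and b == ref:
            continue
        informative += 1
        if mode == "strict":
            if a == b and a != ref:
                matched += 1
        else:
            if a != ref and b != ref:
                matched += 1
    return (matched / informative if informative else np.nan), informative


def ro_oracle(a, b):
    if a[0] != b[0]:
        return (0.0, 0.0)
    ov = min(a[2], b[2]) - max(a[1], b[1])
    if ov <= 0:
        return (0.0, 0.0)
    return ov / (a[2] - a[1]), ov / (b[2] - b[1])


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
        return np.nan
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def components_oracle(ids, edge_fn):
    """Connected components from an arbitrary pairwise predicate."""
    dsu = DSU(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if edge_fn(a, b):
                dsu.union(a, b)
    return dsu.components()


def dedup_speedseq_oracle(records, gmatrix):
    """Final component structure of the read-pair dedup rules."""
    by_id = {r.site_id: r for r in records}
    ids = sorted(by_id)

    def ab(sid):
        return gmatrix.ab_row(sid)

    def stage_edge(a_id, b_id):
        a, b = by_id[a_id], by_id[b_id]
        fa, fb = ro_oracle(a.interval(), b.interval())
        if min(fa, fb) >= 0.5:
            r = pearson_oracle(ab(a_id), ab(b_id))
            if np.isfinite(r) and r > 0.25:
                return True
        inside = (
            (a.chrom == b.chrom)
            and ((a.start <= b.start and b.end <= a.end) or (b.start <= a.start and a.end <= b.end))
        )
        if inside:
            r = pearson_oracle(ab(a_id), ab(b_id))
            if np.isfinite(r) and r >= 0.5:
                return True
        return False

    comps = components_oracle(ids, stage_edge)
    survivors = set()
    for comp in comps:
        best = max(comp, key=lambda s: (by_id[s].quality.get("MSQ", -np.inf), ))
        best_q = by_id[best].quality.get("MSQ", -np.inf)
        survivors.add(min(s for s in comp if by_id[s].quality.get("MSQ", -np.inf) == best_q))
    return comps, survivors


def dedup_genomestrip_oracle(set_a, set_b, gm_a, gm_b, cols_a, cols_b,
                             min_ro=0.5, cn_r=0.95, max_diff=0.05):
    """Redundant (secondary) ids under the two-set read-depth dedup rules."""
    recs = {r.site_id: r for r in list(set_a) + list(set_b)}

    def cn(sid):
        gm, cols = (gm_a, cols_a) if sid in gm_a._site_index else (gm_b, cols_b)
        return gm.cn[gm.site_row(sid)][cols]

    def modal(v):
        f = v[np.isfinite(v)]
        vals, cts = np.unique(f, return_counts=True)
        return vals[np.argmax(cts)]

    def redundant(u, v):
        fa, fb = ro_oracle(recs[u].interval(), recs[v].interval())
        if min(fa, fb) < min_ro:
            return None
        r = pearson_oracle(cn(u), cn(v))
        if not (np.isfinite(r) and r > cn_r):
            return None
        a, b = cn(u), cn(v)
        ok = np.isfinite(a) & np.isfinite(b)
        if not ok.any():
            return None
        union = ok & ((a != modal(a[ok])) | (b != modal(b[ok])))
        if union.any() and np.mean(a[union] != b[union]) >= max_diff:
            return None
        return (fa, fb)

    qual = lambda s: recs[s].quality.get("GSCNQUAL", 0.0)
    ids = sorted(recs)
    pairs = []
    for i, u in enumerate(ids):
        for v in ids[i + 1:]:
            hit = redundant(u, v)
            if hit:
                pairs.append((u, v, *hit))
    removed = set()
    # exact-coordinate pass
    for u, v, fa, fb in pairs:
        a, b = recs[u], recs[v]
        if (a.chrom, a.start, a.end) == (b.chrom, b.start, b.end):
            if u in removed or v in removed:
                continue
            if qual(u) > qual(v):
                removed.add(v)
            elif qual(v) > qual(u):
                removed.add(u)
            else:
                removed.add(max(u, v))
    live = [p for p in pairs if p[0] not in removed and p[1] not in removed
            and (recs[p[0]].chrom, recs[p[0]].start, recs[p[0]].end)
            != (recs[p[1]].chrom, recs[p[1]].start, recs[p[1]].end)]
    dsu = DSU(sorted({x for p in live for x in p[:2]}))
    for u, v, *_ in live:
        dsu.union(u, v)
    for comp in dsu.components():
        comp_set = set(comp)
        cp = [p for p in live if p[0] in comp_set and p[1] in comp_set]
        cp.sort(key=lambda p: (-(p[2] + p[3]) / 2, -(qual(p[0]) + qual(p[1])), p[0], p[1]))
        secondaries = set()
        for u, v, fa, fb in cp:
            if u in secondaries or v in secondaries:
                continue
            if qual(u) > qual(v):
                secondaries.add(v)
            elif qual(v) > qual(u):
                secondaries.add(u)
            else:
                secondaries.add(max(u, v))
        removed |= secondaries
    return removed


def lcnv_oracle(records):
    ids = sorted(r.site_id for r in records)
    by_id = {r.site_id: r for r in records}

    def edge(a, b):
        fa, fb = ro_oracle(by_id[a].interval(), by_id[b].interval())
        return min(fa, fb) >= 0.8

    comps = components_oracle(ids, edge)
    merged = []
    for comp in comps:
        merged.append((min(by_id[s].start for s in comp), max(by_id[s].end for s in comp),
                       tuple(comp)))
    return sorted(merged)


def merge_generic_oracle(records, min_ro=0.5):
    ids = sorted(r.site_id for r in records)
    by_id = {r.site_id: r for r in records}

    def edge(a, b):
        if by_id[a].svtype != by_id[b].svtype:
            return False
        fa, fb = ro_oracle(by_id[a].interval(), by_id[b].interval())
        return min(fa, fb) >= min_ro

    return components_oracle(ids, edge)


def unify_oracle(gs_records, ss_records, gs_cn, ss_ab, min_ro=0.5, frac=0.4,
                 r2_general=0.5, r2_mixed=0.0):
    """Two-stage unification components, recomputed from scratch."""
    compatible = lambda x, y: x == y or {x, y} in ({"mCNV", "DEL"}, {"mCNV", "DUP"}, {"DEL", "rMEI"})
    recs = {r.site_id: r for r in list(gs_records) + list(ss_records)}
    ids = sorted(recs)

    def evidence(sid):
        r = recs[sid]
        if r.caller == "genomestrip":
            return gs_cn.cn_row(sid)
        return ss_ab.ab_row(sid)

    def stage1(a_id, b_id):
        a, b = recs[a_id], recs[b_id]
        if a.caller == b.caller or not compatible(a.svtype, b.svtype):
            return False
        fa, fb = ro_oracle(a.interval(), b.interval())
        if min(fa, fb) > min_ro:
            return True
        inside = (
            a.chrom == b.chrom
            and ((a.start <= b.start and b.end <= a.end) or (b.start <= a.start and a.end <= b.end))
        )
        if inside:
            small = min(a.end - a.start, b.end - b.start)
            large = max(a.end - a.start, b.end - b.start)
            return small >= frac * large
        return False

    final = []
    for comp in components_oracle(ids, stage1):
        if len(comp) == 1:
            continue
        ss_types = {recs[s].svtype for s in comp if recs[s].caller == "speedseq"}
        mixed = {"DUP", "DEL"} <= ss_types and any(
            recs[s].caller == "genomestrip" and recs[s].svtype == "mCNV" for s in comp
        )
        thr = r2_mixed if mixed else r2_general

        def stage2(a_id, b_id):
            r = pearson_oracle(evidence(a_id), evidence(b_id))
            return np.isfinite(r) and r * r > thr

        for sub in components_oracle(list(comp), stage2):
            if len(sub) > 1:
                final.append(tuple(sub))
    return sorted(final)


def co_discovery_oracle(query, target, min_ro=0.25, frac=0.2, inv_ro=0.8, bnd=50):
    """Exhaustive matched query-target id pairs under the comparison rules."""
    point = {"BND"}
    out = set()
    for q in query:
        for t in target:
            pair = {q.svtype, t.svtype}
            if not (q.svtype == t.svtype or ("mCNV" in pair and pair & {"DEL", "DUP"})):
                continue
            if q.svtype in point or t.svtype in point:
                if q.chrom == t.chrom and abs(q.start - t.start) <= bnd:
                    out.add((q.site_id, t.site_id))
                continue
            fa, fb = ro_oracle(q.interval(), t.interval())
            need = inv_ro if q.svtype == "INV" else min_ro
            if min(fa, fb) >= need:
                out.add((q.site_id, t.site_id))
                continue
            if q.svtype == "INV":
                continue
            inside = (
                q.chrom == t.chrom
                and ((q.start <= t.start and t.end <= q.end) or (t.start <= q.start and q.end <= t.end))
            )
            if inside:
                small = min(q.length, t.length)
                large = max(q.length, t.length)
                if small >= frac * large:
                    out.add((q.site_id, t.site_id))
    return out


def max_r2_oracle(dosage, snp_gt, snp_pos, snp_chrom, chrom, start, end, window):
    best = None
    dosage = np.asarray(dosage, float)
    for k in range(snp_gt.shape[0]):
        if snp_chrom[k] != chrom or not (start - window <= snp_pos[k] <= end + window):
            continue
        snp = snp_gt[k].astype(float)
        ok = np.isfinite(dosage) & (snp != MISSING)
        if ok.sum() < 2 or dosage[ok].std() == 0 or snp[ok].std() == 0:
            continue
        r2 = float(np.corrcoef(dosage[ok], snp[ok])[0, 1] ** 2)
        if best is None or r2 > best:
            best = r2
    return best
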