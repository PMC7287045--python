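"""Replication rate (RR) from genetic replicates and quality-threshold sweeps.

RR for a site is the number of replicate pairs with matching non-reference
genotypes divided by the number of pairs with at least one non-reference
genotype. Pairs with a missing genotype in either member are excluded from
both numerator and denominator. Two concordance modes are provided: *strict*
(default) counts a match only when both genotypes are identical and
non-reference; *nonref_only* counts any pair where both members are
non-reference.

For copy-number rows (mCNVs) "non-reference" means a copy number different
from the modal copy number across samples, and concordance means equal copy
number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model_io import MISSING_GT, GenotypeMatrix

MODES = ("strict", "nonref_only")

#: metrics where the published rule is a strict inequality (score > t);
#: all others use score >= t ("minimum score required")
STRICT_METRICS = frozenset({"MSQ"})


def _modal_value(values: np.ndarray) -> float:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return np.nan
    vals, counts = np.unique(finite, return_counts=True)
    return float(vals[np.argmax(counts)])


def site_rr(row, pair_index, mode: str = "strict", channel: str = "gt"):
    """Per-site replication rate.

    Parameters
    ----------
    row : array of per-sample genotypes (``-1`` missing) or copy numbers
        (nan missing) depending on ``channel``.
    pair_index : sequence of (col_a, col_b) column index pairs.
    mode : "strict" or "nonref_only".
    channel : "gt" (reference = 0) or "cn" (reference = modal value).

    Returns
    -------
    (rr, n_informative) — rr is nan when no pair is informative.
    """
    if len(pair_index) == 0:
        raise ValueError("empty replicate pair list")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    row = np.asarray(row, dtype=float)
    if channel == "gt":
        missing = row == MISSING_GT
        ref_value = 0.0
    elif channel == "cn":
        missing = ~np.isfinite(row)
        ref_value = _modal_value(row)
    else:
        raise ValueError(f"unknown channel {channel!r}")

    n_informative = 0
    n_match = 0
    for ia, ib in pair_index:
        if missing[ia] or missing[ib]:
            continue
        a, b = row[ia], row[ib]
        a_nonref = a != ref_value
        b_nonref = b != ref_value
        if not (a_nonref or b_nonref):
            continue
        n_informative += 1
        if mode == "strict":
            if a_nonref and b_nonref and a == b:
                n_match += 1
        else:
            if a_nonref and b_nonref:
                n_match += 1
    rr = n_match / n_informative if n_informative else np.nan
    return rr, n_informative


def pair_columns(gmatrix: GenotypeMatrix, pairs):
    """Map ReplicatePairs to column-index tuples, checking membership."""
    cols = []
    for p in pairs:
        cols.append((gmatrix.sample_col(p.sample_a), gmatrix.sample_col(p.sample_b)))
    return cols


def rr_table(records, gmatrix: GenotypeMatrix, pairs, mode="strict") -> pd.DataFrame:
    """Per-site RR table (rr, n_informative, segregating) for all records.

    mCNV records are scored on the copy-number channel; all other classes on
    genotypes.
    """
    pair_idx = pair_columns(gmatrix, pairs)
    rows = []
    for rec in records:
        channel = "cn" if rec.svtype == "mCNV" else "gt"
        values = gmatrix.cn_row(rec.site_id) if channel == "cn" else gmatrix.gt_row(rec.site_id)
        rr, n_inf = site_rr(values, pair_idx, mode=mode, channel=channel)
        rows.append(
            {"site_id": rec.site_id, "caller": rec.caller, "svtype": rec.svtype,
             "rr": rr, "n_informative": n_inf, "segregating": n_inf > 0}
        )
    return pd.DataFrame(rows, columns=["site_id", "caller", "svtype", "rr",
                                       "n_informative", "segregating"])


def class_rr(records, gmatrix, pairs, by=("caller", "svtype"), mode="strict") -> pd.DataFrame:
    """Mean RR per group (caller x svtype by default), with site counts.

    Groups with zero sites with a defined RR report nan with n_sites 0.
    """
    table = rr_table(records, gmatrix, pairs, mode=mode)
    by = list(by)
    out = []
    for keys, grp in table.groupby(by, sort=True):
        defined = grp["rr"].dropna()
        row = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        row["mean_rr"] = float(defined.mean()) if len(defined) else np.nan
        row["n_sites"] = int(len(defined))
        out.append(row)
    return pd.DataFrame(out, columns=by + ["mean_rr", "n_sites"])


def threshold_sweep(records, gmatrix, pairs, metric: str, thresholds, mode="strict",
                    strict=None) -> pd.DataFrame:
    """Sweep a quality metric, reporting sites passing and mean RR at each cut.

    Comparison direction follows the published convention per metric: strict
    ``>`` for MSQ, ``>=`` otherwise (override with ``strict``). Records
    lacking the metric are excluded from all cells and counted in
    ``n_missing_metric``.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold list")
    if strict is None:
        strict = metric in STRICT_METRICS
    table = rr_table(records, gmatrix, pairs, mode=mode)
    scores = {}
    n_missing_metric = 0
    for rec in records:
        if metric in rec.quality:
            scores[rec.site_id] = float(rec.quality[metric])
        else:
            n_missing_metric += 1
    table = table[table["site_id"].isin(scores)]
    svals = table["site_id"].map(scores).to_numpy()
    rows = []
    for t in sorted(thresholds):
        keep = svals > t if strict else svals >= t
        sub = table.loc[keep, "rr"].dropna()
        rows.append(
            {"threshold": t, "n_sites_passing": int(keep.sum()),
             "mean_rr": float(sub.mean()) if len(sub) else np.nan,
             "n_missing_metric": n_missing_metric}
        )
    return pd.DataFrame(rows, columns=["threshold", "n_sites_passing", "mean_rr",
                                       "n_missing_metric"])


MELT_FLAG_SUBSETS = (
    ("lc",),
    ("s25",),
    ("rSD",),
    ("hDP",),
    ("lc", "s25", "rSD", "hDP"),
    ("lc", "s25", "rSD", "hDP", "ASSESS5"),
)


def melt_flag_sweep(records, gmatrix, pairs, mode="strict") -> pd.DataFrame:
    """RR impact of the MELT hard site filters.

    Each row removes records carrying any flag in the subset; the last row
    additionally requires the top evidence tranche (ASSESS = 5).
    """
    non_melt = [r.site_id for r in records if r.caller != "melt"]
    if non_melt:
        raise ValueError(f"melt_flag_sweep given non-MELT records, e.g. {non_melt[0]!r}")
    table = rr_table(records, gmatrix, pairs, mode=mode).set_index("site_id")
    rows = []
    for subset in MELT_FLAG_SUBSETS:
        flags = frozenset(f for f in subset if f != "ASSESS5")
        need_assess5 = "ASSESS5" in subset
        kept = []
        for rec in records:
            if rec.melt_flags & flags:
                continue
            if need_assess5 and rec.quality.get("ASSESS") != 5:
                continue
            kept.append(rec.site_id)
        rr = table.loc[kept, "rr"].dropna()
        rows.append(
            {"filter": "+".join(subset), "n_sites": len(kept),
             "mean_rr": float(rr.mean()) if len(rr) else np.nan}
        )
    return pd.DataFrame(rows, columns=["filter", "n_sites", "mean_rr"])
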