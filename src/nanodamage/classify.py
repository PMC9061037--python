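"""Clustering of damage records and the seven-way DSB taxonomy.

A DSB is any cluster of damaged backbones on opposite strands separated by
10 bp or less (inclusive), closed transitively so chained clusters spanning
more than 10 bp still count as one DSB.  Damaged bases within 3 bp of a
cluster's extremities are associated to it; a damaged base directly attached
to a damaged backbone (same bp, same strand) is removed before clustering.
An isolated backbone opposite an isolated base within 10 bp forms a
*potential* DSB, which is never promoted to a real DSB.

Categories:
``isolated_base``, ``isolated_backbone_SSB``, ``potential_DSB``,
``simple_DSB`` (2 backbones), ``simple_DSB_with_base``, ``complex_DSB``
(>=3 backbones), ``complex_DSB_with_base``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DnaGeometry

__all__ = [
    "CATEGORIES",
    "DSB_CATEGORIES",
    "DamageCluster",
    "cluster_damages",
    "classify",
    "tally_yields",
]

CATEGORIES = (
    "isolated_base",
    "isolated_backbone_SSB",
    "potential_DSB",
    "simple_DSB",
    "simple_DSB_with_base",
    "complex_DSB",
    "complex_DSB_with_base",
)

DSB_CATEGORIES = ("simple_DSB", "simple_DSB_with_base",
                  "complex_DSB", "complex_DSB_with_base")

MAX_DSB_SEPARATION_BP = 10   # inclusive
BASE_ATTACH_BP = 3           # inclusive
DA_PER_BP = 650.0            # mass conversion for literature comparison


@dataclass
class DamageCluster:
    """A maximal set of associated damage records with its classification."""

    records: pd.DataFrame
    category: str = ""
    extremities: tuple[int, int] = (0, 0)

    @property
    def n_backbones(self) -> int:
        return int((self.records["kind"] == "backbone").sum())

    @property
    def n_bases(self) -> int:
        return int((self.records["kind"] == "base").sum())

    @property
    def cause_mix(self) -> dict:
        return self.records["cause"].value_counts().to_dict()


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _extremities(bps: np.ndarray, geometry: DnaGeometry) -> tuple[int, int]:
    """Cluster extremities; on circular genomes unwrap at the largest gap."""
    u = np.unique(bps)
    if geometry.topology != "circular" or len(u) == 1:
        return int(u.min()), int(u.max())
    n = geometry.n_bp
    gaps = np.diff(np.concatenate([u, [u[0] + n]]))
    k = int(np.argmax(gaps))
    # linear run starts just after the largest gap
    start = u[(k + 1) % len(u)]
    end = u[k]
    return int(start), int(end)


def _arc_to_extremity(bp: int, ext: tuple[int, int], geometry: DnaGeometry) -> int:
    return min(geometry.bp_separation(bp, ext[0]), geometry.bp_separation(bp, ext[1]))


def cluster_damages(records: pd.DataFrame, geometry: DnaGeometry) -> list[DamageCluster]:
    """Partition damage records of one exposure into classified clusters.

    Damaged bases directly attached to a damaged backbone (same bp, same
    strand) are dropped before clustering; every other record ends up in
    exactly one cluster.  Record order does not affect the partition.
    """
    if len(records) == 0:
        return []
    bad = (records["bp_index"] < 1) | (records["bp_index"] > geometry.n_bp)
    if bad.any():
        raise ValueError(
            f"damage records reference bp outside 1..{geometry.n_bp}: "
            f"{sorted(records.loc[bad, 'bp_index'].unique())}")

    recs = records.reset_index(drop=True)
    is_bb = recs["kind"] == "backbone"
    bb = recs[is_bb].reset_index(drop=True)
    bases = recs[~is_bb].reset_index(drop=True)

    # drop bases directly attached to a damaged backbone (same bp & strand)
    if len(bases):
        bb_keys = set(zip(bb["bp_index"], bb["strand"]))
        attached_flag = [
            (b, s) in bb_keys for b, s in zip(bases["bp_index"], bases["strand"])]
        bases = bases[~np.asarray(attached_flag, bool)].reset_index(drop=True)

    # transitive backbone clustering over the opposite-strand <=10 bp predicate
    nbb = len(bb)
    dsu = _DSU(nbb)
    bp_arr = bb["bp_index"].to_numpy(int)
    st_arr = bb["strand"].to_numpy(int)
    for a in range(nbb):
        for b in range(a + 1, nbb):
            if st_arr[a] != st_arr[b] and \
                    geometry.bp_separation(int(bp_arr[a]), int(bp_arr[b])) \
                    <= MAX_DSB_SEPARATION_BP:
                dsu.union(a, b)
    groups: dict[int, list[int]] = {}
    for a in range(nbb):
        groups.setdefault(dsu.find(a), []).append(a)
    # deterministic ordering by smallest member bp
    ordered = sorted(groups.values(), key=lambda g: (int(bp_arr[g].min()), len(g)))

    clusters: list[DamageCluster] = []
    singles_bb: list[int] = []
    dsb_groups = []
    for g in ordered:
        if len(g) >= 2:
            dsb_groups.append(g)
        else:
            singles_bb.append(g[0])

    # attach bases to DSB clusters (after clustering converges): nearest
    # extremity wins, lower-extremity cluster on tie
    base_assign = np.full(len(bases), -1, dtype=int)
    if len(bases) and dsb_groups:
        exts = [_extremities(bp_arr[g], geometry) for g in dsb_groups]
        for ib in range(len(bases)):
            bbp = int(bases.loc[ib, "bp_index"])
            best = None  # (distance, lower extremity bp, cluster idx)
            for ic, ext in enumerate(exts):
                d = _arc_to_extremity(bbp, ext, geometry)
                if d <= BASE_ATTACH_BP:
                    key = (d, min(ext))
                    if best is None or key < best[:2]:
                        best = (d, min(ext), ic)
            if best is not None:
                base_assign[ib] = best[2]

    for ic, g in enumerate(dsb_groups):
        members = bb.loc[g]
        att = bases[base_assign == ic]
        allrec = pd.concat([members, att], ignore_index=True)
        cl = DamageCluster(records=allrec,
                           extremities=_extremities(bp_arr[g], geometry))
        cl.category = classify(cl)
        clusters.append(cl)

    # potential DSBs: isolated backbone + isolated base, opposite strands,
    # <=10 bp apart; greedy nearest pairing, lower bp on tie
    free_bases = [ib for ib in range(len(bases)) if base_assign[ib] < 0]
    used_base: set[int] = set()
    singles_bb_sorted = sorted(singles_bb, key=lambda a: int(bp_arr[a]))
    for a in singles_bb_sorted:
        best = None
        for ib in free_bases:
            if ib in used_base:
                continue
            if int(bases.loc[ib, "strand"]) == int(st_arr[a]):
                continue
            d = geometry.bp_separation(int(bp_arr[a]), int(bases.loc[ib, "bp_index"]))
            if d <= MAX_DSB_SEPARATION_BP:
                key = (d, int(bases.loc[ib, "bp_index"]))
                if best is None or key < best[:2]:
                    best = (d, int(bases.loc[ib, "bp_index"]), ib)
        if best is not None:
            ib = best[2]
            used_base.add(ib)
            allrec = pd.concat([bb.loc[[a]], bases.loc[[ib]]], ignore_index=True)
            lo = min(int(bp_arr[a]), best[1])
            hi = max(int(bp_arr[a]), best[1])
            cl = DamageCluster(records=allrec, extremities=(lo, hi))
            cl.category = classify(cl)
            clusters.append(cl)
        else:
            cl = DamageCluster(records=bb.loc[[a]].reset_index(drop=True),
                               extremities=(int(bp_arr[a]), int(bp_arr[a])))
            cl.category = classify(cl)
            clusters.append(cl)

    for ib in free_bases:
        if ib in used_base:
            continue
        bbp = int(bases.loc[ib, "bp_index"])
        cl = DamageCluster(records=bases.loc[[ib]].reset_index(drop=True),
                           extremities=(bbp, bbp))
        cl.category = classify(cl)
        clusters.append(cl)
    return clusters


def classify(cluster: DamageCluster) -> str:
    """Assign the seven-way category from cluster content alone."""
    nb, nbase = cluster.n_backbones, cluster.n_bases
    if nb == 0 and nbase == 0:
        raise ValueError("cannot classify an empty cluster")
    if nb == 0:
        return "isolated_base"
    if nb == 1:
        return "potential_DSB" if nbase >= 1 else "isolated_backbone_SSB"
    if nb == 2:
        return "simple_DSB_with_base" if nbase >= 1 else "simple_DSB"
    return "complex_DSB_with_base" if nbase >= 1 else "complex_DSB"


def tally_yields(clusters: list[DamageCluster], genome_bp: float, dose: float,
                 n_exposures: int = 1) -> pd.DataFrame:
    """Normalised damage yields per category.

    Returns a table with raw counts, yields per Gbp per Gy and per Mbp per
    Gy, plus the aggregate SSB (isolated backbones) and DSB (all four DSB
    categories) rows.  ``per_gda_gy`` uses the 650 Da/bp mass conversion
    for comparison with studies reporting per unit mass.
    """
    if genome_bp <= 0 or dose <= 0:
        raise ValueError("genome size and dose must be positive")
    counts = {c: 0 for c in CATEGORIES}
    for cl in clusters:
        counts[cl.category] += 1
    counts["SSB"] = counts["isolated_backbone_SSB"]
    counts["DSB"] = sum(counts[c] for c in DSB_CATEGORIES)
    rows = []
    denom_gbp = (genome_bp / 1e9) * dose * n_exposures
    denom_mbp = (genome_bp / 1e6) * dose * n_exposures
    denom_gda = (genome_bp * DA_PER_BP / 1e9) * dose * n_exposures
    for cat, cnt in counts.items():
        rows.append({
            "category": cat, "count": cnt,
            "per_gbp_gy": cnt / denom_gbp,
            "per_mbp_gy": cnt / denom_mbp,
            "per_gda_gy": cnt / denom_gda,
        })
    return pd.DataFrame(rows).set_index("category")
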