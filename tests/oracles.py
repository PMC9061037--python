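"""Independent brute-force oracle for damage clustering.

Deliberately naive: explicit all-pairs predicate, BFS connected components
and literal rule application, sharing no code with the package
implementation.
"""

import numpy as np
import pandas as pd


def _sep(i, j, n_bp, circular):
    d = abs(i - j)
    return min(d, n_bp - d) if circular else d


def oracle_cluster(records: pd.DataFrame, n_bp: int, circular: bool):
    """Return (backbone_partition, category_multiset).

    ``backbone_partition`` is a set of frozensets of backbone record row
    labels; categories follow the seven-way taxonomy.
    """
    recs = records.reset_index(drop=True)
    bb = [(i, int(r["bp_index"]), int(r["strand"]))
          for i, r in recs.iterrows() if r["kind"] == "backbone"]
    ba = [(i, int(r["bp_index"]), int(r["strand"]))
          for i, r in recs.iterrows() if r["kind"] == "base"]

    # remove bases directly attached to a damaged backbone
    bb_pos = {(b, s) for _, b, s in bb}
    ba = [t for t in ba if (t[1], t[2]) not in bb_pos]

    # all-pairs adjacency + BFS components
    adj = {i: set() for i, _, _ in bb}
    for x in range(len(bb)):
        for y in range(x + 1, len(bb)):
            i1, b1, s1 = bb[x]
            i2, b2, s2 = bb[y]
            if s1 != s2 and _sep(b1, b2, n_bp, circular) <= 10:
                adj[i1].add(i2)
                adj[i2].add(i1)
    seen, comps = set(), []
    for i, _, _ in bb:
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(comp)

    bp_of = {i: b for i, b, _ in bb}
    strand_of = {i: s for i, _, s in bb}

    def extremities(comp):
        bps = sorted({bp_of[i] for i in comp})
        if not circular or len(bps) == 1:
            return bps[0], bps[-1]
        ext = bps + [bps[0] + n_bp]
        gaps = [ext[k + 1] - ext[k] for k in range(len(bps))]
        k = int(np.argmax(gaps))
        return bps[(k + 1) % len(bps)], bps[k]

    dsb = [c for c in comps if len(c) >= 2]
    singles = sorted((next(iter(c)) for c in comps if len(c) == 1),
                     key=lambda i: bp_of[i])

    # base association to DSB extremities (<=3 bp, nearest, lower bp tie)
    exts = [extremities(c) for c in dsb]
    n_base_attached = [0] * len(dsb)
    free_bases = []
    for i, b, s in ba:
        best = None
        for ic, (lo, hi) in enumerate(exts):
            d = min(_sep(b, lo, n_bp, circular), _sep(b, hi, n_bp, circular))
            if d <= 3 and (best is None or (d, min(lo, hi)) < best[:2]):
                best = (d, min(lo, hi), ic)
        if best is not None:
            n_base_attached[best[2]] += 1
        else:
            free_bases.append((i, b, s))

    categories = []
    for c, nb in zip(dsb, n_base_attached):
        if len(c) == 2:
            categories.append("simple_DSB_with_base" if nb else "simple_DSB")
        else:
            categories.append("complex_DSB_with_base" if nb else "complex_DSB")

    # potential DSBs: greedy nearest base, lower bp tie, backbone bp order
    used = set()
    for i in singles:
        b, s = bp_of[i], strand_of[i]
        best = None
        for j, bb2, s2 in free_bases:
            if j in used or s2 == s:
                continue
            d = _sep(b, bb2, n_bp, circular)
            if d <= 10 and (best is None or (d, bb2) < best[:2]):
                best = (d, bb2, j)
        if best is not None:
            used.add(best[2])
            categories.append("potential_DSB")
        else:
            categories.append("isolated_backbone_SSB")
    categories.extend("isolated_base" for j, _, _ in free_bases if j not in used)

    partition = {frozenset(c) for c in comps}
    return partition, sorted(categories)


def random_damage_set(rng: np.random.Generator, n_bp: int, max_records: int = 50):
    n = rng.integers(1, max_records + 1)
    # cluster bp positions so separations <=10 actually occur
    centres = rng.integers(1, n_bp + 1, size=max(1, n // 6 + 1))
    bp = (centres[rng.integers(0, len(centres), n)]
          + rng.integers(-12, 13, n) - 1) % n_bp + 1
    return pd.DataFrame({
        "bp_index": bp,
        "strand": rng.integers(1, 3, n),
        "kind": rng.choice(["backbone", "base"], n, p=[0.7, 0.3]),
        "cause": rng.choice(["direct", "indirect"], n),
        "deposited_energy": 20.0,
        "primary_id": 0,
    }).drop_duplicates(subset=["bp_index", "strand", "kind"]).reset_index(drop=True)
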