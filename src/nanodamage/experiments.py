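"""The two in-silico irradiation assays.

Plasmid assay: dry pBR322 plasmids on a coverslip are irradiated
perpendicular to the plane with a fixed number of primaries; the dose is set
through the fluence, i.e. the radius of the irradiation disc,

    Phi = D * rho / L,    R = sqrt(N / (pi * Phi)),

with D the dose, rho the DNA density and L the LET (1 keV/um =
1.602e-10 J/m).  Only direct damage is scored (dry conditions), and SSB/DSB
yields are reported per Mbp per Gy.

Chromatin-fibre assay: one primary per exposure starts on the surface of
the water envelope with an inward random direction; direct and indirect
damage are scored per primary, giving DSB-category probabilities, the
indirect backbone-damage fraction, and the complexity samples that later
populate the cell model.  The OH backbone damage probability P_Ind is
calibrated here by bisection against the 35:65 direct:indirect target for
the Co-60 surrogate beam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import tracks
from .classify import CATEGORIES, DSB_CATEGORIES, cluster_damages, tally_yields
from .damage import (DirectModelConfig, IndirectModelConfig, accumulate_energy,
                     apply_direct, apply_indirect, merge_damage, _unpack_codes)
from .geometry import FibreGeometry, build_fibre, build_plasmid
from .tracks import TrackModel, diffuse, sample_track_arrays, spawn_radicals

__all__ = [
    "PlasmidIrradiationConfig",
    "FibreExposureResult",
    "CalibrationResult",
    "CalibrationError",
    "disc_radius",
    "run_plasmid",
    "run_fibre",
    "calibrate_p_ind",
]

KEV_PER_UM_TO_J_PER_M = 1.602e-10


@dataclass
class PlasmidIrradiationConfig:
    """Fluence-matched plasmid exposure (dose fixed through the disc radius)."""

    n_primaries: int = 5000
    dose_gy: float = 2000.0
    let_t: float = 10.0
    density_g_cm3: float = 1.407
    disc_offset_um: float = 1.0
    backscatter_fraction: float = 0.0   # coverslip backscatter surrogate, off by default

    def __post_init__(self):
        if min(self.n_primaries, self.dose_gy, self.let_t, self.density_g_cm3) <= 0:
            raise ValueError("n_primaries, dose, LET and density must be positive")


def disc_radius(cfg: PlasmidIrradiationConfig) -> float:
    """Irradiation disc radius in um delivering the configured dose.

    Fluence Phi = D * rho / L with L converted via 1 keV/um = 1.602e-10 J/m;
    the radius follows from N primaries over the disc area.
    """
    if cfg.let_t <= 0:
        raise ValueError("LET must be positive")
    let_j_per_m = cfg.let_t * KEV_PER_UM_TO_J_PER_M
    rho_kg_m3 = cfg.density_g_cm3 * 1000.0
    fluence_m2 = cfg.dose_gy * rho_kg_m3 / let_j_per_m
    radius_m = math.sqrt(cfg.n_primaries / (math.pi * fluence_m2))
    return radius_m * 1e6


def run_plasmid(cfg: PlasmidIrradiationConfig,
                direct_cfg: DirectModelConfig | None = None,
                shape: str = "quarter_cylinder", seed=0,
                n_repeats: int = 5,
                track_model: TrackModel | None = None,
                geometry=None,
                injected_events: pd.DataFrame | None = None) -> pd.DataFrame:
    """Simulate dry-plasmid irradiation and return SSB/DSB yields.

    Primaries are sampled uniformly on the irradiation disc with
    perpendicular incidence; only those passing near the DNA ring can
    deposit in DNA volumes, so distant primaries are skipped analytically.
    Returns a table with per-repeat SSB/DSB counts and yields per Mbp per
    Gy, plus their mean and standard error in the attrs.

    ``injected_events`` replaces the surrogate generator with an external
    event list (e.g. from a real track-structure code); it is used for
    every repeat as-is.
    """
    direct_cfg = direct_cfg or DirectModelConfig()
    track_model = track_model or TrackModel()
    geom = geometry if geometry is not None else build_plasmid(shape)
    rng_root = np.random.default_rng(seed)
    disc_r_nm = disc_radius(cfg) * 1e3
    ring_r_nm = geom.circle_radius_nm
    # primaries farther than this from the DNA ring cannot reach any volume
    reach_nm = (1.15 + 5.0 * track_model.penumbra_mean_nm
                + 4.0 * track_model.spur_sigma_nm)
    z_win = 1.15 + 4.0 * track_model.spur_sigma_nm   # events beyond cannot damage

    rows = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(rng_root.integers(2 ** 31))
        if injected_events is not None:
            events = injected_events
        else:
            # uniform positions on the disc
            u = rng.random(cfg.n_primaries)
            r = disc_r_nm * np.sqrt(u)
            phi = rng.uniform(0, 2 * math.pi, cfg.n_primaries)
            x, y = r * np.cos(phi), r * np.sin(phi)
            near = np.abs(np.hypot(x, y) - ring_r_nm) <= reach_nm
            pos_list, e_list, ion_list, pid_list = [], [], [], []
            for k in np.flatnonzero(near):
                p, e, ion = sample_track_arrays(
                    rng, cfg.let_t, 2 * z_win,
                    origin=(x[k], y[k], z_win), direction=(0, 0, -1.0),
                    model=track_model)
                if cfg.backscatter_fraction > 0 and len(e):
                    keep = rng.random(len(e)) < cfg.backscatter_fraction
                    pm = p[keep].copy()
                    pm[:, 2] = -2 * z_win - pm[:, 2]  # mirrored at the slab plane
                    p = np.vstack([p, pm])
                    e = np.concatenate([e, e[keep]])
                    ion = np.concatenate([ion, ion[keep]])
                pos_list.append(p)
                e_list.append(e)
                ion_list.append(ion)
                pid_list.append(np.full(len(e), k, dtype=int))
            if pos_list:
                pos = np.concatenate(pos_list)
                events = pd.DataFrame({
                    "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
                    "energy": np.concatenate(e_list),
                    "is_ionisation": np.concatenate(ion_list),
                    "track_id": np.concatenate(pid_list),
                    "primary_id": np.concatenate(pid_list),
                })
            else:
                events = pd.DataFrame(columns=tracks.EVENT_COLUMNS)
        e_map = accumulate_energy(events, geom)
        damage = apply_direct(e_map, direct_cfg, seed=rng)
        clusters = cluster_damages(damage, geom)
        tal = tally_yields(clusters, genome_bp=geom.n_bp, dose=cfg.dose_gy)
        rows.append({
            "repeat": rep,
            "ssb": int(tal.loc["SSB", "count"]),
            "dsb": int(tal.loc["DSB", "count"]),
            "ssb_per_mbp_gy": tal.loc["SSB", "per_mbp_gy"],
            "dsb_per_mbp_gy": tal.loc["DSB", "per_mbp_gy"],
        })
    out = pd.DataFrame(rows)
    out.attrs["let_t"] = cfg.let_t
    out.attrs["shape"] = geom.shape
    out.attrs["mode"] = direct_cfg.mode
    for col in ("ssb_per_mbp_gy", "dsb_per_mbp_gy"):
        out.attrs[f"{col}_mean"] = float(out[col].mean())
        out.attrs[f"{col}_sem"] = float(out[col].std(ddof=1) / math.sqrt(len(out))) \
            if len(out) > 1 else float("nan")
    return out


# ---------------------------------------------------------------------------
# chromatin fibre assay
# ---------------------------------------------------------------------------

@dataclass
class FibreExposureResult:
    """Aggregated per-primary damage statistics for one beam setting."""

    let_t: float
    n_primaries: int
    indirect_fraction: float
    indirect_fraction_sem: float
    dsb_probabilities: dict
    category_counts: dict
    dsb_samples: pd.DataFrame       # one row per DSB: category, n_backbones, n_bases
    isolated_samples: list          # isolated_* / potential_DSB draws
    records: pd.DataFrame | None = None

    @property
    def dsb_per_primary(self) -> float:
        return sum(self.category_counts.get(c, 0) for c in DSB_CATEGORIES) \
            / max(self.n_primaries, 1)


def _fibre_surface_starts(rng: np.random.Generator, n: int, fib: FibreGeometry):
    """Uniform points on the envelope lateral surface + inward directions."""
    r = fib.ENVELOPE_DIAMETER_NM / 2.0
    phi = rng.uniform(0, 2 * math.pi, n)
    z = rng.uniform(fib.LENGTH_NM / 2.0 - fib.ENVELOPE_LENGTH_NM / 2.0,
                    fib.LENGTH_NM / 2.0 + fib.ENVELOPE_LENGTH_NM / 2.0, n)
    origins = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    # isotropic directions, flipped into the inward hemisphere
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    inward = -origins.copy()
    inward[:, 2] = 0.0
    inward /= np.maximum(np.linalg.norm(inward, axis=1, keepdims=True), 1e-12)
    flip = np.einsum("ij,ij->i", d, inward) < 0
    d[flip] *= -1.0
    return origins, d


@dataclass
class _FibrePhysicsCache:
    """p-independent physics/chemistry realisation reused by the calibration."""

    direct: pd.DataFrame            # direct damage records (drawn once)
    radical_hits: pd.DataFrame      # per radical-DNA reaction: vol code, kind, primary
    n_primaries: int


def _run_fibre_physics(let_t, n_primaries, seed, fib: FibreGeometry,
                       direct_cfg: DirectModelConfig,
                       track_model: TrackModel, g_value: float,
                       chunk: int = 512) -> _FibrePhysicsCache:
    """Tracks, direct damage and radical transport (nothing depends on P_Ind)."""
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    direct_parts, hit_parts = [], []
    done = 0
    while done < n_primaries:
        m = min(chunk, n_primaries - done)
        origins, dirs = _fibre_surface_starts(rng, m, fib)
        pos_list, e_list, ion_list, pid_list = [], [], [], []
        for k in range(m):
            path = fib.envelope_chord(origins[k], dirs[k])
            if path <= 0:
                continue
            p, e, ion = sample_track_arrays(rng, let_t, path, origins[k],
                                            dirs[k], track_model)
            if len(e) == 0:
                continue
            pos_list.append(p)
            e_list.append(e)
            ion_list.append(ion)
            pid_list.append(np.full(len(e), done + k, dtype=int))
        if pos_list:
            pos = np.concatenate(pos_list)
            events = pd.DataFrame({
                "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
                "energy": np.concatenate(e_list),
                "is_ionisation": np.concatenate(ion_list),
                "track_id": np.concatenate(pid_list),
                "primary_id": np.concatenate(pid_list),
            })
            e_map = accumulate_energy(events, fib)
            direct_parts.append(apply_direct(e_map, direct_cfg, seed=rng))
            radicals = spawn_radicals(events, g_value=g_value, seed=rng)
            diff = diffuse(radicals, geometry=fib, seed=rng)
            reacted = diff.terminated_by == "dna_reaction"
            codes = diff.hit_volume[reacted]
            bp, strand, kind = _unpack_codes(codes)
            hit_parts.append(pd.DataFrame({
                "vol_code": codes, "bp_index": bp, "strand": strand,
                "kind": kind, "primary_id": diff.primary_id[reacted]}))
        done += m
    direct = pd.concat(direct_parts, ignore_index=True) if direct_parts \
        else apply_direct(pd.DataFrame(), direct_cfg)
    hits = pd.concat(hit_parts, ignore_index=True) if hit_parts \
        else pd.DataFrame(columns=["vol_code", "bp_index", "strand", "kind",
                                   "primary_id"])
    return _FibrePhysicsCache(direct=direct, radical_hits=hits,
                              n_primaries=n_primaries)


def _indirect_from_hits(cache: _FibrePhysicsCache, indirect_cfg: IndirectModelConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Bernoulli damage draws for cached radical-DNA reactions."""
    hits = cache.radical_hits
    if len(hits) == 0:
        return hits.assign(cause="indirect", deposited_energy=np.nan)[
            ["bp_index", "strand", "kind", "cause", "deposited_energy", "primary_id"]]
    p = np.where(hits["kind"].to_numpy() == "backbone",
                 indirect_cfg.p_backbone, indirect_cfg.p_base)
    take = rng.random(len(hits)) < p
    sub = hits[take]
    return pd.DataFrame({
        "bp_index": sub["bp_index"].to_numpy(int),
        "strand": sub["strand"].to_numpy(int),
        "kind": sub["kind"].to_numpy(str),
        "cause": "indirect",
        "deposited_energy": np.nan,
        "primary_id": sub["primary_id"].to_numpy(int),
    })


def _indirect_fraction(records: pd.DataFrame) -> tuple[float, int]:
    bb = records[records["kind"] == "backbone"]
    n = len(bb)
    if n == 0:
        return float("nan"), 0
    return float((bb["cause"] == "indirect").mean(), ), n


def run_fibre(let_t, n_primaries: int = 2000, seed=0,
              direct_cfg: DirectModelConfig | None = None,
              indirect_cfg: IndirectModelConfig | None = None,
              track_model: TrackModel | None = None,
              g_value: float = 2.5,
              shape: str = "quarter_cylinder",
              include_indirect: bool = True,
              fibre: FibreGeometry | None = None,
              keep_records: bool = False) -> FibreExposureResult:
    """Expose the chromatin fibre to ``n_primaries`` independent primaries.

    ``let_t`` is a proton LET in keV/um or the string ``"co60"`` for the
    photon-surrogate electron beam (LET 0.2 keV/um).  One primary per
    exposure is assumed (no multi-track traversal of a fibre segment).
    """
    direct_cfg = direct_cfg or DirectModelConfig()
    indirect_cfg = indirect_cfg or IndirectModelConfig()
    track_model = track_model or TrackModel()
    fib = fibre if fibre is not None else build_fibre(shape)
    let = tracks.CO60_REFERENCE_LET if isinstance(let_t, str) else float(let_t)
    if isinstance(let_t, str) and let_t.lower() != "co60":
        raise ValueError(f"unknown beam key {let_t!r}")

    cache = _run_fibre_physics(let, n_primaries, seed, fib, direct_cfg,
                               track_model, g_value)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    if include_indirect:
        indirect = _indirect_from_hits(cache, indirect_cfg, rng)
    else:
        indirect = None
    records = merge_damage(cache.direct, indirect)

    frac, n_bb = _indirect_fraction(records)
    sem = math.sqrt(frac * (1 - frac) / n_bb) if n_bb else float("nan")

    counts = {c: 0 for c in CATEGORIES}
    dsb_rows, isolated = [], []
    if len(records):
        for pid, sub in records.groupby("primary_id"):
            for cl in cluster_damages(sub, fib):
                counts[cl.category] += 1
                if cl.category in DSB_CATEGORIES:
                    dsb_rows.append({"category": cl.category,
                                     "n_backbones": cl.n_backbones,
                                     "n_bases": cl.n_bases})
                else:
                    isolated.append(cl.category)
    n_dsb = sum(counts[c] for c in DSB_CATEGORIES)
    probs = {c: counts[c] / n_dsb if n_dsb else float("nan")
             for c in DSB_CATEGORIES}
    return FibreExposureResult(
        let_t=let, n_primaries=n_primaries,
        indirect_fraction=frac if include_indirect else 0.0,
        indirect_fraction_sem=sem if include_indirect else 0.0,
        dsb_probabilities=probs, category_counts=counts,
        dsb_samples=pd.DataFrame(dsb_rows,
                                 columns=["category", "n_backbones", "n_bases"]),
        isolated_samples=isolated,
        records=records if keep_records else None,
    )


# ---------------------------------------------------------------------------
# P_Ind calibration
# ---------------------------------------------------------------------------

class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationResult:
    p_ind: float
    achieved_fraction: float
    stderr: float
    target_fraction: float
    n_primaries: int
    iterations: int
    fraction_at_pmax: float


def calibrate_p_ind(target_fraction: float = 0.65, let_t="co60",
                    tolerance: float = 0.01, seed=0,
                    n_primaries: int = 20000,
                    direct_cfg: DirectModelConfig | None = None,
                    track_model: TrackModel | None = None,
                    g_value: float = 2.5,
                    shape: str = "quarter_cylinder",
                    fibre: FibreGeometry | None = None,
                    max_iter: int = 40) -> CalibrationResult:
    """Bisection of P_Ind against the indirect backbone-damage fraction.

    The physics/chemistry realisation is simulated once; for a candidate
    P_Ind the expected indirect fraction is evaluated from the cached
    radical-backbone reactions (each undamaged backbone volume with k
    radical reactions is broken with probability 1-(1-p)^k, duplicates with
    direct damage excluded), which makes the bisection objective smooth and
    strictly monotone in p.
    """
    if not 0.0 < target_fraction < 1.0:
        raise CalibrationError("target fraction must lie strictly in (0, 1)")
    direct_cfg = direct_cfg or DirectModelConfig()
    track_model = track_model or TrackModel()
    fib = fibre if fibre is not None else build_fibre(shape)
    let = tracks.CO60_REFERENCE_LET if isinstance(let_t, str) else float(let_t)

    cache = _run_fibre_physics(let, n_primaries, seed, fib, direct_cfg,
                               track_model, g_value)
    direct_bb = cache.direct[cache.direct["kind"] == "backbone"]
    d_keys = set(zip(direct_bb["primary_id"], direct_bb["bp_index"],
                     direct_bb["strand"]))
    hits_bb = cache.radical_hits[cache.radical_hits["kind"] == "backbone"]
    # radical reactions on volumes already broken by the physical stage do
    # not add damage (one record per volume, direct precedence)
    dup = [key in d_keys for key in zip(hits_bb["primary_id"],
                                        hits_bb["bp_index"], hits_bb["strand"])]
    hits_bb = hits_bb[~np.asarray(dup, bool)] if len(hits_bb) else hits_bb
    mult = hits_bb.groupby(["primary_id", "bp_index", "strand"]).size().to_numpy() \
        if len(hits_bb) else np.empty(0, int)
    n_direct = len(direct_bb)

    def expected_fraction(p: float) -> float:
        e_ind = float(np.sum(1.0 - (1.0 - p) ** mult))
        denom = e_ind + n_direct
        return e_ind / denom if denom else float("nan")

    f_hi = expected_fraction(1.0)
    f_lo = expected_fraction(0.0)
    if not np.isfinite(f_hi) or f_hi < target_fraction or f_lo > target_fraction:
        raise CalibrationError(
            f"target {target_fraction} not bracketed: fraction range "
            f"[{f_lo:.3f}, {f_hi:.3f}] at p in [0, 1] "
            f"({n_direct} direct backbone damages, {len(mult)} reactive volumes)")

    lo, hi = 0.0, 1.0
    it = 0
    p = 0.5
    for it in range(1, max_iter + 1):
        p = 0.5 * (lo + hi)
        f = expected_fraction(p)
        if abs(f - target_fraction) < tolerance:
            break
        if f < target_fraction:
            lo = p
        else:
            hi = p
    achieved = expected_fraction(p)

    # batch-split standard error of the achieved fraction
    nb = 10
    batches = np.array_split(np.arange(cache.n_primaries), nb)
    fr = []
    for b in batches:
        bset = set(b.tolist())
        nd = int(direct_bb["primary_id"].isin(bset).sum())
        if len(hits_bb):
            msub = hits_bb[hits_bb["primary_id"].isin(bset)]
            mm = msub.groupby(["primary_id", "bp_index", "strand"]).size().to_numpy()
            ei = float(np.sum(1.0 - (1.0 - p) ** mm))
        else:
            ei = 0.0
        if ei + nd > 0:
            fr.append(ei / (ei + nd))
    stderr = float(np.std(fr, ddof=1) / math.sqrt(len(fr))) if len(fr) > 1 else float("nan")
    return CalibrationResult(p_ind=p, achieved_fraction=achieved, stderr=stderr,
                             target_fraction=target_fraction,
                             n_primaries=n_primaries, iterations=it,
                             fraction_at_pmax=f_hi)
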