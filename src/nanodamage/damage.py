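"""Conversion of physics/chemistry events into DNA damage records.

Direct damage: energy deposits falling inside a DNA volume are summed per
primary-particle lineage and converted to damage under one of three models —
``energy_range`` (linear damage probability between 5 and 37.5 eV),
``threshold`` (damaged iff the summed energy strictly exceeds 17.5 eV) or
``ionisation`` (damaged iff at least one ionisation event occurred in the
volume).

Indirect damage: an OH radical whose trajectory terminates inside a DNA
volume always reacts there; with probability ``p_backbone`` (the calibrated
P_Ind) for backbones or ``p_base`` = 0.8 for bases the reaction records a
strand-break/base damage, otherwise the radical is consumed without damage.

Damage records are pandas DataFrames with columns ``DAMAGE_COLUMNS``; a
volume is damaged at most once per exposure, direct cause taking precedence
(the physical stage precedes the chemical one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DnaGeometry

__all__ = [
    "DAMAGE_COLUMNS",
    "DirectModelConfig",
    "IndirectModelConfig",
    "DamageRecord",
    "accumulate_energy",
    "direct_damage_probability",
    "apply_direct",
    "apply_indirect",
    "merge_damage",
]

DAMAGE_COLUMNS = ["bp_index", "strand", "kind", "cause", "deposited_energy", "primary_id"]

DIRECT_MODES = ("energy_range", "threshold", "ionisation")


@dataclass
class DirectModelConfig:
    """Direct-damage model selection and its energy parameters (eV)."""

    mode: str = "energy_range"
    e_min: float = 5.0
    e_max: float = 37.5
    e_threshold: float = 17.5

    def __post_init__(self):
        if self.mode not in DIRECT_MODES:
            raise ValueError(f"unknown direct damage mode {self.mode!r}")
        if not self.e_min < self.e_max:
            raise ValueError("require e_min < e_max")


@dataclass
class IndirectModelConfig:
    """OH-reaction damage probabilities.

    ``p_backbone`` is P_Ind, calibrated against the 35:65 direct:indirect
    backbone-damage ratio for the photon reference; ``p_base`` is fixed at
    0.8 to account for the higher OH-base reaction rates.
    """

    p_backbone: float = 0.5
    p_base: float = 0.8

    def __post_init__(self):
        for p in (self.p_backbone, self.p_base):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class DamageRecord:
    """One damaged backbone or base volume."""

    bp_index: int
    strand: int
    kind: str
    cause: str
    deposited_energy: float
    primary_id: int


def _unpack_codes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Packed volume code -> (bp_index, strand, kind)."""
    bp = codes // 4 + 1
    off = codes % 4
    strand = np.where(off % 2 == 0, 1, 2)
    kind = np.where(off < 2, "backbone", "base")
    return bp, strand, kind


def _empty_damage() -> pd.DataFrame:
    return pd.DataFrame({
        "bp_index": pd.Series(dtype=int), "strand": pd.Series(dtype=int),
        "kind": pd.Series(dtype=str), "cause": pd.Series(dtype=str),
        "deposited_energy": pd.Series(dtype=float),
        "primary_id": pd.Series(dtype=int),
    })


def accumulate_energy(events: pd.DataFrame, geometry: DnaGeometry) -> pd.DataFrame:
    """Sum deposited energy per DNA volume per primary lineage.

    Events outside every DNA volume are ignored.  Returns a DataFrame with
    one row per (primary_id, volume): columns ``primary_id, vol_code,
    bp_index, strand, kind, energy, n_ionisations``.
    """
    if len(events) == 0:
        return pd.DataFrame(columns=["primary_id", "vol_code", "bp_index", "strand",
                                     "kind", "energy", "n_ionisations"])
    codes = geometry.locate(events[["x", "y", "z"]].to_numpy(float))
    inside = codes >= 0
    if not inside.any():
        return pd.DataFrame(columns=["primary_id", "vol_code", "bp_index", "strand",
                                     "kind", "energy", "n_ionisations"])
    sub = events.loc[inside, ["primary_id", "energy", "is_ionisation"]].copy()
    sub["vol_code"] = codes[inside]
    grouped = (sub.groupby(["primary_id", "vol_code"], as_index=False)
               .agg(energy=("energy", "sum"), n_ionisations=("is_ionisation", "sum")))
    bp, strand, kind = _unpack_codes(grouped["vol_code"].to_numpy())
    grouped["bp_index"] = bp
    grouped["strand"] = strand
    grouped["kind"] = kind
    return grouped


def direct_damage_probability(e_sum, cfg: DirectModelConfig | None = None):
    """Linear damage probability: 0 below e_min, 1 at/above e_max."""
    cfg = cfg or DirectModelConfig()
    e = np.asarray(e_sum, float)
    if np.any(e < 0):
        raise ValueError("energy must be non-negative")
    p = np.clip((e - cfg.e_min) / (cfg.e_max - cfg.e_min), 0.0, 1.0)
    return float(p) if np.isscalar(e_sum) else p


def apply_direct(e_map: pd.DataFrame, cfg: DirectModelConfig, seed=None) -> pd.DataFrame:
    """Convert per-volume energy sums into direct damage records."""
    if len(e_map) == 0:
        return _empty_damage()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    e = e_map["energy"].to_numpy(float)
    if cfg.mode == "energy_range":
        damaged = rng.random(len(e)) < direct_damage_probability(e, cfg)
    elif cfg.mode == "threshold":
        damaged = e > cfg.e_threshold  # strictly more than the threshold
    else:  # ionisation
        damaged = e_map["n_ionisations"].to_numpy(int) >= 1
    sub = e_map.loc[damaged]
    return pd.DataFrame({
        "bp_index": sub["bp_index"].to_numpy(int),
        "strand": sub["strand"].to_numpy(int),
        "kind": sub["kind"].to_numpy(str),
        "cause": "direct",
        "deposited_energy": sub["energy"].to_numpy(float),
        "primary_id": sub["primary_id"].to_numpy(int),
    })


def apply_indirect(diffusion, cfg: IndirectModelConfig | None = None,
                   seed=None) -> pd.DataFrame:
    """Convert radical-DNA reactions into indirect damage records.

    ``diffusion`` is a :class:`~nanodamage.tracks.DiffusionResult`.  Every
    radical that reached a DNA volume has reacted; the Bernoulli draw only
    decides whether the reaction broke the backbone (p = P_Ind) or damaged
    the base (p = 0.8).
    """
    cfg = cfg or IndirectModelConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mask = diffusion.terminated_by == "dna_reaction"
    codes = diffusion.hit_volume[mask]
    prim = diffusion.primary_id[mask]
    if len(codes) == 0:
        return _empty_damage()
    bp, strand, kind = _unpack_codes(codes)
    p = np.where(kind == "backbone", cfg.p_backbone, cfg.p_base)
    damaged = rng.random(len(codes)) < p
    return pd.DataFrame({
        "bp_index": bp[damaged].astype(int),
        "strand": strand[damaged].astype(int),
        "kind": kind[damaged].astype(str),
        "cause": "indirect",
        "deposited_energy": np.nan,
        "primary_id": prim[damaged].astype(int),
    })


def merge_damage(*record_sets: pd.DataFrame) -> pd.DataFrame:
    """Merge damage records, keeping one record per volume per primary.

    Record sets are given in simulation-time order (direct stage first);
    the first occurrence wins, so direct cause takes precedence over an
    indirect hit on the same volume.
    """
    frames = [r for r in record_sets if r is not None and len(r)]
    if not frames:
        return _empty_damage()
    allrec = pd.concat(frames, ignore_index=True)
    return allrec.drop_duplicates(
        subset=["primary_id", "bp_index", "strand", "kind"], keep="first"
    ).reset_index(drop=True)
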