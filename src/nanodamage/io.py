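"""Export/import plumbing: damage tables, SDD-style records, YAML config."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .classify import DamageCluster

__all__ = [
    "damage_to_csv",
    "damage_to_sdd",
    "clusters_to_frame",
    "load_config",
    "save_config",
]

_SDD_HEADER = """\
# Minimal Standard-DNA-Damage-style lesion records
# columns: bp_position, strand, lesion_kind, cause
"""


def damage_to_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def damage_to_sdd(records: pd.DataFrame, path) -> None:
    """Write damage records as minimal SDD-style plain-text blocks."""
    with open(path, "w") as fh:
        fh.write(_SDD_HEADER)
        for _, r in records.iterrows():
            fh.write(f"{int(r['bp_index'])}, {int(r['strand'])}, "
                     f"{r['kind']}, {r['cause']}\n")


def clusters_to_frame(clusters: list[DamageCluster]) -> pd.DataFrame:
    """Cluster table: category, extremities, content counts, cause mix."""
    rows = []
    for cl in clusters:
        mix = cl.cause_mix
        rows.append({
            "category": cl.category,
            "bp_min": cl.extremities[0], "bp_max": cl.extremities[1],
            "n_backbones": cl.n_backbones, "n_bases": cl.n_bases,
            "n_direct": mix.get("direct", 0), "n_indirect": mix.get("indirect", 0),
        })
    return pd.DataFrame(rows, columns=["category", "bp_min", "bp_max",
                                       "n_backbones", "n_bases",
                                       "n_direct", "n_indirect"])


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
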