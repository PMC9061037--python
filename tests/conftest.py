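import numpy as np
import pandas as pd
import pytest

from nanodamage.geometry import build_fibre, build_helix, build_plasmid


@pytest.fixture(scope="session")
def plasmid_qc():
    return build_plasmid("quarter_cylinder")


@pytest.fixture(scope="session")
def fibre_qc():
    return build_fibre("quarter_cylinder")


@pytest.fixture(scope="session")
def helix_by_shape():
    return {s: build_helix(30, s) for s in
            ("sphere", "quarter_cylinder", "half_cylinder")}


def make_records(entries, primary_id=0):
    """Damage-record table from (bp, strand, kind[, cause]) tuples."""
    rows = []
    for e in entries:
        bp, strand, kind = e[0], e[1], e[2]
        cause = e[3] if len(e) > 3 else "direct"
        rows.append({"bp_index": bp, "strand": strand, "kind": kind,
                     "cause": cause, "deposited_energy": 20.0,
                     "primary_id": primary_id})
    return pd.DataFrame(rows, columns=["bp_index", "strand", "kind", "cause",
                                       "deposited_energy", "primary_id"])


@pytest.fixture
def records_factory():
    return make_records
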