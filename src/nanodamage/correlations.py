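"""Analytic DSB-yield correlations in dose and track-averaged LET.

For each DSB category the per-cell yield (6 Gbp genome) follows

    Yield(D, L) = D * (a * L**2 + b * L + c)

with D the proton dose (Gy) and L the track-averaged LET (keV/um).  The
model is exactly linear in dose, so fitting is done on dose-normalised
yields against L alone.  A reference parameter set fitted to the simulated
yields is shipped as a versioned constants file and is the default input to
the clinical voxel mapper, so mapping works without re-running simulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .classify import DSB_CATEGORIES

__all__ = [
    "CorrelationParams",
    "ReferenceParamSet",
    "load_reference_params",
    "eval_yield",
    "fit_correlation",
    "total_dsb_rate",
]

GENOME_GBP = 6.0


@dataclass(frozen=True)
class CorrelationParams:
    """Quadratic-in-LET coefficients for one DSB category.

    Units: a in Gy^-1 (keV/um)^-2, b in Gy^-1 (keV/um)^-1, c in Gy^-1,
    all per cell (6 Gbp).  ``*_err`` are asymptotic standard errors.
    """

    category: str
    a: float
    b: float
    c: float
    a_err: float = float("nan")
    b_err: float = float("nan")
    c_err: float = float("nan")


class ReferenceParamSet(dict):
    """Mapping category -> :class:`CorrelationParams` for the four DSB types."""

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.keys())

    def to_json(self, path) -> None:
        payload = {"categories": {
            k: {"a": p.a, "a_err": p.a_err, "b": p.b, "b_err": p.b_err,
                "c": p.c, "c_err": p.c_err}
            for k, p in self.items()}}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_mapping(cls, categories: dict) -> "ReferenceParamSet":
        out = cls()
        for name, coeffs in categories.items():
            out[name] = CorrelationParams(
                category=name,
                a=float(coeffs["a"]), b=float(coeffs["b"]), c=float(coeffs["c"]),
                a_err=float(coeffs.get("a_err", "nan")),
                b_err=float(coeffs.get("b_err", "nan")),
                c_err=float(coeffs.get("c_err", "nan")),
            )
        return out

    @classmethod
    def from_json(cls, path) -> "ReferenceParamSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls.from_mapping(payload["categories"])


def load_reference_params() -> ReferenceParamSet:
    """Load the packaged reference correlation parameters."""
    text = (resources.files("nanodamage") / "data" / "reference_correlations.json"
            ).read_text()
    return ReferenceParamSet.from_mapping(json.loads(text)["categories"])


def eval_yield(dose, let, params: CorrelationParams):
    """Expected per-cell yield of one DSB category at dose D and LET L."""
    d = np.asarray(dose, float)
    l = np.asarray(let, float)
    if np.any(d < 0) or np.any(l < 0):
        raise ValueError("dose and LET must be non-negative")
    out = d * (params.a * l ** 2 + params.b * l + params.c)
    return float(out) if out.ndim == 0 else out


def fit_correlation(samples: pd.DataFrame, category: str = "",
                    weighted: bool | None = None) -> CorrelationParams:
    """Least-squares fit of the quadratic LET correlation.

    ``samples`` needs columns ``dose``, ``let``, ``yield`` (per cell) and
    optionally ``yield_err``.  Dose linearity is enforced by regressing
    yield/dose on LET; weights are 1/err^2 on the dose-normalised yields
    when errors are supplied (or ``weighted=True``), unweighted otherwise.
    """
    if not {"dose", "let", "yield"}.issubset(samples.columns):
        raise ValueError("samples must have dose, let and yield columns")
    d = samples["dose"].to_numpy(float)
    l = samples["let"].to_numpy(float)
    y = samples["yield"].to_numpy(float) / d
    if len(np.unique(l)) < 3:
        raise np.linalg.LinAlgError(
            "need at least 3 distinct LET values to fit a quadratic")
    X = np.column_stack([l ** 2, l, np.ones_like(l)])
    if weighted is None:
        weighted = "yield_err" in samples.columns
    if weighted:
        if "yield_err" not in samples.columns:
            raise ValueError("weighted fit requires a yield_err column")
        w = 1.0 / (samples["yield_err"].to_numpy(float) / d)
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y
    coef, res, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < 3:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    # asymptotic covariance of the LS estimate
    dof = max(len(y) - 3, 1)
    resid = yw - Xw @ coef
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(Xw.T @ Xw)
    errs = np.sqrt(np.diag(cov))
    return CorrelationParams(category=category, a=coef[0], b=coef[1], c=coef[2],
                             a_err=errs[0], b_err=errs[1], c_err=errs[2])


def total_dsb_rate(params: ReferenceParamSet, let: float,
                   genome_gbp: float = GENOME_GBP) -> float:
    """Total DSB induction rate, DSB/Gbp/Gy, summed over the four categories.

    Per-cell yields at 1 Gy are summed and divided by the genome size
    (6 Gbp by default).
    """
    if let < 0:
        raise ValueError("LET must be non-negative")
    cats = [c for c in DSB_CATEGORIES if c in params] or list(params)
    total = sum(eval_yield(1.0, let, params[c]) for c in cats)
    return total / genome_gbp
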