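"""Voxel-wise DSB yield and RBE maps from dose and LET grids.

Co-registered grids of physical dose (Gy) and track-averaged LET (keV/um)
— typically 2 x 2 x 2 mm voxels from a treatment-plan simulation — are
converted per voxel into expected per-cell yields of each DSB category via
the analytic correlations, and into RBE maps against a photon reference:

    RBE_x(v) = proton yield_x(D_v, L_v) / photon yield_x(D_v)

The default photon reference evaluates the same correlations at the Co-60
equivalent LET of 0.2 keV/um, so a voxel with L = 0.2 has RBE = 1 exactly;
any callable ``dose -> (simple_yield, complex_yield)`` can be plugged in
instead.  The *simple* map is the two-backbone-only category; the *complex*
map sums the multi-backbone categories (with or without base damage).

Grid I/O uses MetaImage (.mhd) via SimpleITK with a CSV fallback for 2-D
slices.  A display threshold masks voxels below a fraction of the maximum
dose, as is usual for plan review colourwash.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlations import ReferenceParamSet, eval_yield, load_reference_params
from .tracks import CO60_REFERENCE_LET

__all__ = [
    "VoxelGrid",
    "RbeMaps",
    "read_grid",
    "write_grid",
    "predict_yield_maps",
    "compute_rbe",
    "apply_display_threshold",
    "synthetic_sobp_grids",
    "synthetic_plan_grids",
]

COMPLEX_CATEGORIES = ("complex_DSB", "complex_DSB_with_base")


@dataclass
class VoxelGrid:
    """A scalar voxel grid with MetaImage-style spacing and origin (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    quantity: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)

    @property
    def shape(self):
        return self.values.shape

    def same_lattice(self, other: "VoxelGrid") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing)
                and np.allclose(self.origin, other.origin))

    def like(self, values: np.ndarray, quantity: str) -> "VoxelGrid":
        return VoxelGrid(values=np.asarray(values, float), spacing=self.spacing,
                         origin=self.origin, quantity=quantity)


def write_grid(grid: VoxelGrid, path) -> None:
    """Write a grid as MetaImage (.mhd/.raw) or CSV (2-D only)."""
    path = str(path)
    if path.endswith(".csv"):
        if grid.values.ndim > 2:
            raise ValueError("CSV fallback supports at most 2-D grids")
        np.savetxt(path, np.atleast_2d(grid.values), delimiter=",")
        return
    import SimpleITK as sitk
    img = sitk.GetImageFromArray(grid.values)
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, path)


def read_grid(path, quantity: str = "") -> VoxelGrid:
    """Read a MetaImage (.mhd) or CSV grid."""
    path = str(path)
    if path.endswith(".csv"):
        return VoxelGrid(values=np.loadtxt(path, delimiter=",", ndmin=2),
                         quantity=quantity)
    import SimpleITK as sitk
    img = sitk.ReadImage(path)
    return VoxelGrid(values=sitk.GetArrayFromImage(img).astype(float),
                     spacing=tuple(img.GetSpacing()),
                     origin=tuple(img.GetOrigin()), quantity=quantity)


def predict_yield_maps(dose: VoxelGrid, let: VoxelGrid,
                       params: ReferenceParamSet | None = None) -> dict:
    """Per-voxel expected per-cell yields for every DSB category.

    Returns a dict of category -> VoxelGrid plus the aggregate ``simple``
    (two backbones only) and ``complex`` (multiple backbones and/or bases)
    maps used for RBE.
    """
    params = params or load_reference_params()
    if not dose.same_lattice(let):
        raise ValueError("dose and LET grids must share shape, spacing and origin")
    if np.any(dose.values < 0) or np.any(let.values < 0):
        raise ValueError("dose and LET must be non-negative")
    maps = {}
    for cat, p in params.items():
        maps[cat] = dose.like(eval_yield(dose.values, let.values, p),
                              quantity=f"{cat} yield per cell")
    maps["simple"] = dose.like(maps["simple_DSB"].values, "simple DSB yield per cell")
    cx = sum(maps[c].values for c in COMPLEX_CATEGORIES if c in maps)
    maps["complex"] = dose.like(cx, "complex DSB yield per cell")
    return maps


@dataclass
class RbeMaps:
    """RBE of damage maps with their display mask."""

    rbe_simple: VoxelGrid
    rbe_complex: VoxelGrid
    mask: np.ndarray


def compute_rbe(yield_maps: dict, dose: VoxelGrid,
                params: ReferenceParamSet | None = None,
                photon_reference=None,
                reference_let: float = CO60_REFERENCE_LET,
                threshold_fraction: float = 0.1) -> RbeMaps:
    """Voxel-wise RBE of simple and complex damage against photons.

    ``photon_reference`` may be a callable ``dose_array -> (simple, complex)``
    per-cell photon yields; by default the packaged correlations evaluated at
    ``reference_let`` are used, making the model self-consistent (RBE = 1
    where L = reference LET).  Voxels with zero photon yield are masked, as
    are voxels below the display threshold.
    """
    params = params or load_reference_params()
    if photon_reference is None:
        def photon_reference(d):
            simple = eval_yield(d, np.full_like(d, reference_let),
                                params["simple_DSB"])
            cx = sum(eval_yield(d, np.full_like(d, reference_let), params[c])
                     for c in COMPLEX_CATEGORIES)
            return simple, cx
    ph_simple, ph_complex = photon_reference(dose.values)
    mask = apply_display_threshold(dose, threshold_fraction)
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = np.where(ph_simple > 0, yield_maps["simple"].values / ph_simple, np.nan)
        rc = np.where(ph_complex > 0, yield_maps["complex"].values / ph_complex, np.nan)
    mask = mask & (ph_simple > 0) & (ph_complex > 0)
    return RbeMaps(rbe_simple=dose.like(rs, "RBE simple damage"),
                   rbe_complex=dose.like(rc, "RBE complex damage"),
                   mask=mask)


def apply_display_threshold(grid: VoxelGrid, threshold_fraction: float = 0.1
                            ) -> np.ndarray:
    """Mask of voxels at or above ``threshold_fraction`` of the grid maximum."""
    if not 0.0 <= threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in [0, 1)")
    return grid.values >= threshold_fraction * float(grid.values.max())


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

def synthetic_sobp_grids(n_depth: int = 80, plateau_dose_gy: float = 1.8,
                         entrance_let: float = 1.0, distal_let: float = 10.0,
                         spacing_mm: float = 2.0) -> tuple[VoxelGrid, VoxelGrid]:
    """1-D pseudo-SOBP phantom: a dose plateau with LET rising towards the
    distal edge, then a sharp fall-off.  Returns (dose, LET) grids of shape
    (1, 1, n_depth)."""
    depth = np.arange(n_depth, dtype=float)
    edge = 0.85 * n_depth
    dose = np.where(depth <= edge, plateau_dose_gy, 0.0)
    falloff = (depth > edge) & (depth <= edge + 4)
    dose[falloff] = plateau_dose_gy * np.linspace(0.7, 0.05, falloff.sum())
    let = entrance_let + (distal_let - entrance_let) * (depth / edge) ** 3
    let = np.where(depth <= edge + 4, let, 0.0)
    shape = (1, 1, n_depth)
    sp = (spacing_mm,) * 3
    return (VoxelGrid(dose.reshape(shape), sp, quantity="dose Gy"),
            VoxelGrid(let.reshape(shape), sp, quantity="LET keV/um"))


def synthetic_plan_grids(shape=(16, 24, 24), plateau_dose_gy: float = 1.8,
                         seed: int = 0) -> tuple[VoxelGrid, VoxelGrid]:
    """3-field-like synthetic dose/LET phantom for tests.

    Three orthogonal beams overlap in a central target; LET is elevated at
    each beam's end of range, emulating the hotspots of a real plan.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    dose = np.zeros(shape)
    let = np.full(shape, 0.5)
    cz, cy, cx = nz // 2, ny // 2, nx // 2
    t = 3  # half-width of the target
    for axis in range(3):
        d1 = np.zeros(shape)
        idx = [slice(cz - t, cz + t), slice(cy - t, cy + t), slice(cx - t, cx + t)]
        idx[axis] = slice(None)
        d1[tuple(idx)] = 0.35 * plateau_dose_gy
        # end of range just past the target along this axis
        stop = [cz + t, cy + t, cx + t][axis]
        idx[axis] = slice(stop, min(stop + 2, shape[axis]))
        dose += d1
        let[tuple(idx)] += 6.0
        d1[tuple(idx)] *= 0.4
    dose[tuple(slice(c - t, c + t) for c in (cz, cy, cx))] += 0.05 * plateau_dose_gy
    dose += rng.normal(0.0, 0.005 * plateau_dose_gy, shape).clip(0)
    let += rng.normal(0.0, 0.05, shape).clip(0)
    sp = (2.0, 2.0, 2.0)
    return (VoxelGrid(dose, sp, quantity="dose Gy"),
            VoxelGrid(let, sp, quantity="LET keV/um"))
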