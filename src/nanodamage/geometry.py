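"""Nucleotide-resolution DNA target geometries.

Three simplified volumetric models of the B-DNA double helix are provided
(``sphere``, ``quarter_cylinder``, ``half_cylinder``), each representing every
backbone and base as a single discrete volume carrying a 1-based genome index
so that base-pair separation between damaged volumes is exact.  On top of the
linear helix two composite targets are built: the closed-circular pBR322
plasmid (4361 bp) and a solenoid chromatin fibre (102 histones, 18.3 kbp).

Successive base pairs are rotated 36 degrees about the helix axis (10 bp per
turn, 0.34 nm rise) and paired volumes sit directly opposite each other: the
major/minor groove asymmetry is deliberately not modelled.

Internally a geometry stores per-base-pair frames (axis point, tangent and a
twist reference direction) as dense arrays; point-in-volume queries are
analytic per shape and accelerated with a KD-tree over the axis points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "SHAPES",
    "RISE_NM",
    "TWIST_DEG",
    "DNA_DENSITY_G_CM3",
    "NucleotideVolume",
    "DnaGeometry",
    "HelixSegment",
    "PlasmidGeometry",
    "FibreGeometry",
    "build_helix",
    "build_plasmid",
    "build_fibre",
    "bp_separation",
]

SHAPES = ("sphere", "quarter_cylinder", "half_cylinder")

RISE_NM = 0.34          # axial rise per base pair
TWIST_DEG = 36.0        # helical twist per base pair (10 bp / turn)
DNA_DENSITY_G_CM3 = 1.407

# sphere model radii
SPHERE_BACKBONE_RADIUS = 0.240
SPHERE_BASE_RADIUS = 0.208
# radial placement of the sphere centres: backbones inside the 1.15 nm helix
# envelope, bases tucked inside the central 0.5 nm core
SPHERE_BACKBONE_OFFSET = 1.15 - SPHERE_BACKBONE_RADIUS
SPHERE_BASE_OFFSET = 0.5 - SPHERE_BASE_RADIUS

# cylinder-sector models: base half-cylinder r<=0.5 nm, backbone annular
# sector 0.5..1.15 nm, axial thickness = one bp rise
CYL_BASE_RADIUS = 0.5
CYL_BACKBONE_RADIUS = 1.15
CYL_HALF_THICKNESS = RISE_NM / 2.0
# backbone angular half-width about the strand direction, per model
BACKBONE_HALF_ANGLE = {"quarter_cylinder": math.pi / 4.0, "half_cylinder": math.pi / 2.0}

# packed volume codes: (bp-1)*4 + offset
_OFF_BACKBONE = {1: 0, 2: 1}
_OFF_BASE = {1: 2, 2: 3}


class ConfigurationError(ValueError):
    """Raised for invalid geometry configuration (unknown shape, bad sizes)."""


@dataclass(frozen=True)
class NucleotideVolume:
    """A single backbone or base volume of one nucleotide."""

    bp_index: int
    strand: int
    kind: str                 # "backbone" | "base"
    shape: str
    centre: tuple[float, float, float]
    orientation_deg: float    # twist about the local helix axis
    dimensions: dict = field(default_factory=dict)


def _check_shape(shape: str) -> None:
    if shape not in SHAPES:
        raise ConfigurationError(f"unknown DNA volume model {shape!r}; choose from {SHAPES}")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp(v: np.ndarray) -> np.ndarray:
    """Any unit vector perpendicular to unit vector v."""
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(v, ref))


class DnaGeometry(Sequence):
    """Base class for nucleotide-resolution DNA targets.

    Holds per-bp frames: ``axis_points`` (n,3), ``tangents`` (n,3) and
    ``udirs`` (n,3) — the twisted reference direction pointing from the helix
    axis towards the strand-1 backbone of that base pair.  Iterating the
    geometry yields :class:`NucleotideVolume` objects (4 per bp).
    """

    topology = "linear"

    def __init__(self, shape: str, axis_points: np.ndarray, tangents: np.ndarray,
                 udirs: np.ndarray):
        _check_shape(shape)
        self.shape = shape
        self.axis_points = np.asarray(axis_points, float)
        self.tangents = np.asarray(tangents, float)
        self.udirs = np.asarray(udirs, float)
        self.n_bp = len(self.axis_points)
        self.density_g_cm3 = DNA_DENSITY_G_CM3
        self._vdirs = np.cross(self.tangents, self.udirs)
        self._tree: cKDTree | None = None
        self._histone_tree: cKDTree | None = None
        self._histone_reach = 0.0
        # histone cylinders: (centre xyz, axis xyz, radius, half_height)
        self.histones: np.ndarray | None = None

    # -- indexing ---------------------------------------------------------

    def bp_separation(self, i: int, j: int) -> int:
        if not (1 <= i <= self.n_bp and 1 <= j <= self.n_bp):
            raise IndexError(f"bp index out of range 1..{self.n_bp}: ({i}, {j})")
        d = abs(int(i) - int(j))
        if self.topology == "circular":
            d = min(d, self.n_bp - d)
        return d

    # -- volume enumeration ----------------------------------------------

    def __len__(self) -> int:
        return 4 * self.n_bp

    def __getitem__(self, idx: int) -> NucleotideVolume:
        if isinstance(idx, slice):
            return [self[i] for i in range(*idx.indices(len(self)))]
        if idx < 0:
            idx += len(self)
        if not 0 <= idx < len(self):
            raise IndexError(idx)
        bp = idx // 4 + 1
        off = idx % 4
        strand = 1 if off in (0, 2) else 2
        kind = "backbone" if off in (0, 1) else "base"
        return self._make_volume(bp, strand, kind)

    def __iter__(self) -> Iterator[NucleotideVolume]:
        for i in range(len(self)):
            yield self[i]

    def _make_volume(self, bp: int, strand: int, kind: str) -> NucleotideVolume:
        i = bp - 1
        sgn = 1.0 if strand == 1 else -1.0
        u = self.udirs[i]
        if self.shape == "sphere":
            off = SPHERE_BACKBONE_OFFSET if kind == "backbone" else SPHERE_BASE_OFFSET
            centre = self.axis_points[i] + sgn * off * u
            dims = {"radius": SPHERE_BACKBONE_RADIUS if kind == "backbone" else SPHERE_BASE_RADIUS}
        else:
            if kind == "backbone":
                rmid = 0.5 * (CYL_BASE_RADIUS + CYL_BACKBONE_RADIUS)
                dims = {
                    "radius": CYL_BACKBONE_RADIUS,
                    "inner_radius": CYL_BASE_RADIUS,
                    "thickness": RISE_NM,
                    "half_angle_deg": math.degrees(BACKBONE_HALF_ANGLE[self.shape]),
                }
            else:
                rmid = 0.5 * CYL_BASE_RADIUS
                dims = {"radius": CYL_BASE_RADIUS, "thickness": RISE_NM}
            centre = self.axis_points[i] + sgn * rmid * u
        return NucleotideVolume(
            bp_index=bp, strand=strand, kind=kind, shape=self.shape,
            centre=tuple(centre), orientation_deg=(TWIST_DEG * (bp - 1)) % 360.0,
            dimensions=dims,
        )

    def to_frame(self) -> pd.DataFrame:
        """Columnar serialisation: one row per volume."""
        rows = []
        for v in self:
            rows.append({
                "bp_index": v.bp_index, "strand": v.strand, "kind": v.kind,
                "shape": v.shape, "x_nm": v.centre[0], "y_nm": v.centre[1],
                "z_nm": v.centre[2], "orientation_deg": v.orientation_deg,
                **{f"dim_{k}": val for k, val in v.dimensions.items()},
            })
        return pd.DataFrame(rows)

    # -- point-in-volume queries -----------------------------------------

    def _kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.axis_points)
        return self._tree

    @property
    def _query_radius(self) -> float:
        if self.shape == "sphere":
            return SPHERE_BACKBONE_OFFSET + SPHERE_BACKBONE_RADIUS + 1e-9
        return math.hypot(CYL_BACKBONE_RADIUS, CYL_HALF_THICKNESS) + 1e-9

    _LOCATE_K = 8  # candidate axis points per query (nearest-first priority)

    def locate(self, points: np.ndarray) -> np.ndarray:
        """Classify points into volumes.

        Returns an int64 array of packed volume codes ``(bp-1)*4 + offset``
        (offset 0/1 backbone strand 1/2, offset 2/3 base strand 1/2) or -1
        where the point is outside every DNA volume.  Where volumes of
        different base pairs touch, the nearer axis point wins.  Vectorised
        over the ``_LOCATE_K`` nearest axis points of each query.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        n = len(pts)
        out = np.full(n, -1, dtype=np.int64)
        if self.n_bp == 0 or n == 0:
            return out
        k = min(self._LOCATE_K, self.n_bp)
        dist, idx = self._kdtree().query(pts, k=k,
                                         distance_upper_bound=self._query_radius)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        undecided = np.ones(n, dtype=bool)
        for col in range(k):
            valid = undecided & np.isfinite(dist[:, col])
            if not valid.any():
                break
            sel = np.flatnonzero(valid)
            codes = self._classify_batch(pts[sel], idx[sel, col])
            hitmask = codes >= 0
            out[sel[hitmask]] = codes[hitmask]
            undecided[sel[hitmask]] = False
        return out

    def _classify_batch(self, p: np.ndarray, i: np.ndarray) -> np.ndarray:
        """Classify points p (m,3) against candidate bp indices i (m,)."""
        m = len(p)
        codes = np.full(m, -1, dtype=np.int64)
        d = p - self.axis_points[i]
        u = self.udirs[i]
        if self.shape == "sphere":
            x = np.einsum("ij,ij->i", d, u)  # component along strand-1 direction
            rest2 = np.einsum("ij,ij->i", d, d) - x * x
            for strand, sgn in ((1, 1.0), (2, -1.0)):
                bb = (x - sgn * SPHERE_BACKBONE_OFFSET) ** 2 + rest2 \
                    <= SPHERE_BACKBONE_RADIUS ** 2
                codes = np.where(bb & (codes < 0), 4 * i + _OFF_BACKBONE[strand], codes)
                ba = (x - sgn * SPHERE_BASE_OFFSET) ** 2 + rest2 <= SPHERE_BASE_RADIUS ** 2
                codes = np.where(ba & (codes < 0), 4 * i + _OFF_BASE[strand], codes)
            return codes
        tg = self.tangents[i]
        t = np.einsum("ij,ij->i", d, tg)
        rho = d - t[:, None] * tg
        r2 = np.einsum("ij,ij->i", rho, rho)
        inslab = (np.abs(t) <= CYL_HALF_THICKNESS) & (r2 <= CYL_BACKBONE_RADIUS ** 2)
        x = np.einsum("ij,ij->i", rho, u)
        y = np.einsum("ij,ij->i", rho, self._vdirs[i])
        phi = np.arctan2(y, x)  # 0 along strand-1 direction
        isbase = inslab & (r2 <= CYL_BASE_RADIUS ** 2)
        codes = np.where(isbase & (x >= 0), 4 * i + _OFF_BASE[1], codes)
        codes = np.where(isbase & (x < 0), 4 * i + _OFF_BASE[2], codes)
        half = BACKBONE_HALF_ANGLE[self.shape]
        isbb = inslab & ~isbase
        codes = np.where(isbb & (np.abs(phi) <= half), 4 * i + _OFF_BACKBONE[1], codes)
        codes = np.where(isbb & (np.abs(np.abs(phi) - math.pi) <= half),
                         4 * i + _OFF_BACKBONE[2], codes)
        return codes

    def in_histone(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: point lies inside any histone cylinder."""
        pts = np.atleast_2d(np.asarray(points, float))
        mask = np.zeros(len(pts), dtype=bool)
        if self.histones is None or len(pts) == 0:
            return mask
        if self._histone_tree is None:
            self._histone_tree = cKDTree(self.histones[:, 0:3])
            self._histone_reach = float(np.max(np.hypot(self.histones[:, 6],
                                                        self.histones[:, 7])))
        dist, h = self._histone_tree.query(pts, distance_upper_bound=self._histone_reach)
        near = np.isfinite(dist)
        if not near.any():
            return mask
        sel = np.flatnonzero(near)
        hh = h[sel]
        d = pts[sel] - self.histones[hh, 0:3]
        t = np.einsum("ij,ij->i", d, self.histones[hh, 3:6])
        rho2 = np.einsum("ij,ij->i", d, d) - t * t
        inside = (np.abs(t) <= self.histones[hh, 7]) & (rho2 <= self.histones[hh, 6] ** 2)
        mask[sel] = inside
        return mask

    # -- rigid transforms -------------------------------------------------

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "DnaGeometry":
        """Return a rigidly rotated/translated copy (damage statistics must
        be invariant under this)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        tvec = np.zeros(3) if translation is None else np.asarray(translation, float)
        import copy
        g = copy.copy(self)
        g.axis_points = self.axis_points @ R.T + tvec
        g.tangents = self.tangents @ R.T
        g.udirs = self.udirs @ R.T
        g._vdirs = np.cross(g.tangents, g.udirs)
        g._tree = None
        g._histone_tree = None
        if self.histones is not None:
            h = self.histones.copy()
            h[:, 0:3] = h[:, 0:3] @ R.T + tvec
            h[:, 3:6] = h[:, 3:6] @ R.T
            g.histones = h
        return g

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        pad = self._query_radius
        return self.axis_points.min(axis=0) - pad, self.axis_points.max(axis=0) + pad


class HelixSegment(DnaGeometry):
    """A straight double-helix segment."""


class PlasmidGeometry(DnaGeometry):
    """The closed-circular pBR322 plasmid (4361 bp) laid flat at z = 0.

    The helix axis follows a circle in the coverslip plane; the surrounding
    water torus diameter and the coverslip half-space flag are recorded for
    the irradiation assay.
    """

    topology = "circular"
    torus_diameter_nm = 2.4

    def __init__(self, shape: str, n_bp: int = 4361, coverslip: bool = True):
        radius = n_bp * RISE_NM / (2.0 * math.pi)
        alpha = 2.0 * math.pi * (np.arange(n_bp) + 0.5) / n_bp
        axis_points = np.column_stack([radius * np.cos(alpha),
                                       radius * np.sin(alpha),
                                       np.zeros(n_bp)])
        tangents = np.column_stack([-np.sin(alpha), np.cos(alpha), np.zeros(n_bp)])
        theta = np.radians(TWIST_DEG * np.arange(n_bp))
        # twist reference frame: e1 = z-hat, e2 = radial outward
        zhat = np.array([0.0, 0.0, 1.0])
        radial = np.column_stack([np.cos(alpha), np.sin(alpha), np.zeros(n_bp)])
        udirs = np.cos(theta)[:, None] * zhat + np.sin(theta)[:, None] * radial
        super().__init__(shape, axis_points, tangents, udirs)
        self.circle_radius_nm = radius
        self.coverslip = coverslip


class FibreGeometry(DnaGeometry):
    """Solenoid chromatin fibre: 102 histones, 1.65 wrap turns each.

    198 nm long, 37 nm diameter, 5.7 nucleosomes per 11 nm, inside a water
    cylinder envelope of 203 nm x 42 nm diameter.  Genome indexing runs
    contiguously through wrapped and linker DNA.
    """

    LENGTH_NM = 198.0
    DIAMETER_NM = 37.0
    N_HISTONES = 102
    WRAP_TURNS = 1.65
    NUCLEOSOMES_PER_TURN = 6          # -> 17 solenoid turns
    SOLENOID_RADIUS_NM = 12.5
    HISTONE_RADIUS_NM = 3.3
    HISTONE_HALF_HEIGHT_NM = 2.85
    ENVELOPE_LENGTH_NM = 203.0
    ENVELOPE_DIAMETER_NM = 42.0

    def __init__(self, shape: str, wrapped_bp: int = 120, linker_bp: int = 60):
        if linker_bp < 0:
            raise ConfigurationError("linker_bp must be >= 0")
        nh = self.N_HISTONES
        pitch = self.LENGTH_NM / (nh / self.NUCLEOSOMES_PER_TURN)  # nm per turn
        beta = 2.0 * math.pi * np.arange(nh) / self.NUCLEOSOMES_PER_TURN
        # end margin keeps the wrapped DNA of the outermost nucleosomes
        # (superhelix radius ~4 nm) inside the water envelope caps
        margin = 3.5
        zc = margin + (np.arange(nh) + 0.5) * (self.LENGTH_NM - 2 * margin) / nh
        centres = np.column_stack([self.SOLENOID_RADIUS_NM * np.cos(beta),
                                   self.SOLENOID_RADIUS_NM * np.sin(beta),
                                   zc])
        # histone axis: tangent of the solenoid path
        dz = pitch / (2.0 * math.pi * self.SOLENOID_RADIUS_NM)
        haxes = np.column_stack([-np.sin(beta), np.cos(beta), np.full(nh, dz)])
        haxes /= np.linalg.norm(haxes, axis=1, keepdims=True)

        # DNA superhelix around each histone: arc length must equal
        # wrapped_bp * rise over WRAP_TURNS turns
        sh_pitch = 2.39  # nm per superhelix turn, nucleosome-like
        arc = wrapped_bp * RISE_NM
        per_turn = arc / self.WRAP_TURNS
        sh_radius = math.sqrt(max(per_turn ** 2 - sh_pitch ** 2, 1.0)) / (2.0 * math.pi)
        wrap_extent = self.WRAP_TURNS * sh_pitch

        max_radial = (self.SOLENOID_RADIUS_NM + sh_radius + wrap_extent / 2.0
                      + CYL_BACKBONE_RADIUS)
        if 2.0 * max_radial > self.ENVELOPE_DIAMETER_NM:
            raise ConfigurationError(
                f"fibre DNA (radial extent {max_radial:.2f} nm) exceeds the "
                f"{self.ENVELOPE_DIAMETER_NM} nm water envelope")

        axis_pts, tangents, udirs = [], [], []
        prev_exit = None
        theta_acc = 0  # global bp counter for continuous twist
        for h in range(nh):
            m = np.column_stack([np.cos(beta[h]), np.sin(beta[h]), 0.0])[0]  # radial
            nvec = np.cross(haxes[h], m)
            # wrapped bp path
            frac = (np.arange(wrapped_bp) + 0.5) / wrapped_bp
            gamma = 2.0 * math.pi * self.WRAP_TURNS * frac
            axial = (frac - 0.5) * wrap_extent
            pts = (centres[h]
                   + sh_radius * (np.cos(gamma)[:, None] * m + np.sin(gamma)[:, None] * nvec)
                   + axial[:, None] * haxes[h])
            dgam = 2.0 * math.pi * self.WRAP_TURNS / wrapped_bp
            tans = (sh_radius * dgam * (-np.sin(gamma)[:, None] * m
                                        + np.cos(gamma)[:, None] * nvec)
                    + (wrap_extent / wrapped_bp) * haxes[h])
            tans /= np.linalg.norm(tans, axis=1, keepdims=True)
            if prev_exit is not None and linker_bp > 0:
                # straight linker from previous wrap exit to this wrap entry
                a, b = prev_exit, pts[0]
                seg = b - a
                if np.linalg.norm(seg) / linker_bp > RISE_NM:
                    raise ConfigurationError(
                        f"linker_bp={linker_bp} cannot span the "
                        f"{np.linalg.norm(seg):.1f} nm inter-nucleosome gap "
                        f"at {RISE_NM} nm/bp")
                lfrac = (np.arange(linker_bp) + 0.5) / linker_bp
                lpts = a + lfrac[:, None] * seg
                ltan = np.tile(_unit(seg), (linker_bp, 1))
                axis_pts.append(lpts)
                tangents.append(ltan)
                udirs.append(self._twisted_frame(ltan, theta_acc))
                theta_acc += linker_bp
            elif prev_exit is not None and linker_bp == 0:
                pass
            axis_pts.append(pts)
            tangents.append(tans)
            udirs.append(self._twisted_frame(tans, theta_acc))
            theta_acc += wrapped_bp
            prev_exit = pts[-1]

        axis_points = np.concatenate(axis_pts)
        tangents = np.concatenate(tangents)
        udirs = np.concatenate(udirs)
        super().__init__(shape, axis_points, tangents, udirs)
        self.wrapped_bp = wrapped_bp
        self.linker_bp = linker_bp
        self.total_bp = self.n_bp
        self.histones = np.column_stack([
            centres, haxes,
            np.full(nh, self.HISTONE_RADIUS_NM),
            np.full(nh, self.HISTONE_HALF_HEIGHT_NM),
        ])
        self.wrap_turns_per_histone = self.WRAP_TURNS
        self.packing_nucleosomes_per_11nm = 5.7

    @staticmethod
    def _twisted_frame(tangents: np.ndarray, bp_offset: int) -> np.ndarray:
        """Reference directions with 36 deg twist per bp, continuous index."""
        n = len(tangents)
        theta = np.radians(TWIST_DEG * (bp_offset + np.arange(n)))
        udirs = np.empty_like(tangents)
        for j in range(n):
            e1 = _perp(tangents[j])
            e2 = np.cross(tangents[j], e1)
            udirs[j] = math.cos(theta[j]) * e1 + math.sin(theta[j]) * e2
        return udirs

    def envelope_chord(self, origin: np.ndarray, direction: np.ndarray) -> float:
        """Path length from origin along direction to exit the water envelope."""
        cx = np.array([0.0, 0.0, self.LENGTH_NM / 2.0])
        o = np.asarray(origin, float) - cx
        d = _unit(np.asarray(direction, float))
        r = self.ENVELOPE_DIAMETER_NM / 2.0
        hz = self.ENVELOPE_LENGTH_NM / 2.0
        # exit through lateral surface
        a = d[0] ** 2 + d[1] ** 2
        ts = []
        if a > 1e-12:
            b = 2.0 * (o[0] * d[0] + o[1] * d[1])
            c = o[0] ** 2 + o[1] ** 2 - r ** 2
            disc = b * b - 4 * a * c
            if disc >= 0:
                for t in ((-b + math.sqrt(disc)) / (2 * a),):
                    if t > 0:
                        ts.append(t)
        if abs(d[2]) > 1e-12:
            for zcap in (-hz, hz):
                t = (zcap - o[2]) / d[2]
                if t > 0:
                    ts.append(t)
        return min(ts) if ts else 0.0


def build_helix(n_bp: int, shape: str, origin=(0.0, 0.0, 0.0),
                axis=(0.0, 0.0, 1.0)) -> HelixSegment:
    """Build a straight double-helix segment of ``n_bp`` base pairs."""
    if n_bp < 1:
        raise ConfigurationError("n_bp must be >= 1")
    _check_shape(shape)
    a = _unit(np.asarray(axis, float))
    origin = np.asarray(origin, float)
    z = (np.arange(n_bp) + 0.5) * RISE_NM
    axis_points = origin + z[:, None] * a
    tangents = np.tile(a, (n_bp, 1))
    e1 = _perp(a)
    e2 = np.cross(a, e1)
    theta = np.radians(TWIST_DEG * np.arange(n_bp))
    udirs = np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2
    return HelixSegment(shape, axis_points, tangents, udirs)


def build_plasmid(shape: str) -> PlasmidGeometry:
    """Build the 4361 bp closed-circular pBR322 plasmid target."""
    return PlasmidGeometry(shape)


def build_fibre(shape: str, wrapped_bp: int = 120, linker_bp: int = 60) -> FibreGeometry:
    """Build the solenoid chromatin fibre (defaults give 18 300 bp)."""
    return FibreGeometry(shape, wrapped_bp=wrapped_bp, linker_bp=linker_bp)


def bp_separation(geometry: DnaGeometry, i: int, j: int) -> int:
    """Base-pair separation along the genome (shortest arc on circles)."""
    return geometry.bp_separation(i, j)
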