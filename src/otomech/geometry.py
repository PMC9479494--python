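"""Parametric, schematic middle-ear geometry and tetrahedral meshing.

The middle ear is represented by simple primitives that retain the
load path of the real organ: a conical tympanic membrane (eardrum),
box-shaped ossicles (malleus, incus, stapes) chained along a single
transmission axis, short elastic bridges for the incudomalleolar and
incudostapedial joints, prismatic suspensory ligaments/tendons, and a
ring of elements (the annular ligament) seating the stapes footplate
in the oval window.

All blocks are meshed on conforming structured lattices and split into
linear tetrahedra with the Freudenthal/Kuhn decomposition, so shared
interfaces carry identical nodes and faces, the chain
tm -> malleus -> joints -> incus -> stapes -> annular ligament is
connected by construction, and meshing is fully deterministic.

Units are SI (metres) throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import itertools
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import yaml

__all__ = [
    "GeometrySpec",
    "Mesh",
    "GeometryParameterError",
    "REGIONS",
    "CHAIN_REGIONS",
    "build_middle_ear_mesh",
    "validate_mesh",
    "write_vtk",
]

#: Region labels, in transmission-chain order where applicable.
REGIONS = (
    "tm",
    "malleus",
    "incus",
    "stapes",
    "im_joint",
    "is_joint",
    "annular_ligament",
    "aml",
    "pil",
    "tensor_tympani",
    "stapedius",
)

#: The ossicular transmission chain; consecutive entries must share nodes.
CHAIN_REGIONS = (
    "tm",
    "malleus",
    "im_joint",
    "incus",
    "is_joint",
    "stapes",
    "annular_ligament",
)

_LIGAMENTS = ("aml", "pil", "tensor_tympani", "stapedius")


class GeometryParameterError(ValueError):
    """A geometry parameter is infeasible; the message names the field."""


@dataclass(frozen=True)
class GeometrySpec:
    """Dimensions of the schematic middle ear, in metres.

    The tympanic membrane is a shallow cone of radius ``tm_radius``
    whose apex patch carries the malleus; ossicles share a square
    ``ossicle_width`` cross-section and are chained along the x axis;
    ligaments/tendons are square-section prisms of the stated
    equivalent radius (cross-sectional area ``pi * r**2`` preserved).
    ``mesh_resolution`` is the target element edge length; thin
    directions always receive at least two element layers.
    """

    tm_radius: float = 3.2e-3
    tm_depth: float = 1.2e-3
    tm_thickness: float = 0.6e-3
    ossicle_width: float = 1.2e-3
    malleus_length: float = 4.8e-3
    incus_length: float = 4.8e-3
    incus_process_width: float = 1.2e-3
    stapes_length: float = 2.4e-3
    stapes_offset: float = 0.0
    im_joint_length: float = 0.6e-3
    is_joint_length: float = 0.6e-3
    footplate_width: float = 3.0e-3
    footplate_height: float = 1.8e-3
    footplate_thickness: float = 0.6e-3
    annular_ring_width: float = 0.6e-3
    aml_radius: float = 0.34e-3
    aml_length: float = 1.8e-3
    pil_radius: float = 0.34e-3
    pil_length: float = 1.8e-3
    tensor_tympani_radius: float = 0.34e-3
    tensor_tympani_length: float = 1.8e-3
    stapedius_radius: float = 0.34e-3
    stapedius_length: float = 1.8e-3
    attic_patch_fraction: float = 0.0625
    mesh_resolution: float = 0.3e-3

    def __post_init__(self) -> None:
        for name, value in dataclasses.asdict(self).items():
            if name == "stapes_offset":
                if not (value >= 0.0 and math.isfinite(value)):
                    raise GeometryParameterError(
                        f"{name} must be >= 0 and finite, got {value!r}"
                    )
                continue
            if not (value > 0.0 and math.isfinite(value)):
                raise GeometryParameterError(
                    f"{name} must be strictly positive and finite, got {value!r}"
                )
        if not self.attic_patch_fraction <= 1.0:
            raise GeometryParameterError(
                f"attic_patch_fraction must be in (0, 1], got {self.attic_patch_fraction!r}"
            )
        # The mesh resolution must resolve the thinnest structure.
        thicknesses = {
            "tm_thickness": self.tm_thickness,
            "ossicle_width": self.ossicle_width,
            "im_joint_length": self.im_joint_length,
            "is_joint_length": self.is_joint_length,
            "footplate_thickness": self.footplate_thickness,
            "annular_ring_width": self.annular_ring_width,
        }
        for lig in _LIGAMENTS:
            thicknesses[f"{lig}_radius"] = getattr(self, f"{lig}_radius") * math.sqrt(math.pi)
        for name, t in thicknesses.items():
            if self.mesh_resolution >= t * (1 + 1e-12):
                raise GeometryParameterError(
                    f"mesh_resolution {self.mesh_resolution!r} is too coarse to "
                    f"resolve {name} = {t!r}"
                )
        if self.ossicle_width >= 2 * self.tm_radius:
            raise GeometryParameterError(
                "ossicle_width must be smaller than the tympanic membrane diameter"
            )
        if self.footplate_width <= self.ossicle_width or self.footplate_height <= self.ossicle_width:
            raise GeometryParameterError(
                "footplate_width/footplate_height must exceed ossicle_width"
            )

    # -- serialization ---------------------------------------------------

    def to_yaml(self, path=None) -> str:
        """Serialize to YAML (lossless round-trip via ``from_yaml``)."""
        text = yaml.safe_dump(
            {k: float(v) for k, v in dataclasses.asdict(self).items()},
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write("# Middle-ear geometry, SI units (metres; fractions dimensionless)\n")
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "GeometrySpec":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(io.StringIO(str(source)))
        return cls(**data)

    @classmethod
    def default(cls) -> "GeometrySpec":
        from .config import load_default_geometry

        return load_default_geometry()


@dataclass
class Mesh:
    """Tetrahedral mesh with region labels and named node/face sets.

    ``node_coordinates``: (n_nodes, 3) float array, metres.
    ``tetrahedra``: (n_elems, 4) int array, 0-based node indices with
    positive signed volume. ``region``: per-element label. Face sets
    are (n, 3) node triples with outward orientation.
    """

    node_coordinates: np.ndarray
    tetrahedra: np.ndarray
    region: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    face_sets: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return int(self.node_coordinates.shape[0])

    @property
    def n_elements(self) -> int:
        return int(self.tetrahedra.shape[0])

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.node_coordinates, self.tetrahedra)

    def region_volume(self, label: str) -> float:
        return float(self.volumes()[self.region == label].sum())

    def elements_of(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.region == label)

    def content_hash(self) -> str:
        """SHA-1 over coordinates, connectivity, labels and sets."""
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.node_coordinates).tobytes())
        h.update(np.ascontiguousarray(self.tetrahedra).tobytes())
        h.update("|".join(self.region.tolist()).encode())
        for name in sorted(self.node_sets):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.node_sets[name]).tobytes())
        for name in sorted(self.face_sets):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.face_sets[name]).tobytes())
        return h.hexdigest()


def tet_volumes(coords: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for right-handed ordering)."""
    p = coords[tets]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


# ---------------------------------------------------------------------------
# Structured block builder
# ---------------------------------------------------------------------------

# Freudenthal/Kuhn 6-tet split of the unit cube: every tet contains the
# main diagonal (0,0,0)-(1,1,1); face diagonals always run from the
# face's minimum corner to its maximum corner, which makes the split
# conforming across any two lattice blocks aligned with the axes.
_KUHN_PATHS: list[tuple[tuple[int, int, int], ...]] = []
for _perm in itertools.permutations(range(3)):
    _acc = [0, 0, 0]
    _path = [tuple(_acc)]
    for _ax in _perm:
        _acc[_ax] = 1
        _path.append(tuple(_acc))
    _KUHN_PATHS.append(tuple(_path))


class _MeshBuilder:
    """Accumulates lattice blocks, deduplicating nodes by position."""

    def __init__(self, tol: float = 1e-9):
        self.tol = tol
        self._lookup: dict[tuple[int, int, int], int] = {}
        self.coords: list[tuple[float, float, float]] = []
        self.tets: list[tuple[int, int, int, int]] = []
        self.regions: list[str] = []

    def node(self, x: float, y: float, z: float) -> int:
        base = (round(x / self.tol), round(y / self.tol), round(z / self.tol))
        hit = self._lookup.get(base)
        if hit is not None:
            return hit
        # guard against coordinates straddling a rounding boundary
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    key = (base[0] + dx, base[1] + dy, base[2] + dz)
                    hit = self._lookup.get(key)
                    if hit is not None and (dx or dy or dz):
                        cx, cy, cz = self.coords[hit]
                        if (
                            abs(cx - x) <= self.tol
                            and abs(cy - y) <= self.tol
                            and abs(cz - z) <= self.tol
                        ):
                            return hit
        idx = len(self.coords)
        self.coords.append((x, y, z))
        self._lookup[base] = idx
        return idx

    def add_lattice(
        self,
        point_fn: Callable[[int, int, int], tuple[float, float, float]],
        shape: tuple[int, int, int],
        region_fn,
    ) -> np.ndarray:
        """Add an (ni, nj, nk)-cell block; returns the node-index lattice.

        ``point_fn(i, j, k)`` gives the lattice point position; lattice
        axes must ascend with the global axes (or a consistent mapped
        frame) so that Kuhn splits conform across block interfaces.
        ``region_fn(i, j, k)`` labels cell (i, j, k).
        """
        ni, nj, nk = shape
        idx = np.empty((ni + 1, nj + 1, nk + 1), dtype=np.int64)
        for i in range(ni + 1):
            for j in range(nj + 1):
                for k in range(nk + 1):
                    idx[i, j, k] = self.node(*point_fn(i, j, k))
        for i in range(ni):
            for j in range(nj):
                for k in range(nk):
                    label = region_fn(i, j, k) if callable(region_fn) else region_fn
                    if label is None:
                        continue
                    for path in _KUHN_PATHS:
                        tet = tuple(
                            int(idx[i + d[0], j + d[1], k + d[2]]) for d in path
                        )
                        self.tets.append(tet)
                        self.regions.append(label)
        return idx

    def finish(self) -> Mesh:
        coords = np.asarray(self.coords, dtype=np.float64)
        tets = np.asarray(self.tets, dtype=np.int64)
        vols = tet_volumes(coords, tets)
        flip = vols < 0
        tets[flip] = tets[flip][:, [0, 1, 3, 2]]
        return Mesh(
            node_coordinates=coords,
            tetrahedra=tets,
            region=np.asarray(self.regions, dtype=object),
        )


def _ncells(length: float, res: float, minimum: int = 2) -> int:
    return max(minimum, round(length / res))


def _extend_line(inner: np.ndarray, lo: float, hi: float, res: float) -> np.ndarray:
    """Extend a grid line set outward to [lo, hi] with ~res pitch."""
    left = np.linspace(lo, inner[0], _ncells(inner[0] - lo, res, 1) + 1)
    right = np.linspace(inner[-1], hi, _ncells(hi - inner[-1], res, 1) + 1)
    return np.concatenate([left[:-1], inner, right[1:]])


# ---------------------------------------------------------------------------
# Mesh construction
# ---------------------------------------------------------------------------


def build_middle_ear_mesh(spec: GeometrySpec) -> Mesh:
    """Build the schematic middle-ear mesh for ``spec``.

    Deterministic: identical specs produce bit-identical meshes.
    Raises :class:`GeometryParameterError` for infeasible parameters
    (the spec's own validation catches most; attachment feasibility is
    checked here).
    """
    res = spec.mesh_resolution
    a = spec.ossicle_width / 2.0
    b = _MeshBuilder()

    # -- upper ossicular chain box (x: 0 .. end of incus) ----------------
    # The incus carries a long process dropping the transmission axis by
    # ``stapes_offset``; the incudostapedial joint and stapes continue at
    # the lower level, so incus rotation works a lever into the stapes
    # and a stiff joint can hand bending moments on to the footplate.
    seg_defs = [
        ("malleus", spec.malleus_length),
        ("im_joint", spec.im_joint_length),
        ("incus", spec.incus_length),
    ]
    xs_chain = [np.array([0.0])]
    seg_slices: dict[str, slice] = {}
    x0 = 0.0
    cell_start = 0
    for name, length in seg_defs:
        n = _ncells(length, res)
        xs_chain.append(np.linspace(x0, x0 + length, n + 1)[1:])
        seg_slices[name] = slice(cell_start, cell_start + n)
        cell_start += n
        x0 += length
    xs_chain = np.concatenate(xs_chain)
    n_in = _ncells(spec.ossicle_width, res)
    ys_chain = np.linspace(-a, a, n_in + 1)
    zs_chain = ys_chain.copy()

    seg_label = np.empty(cell_start, dtype=object)
    for name, sl in seg_slices.items():
        seg_label[sl] = name

    chain_idx = b.add_lattice(
        lambda i, j, k: (xs_chain[i], ys_chain[j], zs_chain[k]),
        (cell_start, n_in, n_in),
        lambda i, j, k: seg_label[i],
    )

    # -- optional incus long process + lower (stapes-level) axis ---------
    # With stapes_offset = 0 the chain continues straight; a positive
    # offset drops the incudostapedial joint and stapes by that amount,
    # connected through an incus long process.
    D = spec.stapes_offset
    cell = 2 * a / n_in
    x_inc_end = float(xs_chain[-1])
    if D > 0:
        k_off = D / cell
        if abs(k_off - round(k_off)) > 1e-9:
            raise GeometryParameterError(
                f"stapes_offset {D!r} must be a multiple of the ossicle cross "
                f"cell size {cell!r} (ossicle_width / cross divisions)"
            )
        zs_low = np.linspace(-a - D, a - D, n_in + 1)
        wp_cells = _ncells(spec.incus_process_width, res, minimum=2)
        inc_sl = seg_slices["incus"]
        if (inc_sl.stop - inc_sl.start) < wp_cells + 2:
            raise GeometryParameterError(
                "incus_process_width: incus has too few axial cells for the process"
            )
        xs_proc = xs_chain[inc_sl.stop - wp_cells : inc_sl.stop + 1]
        zs_proc = zs_low[zs_low <= -a + 1e-12]
        if zs_proc.size < 2:
            raise GeometryParameterError(
                "stapes_offset too small: the incus long process has no extent"
            )
        b.add_lattice(
            lambda i, j, k: (xs_proc[i], ys_chain[j], zs_proc[k]),
            (len(xs_proc) - 1, n_in, len(zs_proc) - 1),
            "incus",
        )
    else:
        zs_low = zs_chain

    low_defs = [
        ("is_joint", spec.is_joint_length),
        ("stapes", spec.stapes_length),
    ]
    xs_low = [np.array([x_inc_end])]
    low_slices: dict[str, slice] = {}
    x0 = x_inc_end
    low_start = 0
    for name, length in low_defs:
        n = _ncells(length, res)
        xs_low.append(np.linspace(x0, x0 + length, n + 1)[1:])
        low_slices[name] = slice(low_start, low_start + n)
        low_start += n
        x0 += length
    xs_low = np.concatenate(xs_low)
    low_label = np.empty(low_start, dtype=object)
    for name, sl in low_slices.items():
        low_label[sl] = name
    b.add_lattice(
        lambda i, j, k: (xs_low[i], ys_chain[j], zs_low[k]),
        (low_start, n_in, n_in),
        lambda i, j, k: low_label[i],
    )

    # -- tympanic membrane ----------------------------------------------
    t = spec.tm_thickness
    nk_tm = _ncells(t, res)
    xl_tm = np.linspace(-t, 0.0, nk_tm + 1)
    n_ring = max(1, round((spec.tm_radius - a) / res))
    R = spec.tm_radius

    tm_lattices = []
    # inner (apex) block: same (y, z) grid as the chain cross-section
    tm_lattices.append(
        b.add_lattice(
            lambda i, j, k: (xl_tm[k], ys_chain[i], zs_chain[j]),
            (n_in, n_in, nk_tm),
            "tm",
        )
    )
    # four transition blocks mapping the apex square out to the rim circle;
    # the tangential parameter ascends with the relevant global axis so
    # Kuhn face diagonals match across all interfaces.
    # (P_sq(j), theta(j)) per side; l is the outward (ring) axis.
    def _side(block_sq, thetas):
        def point(l, j, k):
            lam = l / n_ring
            sy, sz = block_sq[j]
            cy, cz = R * math.cos(thetas[j]), R * math.sin(thetas[j])
            y = sy + lam * (cy - sy)
            z = sz + lam * (cz - sz)
            return (xl_tm[k] - spec.tm_depth * lam, y, z)

        return b.add_lattice(point, (n_ring, n_in, nk_tm), "tm")

    q = math.pi / 4.0
    # east (y=+a, z ascending), theta -45..45 deg
    tm_lattices.append(
        _side(
            [(a, zs_chain[j]) for j in range(n_in + 1)],
            [-q + 2 * q * j / n_in for j in range(n_in + 1)],
        )
    )
    # north (z=+a, y ascending), theta 135..45 deg (descending)
    tm_lattices.append(
        _side(
            [(ys_chain[j], a) for j in range(n_in + 1)],
            [3 * q - 2 * q * j / n_in for j in range(n_in + 1)],
        )
    )
    # west (y=-a, z ascending), theta 225..135 deg (descending)
    tm_lattices.append(
        _side(
            [(-a, zs_chain[j]) for j in range(n_in + 1)],
            [5 * q - 2 * q * j / n_in for j in range(n_in + 1)],
        )
    )
    # south (z=-a, y ascending), theta 225..315 deg
    tm_lattices.append(
        _side(
            [(ys_chain[j], -a) for j in range(n_in + 1)],
            [5 * q + 2 * q * j / n_in for j in range(n_in + 1)],
        )
    )

    # eardrum rim nodes (outer circle, all thickness layers)
    tm_rim = set()
    for lat in tm_lattices[1:]:
        tm_rim.update(int(v) for v in lat[n_ring, :, :].ravel())

    # lateral (ear-canal facing) load faces: k = 0 layer of every TM block,
    # triangulated along the Kuhn face diagonal (min corner -> max corner),
    # oriented so the outward normal points toward -x (the ear canal).
    tm_load = []
    for lat in tm_lattices:
        ni, nj = lat.shape[0] - 1, lat.shape[1] - 1
        for i in range(ni):
            for j in range(nj):
                v00 = int(lat[i, j, 0])
                v10 = int(lat[i + 1, j, 0])
                v11 = int(lat[i + 1, j + 1, 0])
                v01 = int(lat[i, j + 1, 0])
                tm_load.append((v00, v11, v10))
                tm_load.append((v00, v01, v11))

    # -- stapes footplate plate + annular ligament ring ------------------
    x_fp0 = float(xs_low[-1])
    nx_fp = _ncells(spec.footplate_thickness, res)
    xs_fp = np.linspace(x_fp0, x_fp0 + spec.footplate_thickness, nx_fp + 1)
    W2, H2 = spec.footplate_width / 2.0, spec.footplate_height / 2.0
    ys_fp = _extend_line(ys_chain, -W2, W2, res)
    zs_fp = _extend_line(zs_low, -H2 - D, H2 - D, res)
    fp_idx = b.add_lattice(
        lambda i, j, k: (xs_fp[i], ys_fp[j], zs_fp[k]),
        (nx_fp, len(ys_fp) - 1, len(zs_fp) - 1),
        "stapes",
    )
    footplate_faces = []
    for j in range(len(ys_fp) - 1):
        for k in range(len(zs_fp) - 1):
            v00 = int(fp_idx[nx_fp, j, k])
            v10 = int(fp_idx[nx_fp, j + 1, k])
            v11 = int(fp_idx[nx_fp, j + 1, k + 1])
            v01 = int(fp_idx[nx_fp, j, k + 1])
            # outward normal +x
            footplate_faces.append((v00, v10, v11))
            footplate_faces.append((v00, v11, v01))
    footplate_nodes = sorted(int(v) for v in fp_idx[nx_fp, :, :].ravel())

    # annular ligament: frame of elements around the plate, same x layers
    w_al = spec.annular_ring_width
    ys_al = _extend_line(ys_fp, -W2 - w_al, W2 + w_al, res)
    zs_al = _extend_line(zs_fp, -H2 - D - w_al, H2 - D + w_al, res)

    def _in_plate(y, z):
        return (-W2 - 1e-12 <= y <= W2 + 1e-12) and (
            -H2 - D - 1e-12 <= z <= H2 - D + 1e-12
        )

    def _al_region(i, j, k):
        yc = 0.5 * (ys_al[j] + ys_al[j + 1])
        zc = 0.5 * (zs_al[k] + zs_al[k + 1])
        return None if _in_plate(yc, zc) else "annular_ligament"

    al_idx = b.add_lattice(
        lambda i, j, k: (xs_fp[i], ys_al[j], zs_al[k]),
        (nx_fp, len(ys_al) - 1, len(zs_al) - 1),
        _al_region,
    )
    anchor_annular = set()
    for i in range(nx_fp + 1):
        anchor_annular.update(int(v) for v in al_idx[i, 0, :])
        anchor_annular.update(int(v) for v in al_idx[i, -1, :])
        anchor_annular.update(int(v) for v in al_idx[i, :, 0])
        anchor_annular.update(int(v) for v in al_idx[i, :, -1])

    # -- ligaments / tendons ---------------------------------------------
    def _lig_side_cells(radius: float) -> int:
        side = radius * math.sqrt(math.pi)
        return max(1, round(side / res))

    def _attach_lines(
        xs: np.ndarray, slices: dict, seg: str, width_cells: int, field_name: str
    ) -> np.ndarray:
        sl = slices[seg]
        seg_n = sl.stop - sl.start
        if seg_n < width_cells + 2:
            raise GeometryParameterError(
                f"{field_name}: segment '{seg}' has too few axial cells "
                f"({seg_n}) to attach a {width_cells}-cell ligament"
            )
        i0 = sl.start + max(1, (seg_n - width_cells) // 2)
        return xs[i0 : i0 + width_cells + 1]

    def _add_ligament(
        name: str,
        xs: np.ndarray,
        slices: dict,
        seg: str,
        sign: int,
        z_surface: float,
        radius: float,
        length: float,
    ):
        """Square-section prism from the bone surface along +/- z."""
        wc = _lig_side_cells(radius)
        xs_l = _attach_lines(xs, slices, seg, wc, f"{name}_radius")
        j0 = max(0, (n_in - wc) // 2)
        ys_l = ys_chain[j0 : j0 + wc + 1]
        nz = _ncells(length, res)
        if sign > 0:
            zs_l = np.linspace(z_surface, z_surface + length, nz + 1)
        else:
            zs_l = np.linspace(z_surface - length, z_surface, nz + 1)
        lat = b.add_lattice(
            lambda i, j, k: (xs_l[i], ys_l[j], zs_l[k]),
            (len(xs_l) - 1, wc, nz),
            name,
        )
        far = lat[:, :, -1] if sign > 0 else lat[:, :, 0]
        return sorted(int(v) for v in far.ravel())

    anchors = {
        "anchor_aml": _add_ligament(
            "aml", xs_chain, seg_slices, "malleus", +1, a, spec.aml_radius, spec.aml_length
        ),
        "anchor_pil": _add_ligament(
            "pil", xs_chain, seg_slices, "incus", +1, a, spec.pil_radius, spec.pil_length
        ),
        "anchor_tensor_tympani": _add_ligament(
            "tensor_tympani",
            xs_chain,
            seg_slices,
            "malleus",
            -1,
            -a,
            spec.tensor_tympani_radius,
            spec.tensor_tympani_length,
        ),
        "anchor_stapedius": _add_ligament(
            "stapedius",
            xs_low,
            low_slices,
            "stapes",
            -1,
            -a - D,
            spec.stapedius_radius,
            spec.stapedius_length,
        ),
    }

    # -- attic patches (superior bone surfaces nearest the IM joint) -----
    def _attic_patch(seg: str, where: str) -> list[int]:
        # malleus: patch at the head (adjacent to the IM joint); incus:
        # patch over the body (bone centre). The patch covers
        # ``attic_patch_fraction`` of the superior surface length.
        sl = seg_slices[seg]
        x_lo, x_hi = xs_chain[sl.start], xs_chain[sl.stop]
        frac = spec.attic_patch_fraction
        span = x_hi - x_lo
        if where == "end":
            lo, hi = x_hi - frac * span, x_hi
        else:  # centred
            mid = 0.5 * (x_lo + x_hi)
            lo, hi = mid - 0.5 * frac * span, mid + 0.5 * frac * span
        sel = (xs_chain >= lo - 1e-12) & (xs_chain <= hi + 1e-12)
        nodes = chain_idx[sel, :, n_in]  # top surface z = +a
        return sorted(int(v) for v in nodes.ravel())

    mesh = b.finish()
    mesh.node_sets = {
        "tm_rim": np.asarray(sorted(tm_rim), dtype=np.int64),
        "footplate_nodes": np.asarray(footplate_nodes, dtype=np.int64),
        "attic_patch_malleus": np.asarray(_attic_patch("malleus", "end"), dtype=np.int64),
        "attic_patch_incus": np.asarray(_attic_patch("incus", "center"), dtype=np.int64),
    }
    for name, nodes in anchors.items():
        mesh.node_sets[name] = np.asarray(nodes, dtype=np.int64)
    mesh.node_sets["anchor_annular"] = np.asarray(sorted(anchor_annular), dtype=np.int64)
    mesh.face_sets = {
        "tm_load_faces": np.asarray(tm_load, dtype=np.int64),
        "footplate_faces": np.asarray(footplate_faces, dtype=np.int64),
    }
    return mesh


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _region_edge_connected(mesh: Mesh, label: str) -> bool:
    elems = mesh.elements_of(label)
    if elems.size == 0:
        return False
    parent = {int(e): int(e) for e in elems}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edge_owner: dict[tuple[int, int], int] = {}
    pairs = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
    for e in elems:
        tet = mesh.tetrahedra[e]
        for i, j in pairs:
            key = (int(min(tet[i], tet[j])), int(max(tet[i], tet[j])))
            owner = edge_owner.get(key)
            if owner is None:
                edge_owner[key] = int(e)
            else:
                ra, rb = find(owner), find(int(e))
                if ra != rb:
                    parent[rb] = ra
    roots = {find(int(e)) for e in elems}
    return len(roots) == 1


def validate_mesh(mesh: Mesh) -> list[str]:
    """Return a report of violated mesh invariants (empty when valid)."""
    report: list[str] = []
    vols = mesh.volumes()
    n_neg = int((vols <= 0).sum())
    if n_neg:
        report.append(f"negative-volume: {n_neg} tetrahedra have non-positive signed volume")

    present = set(mesh.region.tolist())
    for label in REGIONS:
        if label not in present:
            report.append(f"missing-region: '{label}' has no elements")
        elif not _region_edge_connected(mesh, label):
            report.append(f"region-connectivity: region '{label}' is not edge-connected")

    total = float(np.abs(vols).sum())
    per_region = sum(float(np.abs(vols)[mesh.region == r].sum()) for r in present)
    if not math.isclose(total, per_region, rel_tol=1e-12):
        report.append("volume-partition: region volumes do not sum to the total volume")

    n = mesh.n_nodes
    for name, nodes in mesh.node_sets.items():
        if nodes.size and (nodes.min() < 0 or nodes.max() >= n):
            report.append(f"set-reference: node set '{name}' references missing nodes")
    for name, faces in mesh.face_sets.items():
        if faces.size and (faces.min() < 0 or faces.max() >= n):
            report.append(f"set-reference: face set '{name}' references missing nodes")

    # chain connectivity: consecutive regions must share nodes
    region_nodes = {
        label: set(mesh.tetrahedra[mesh.region == label].ravel().tolist())
        for label in present
    }
    for r1, r2 in zip(CHAIN_REGIONS[:-1], CHAIN_REGIONS[1:]):
        if r1 not in region_nodes or r2 not in region_nodes:
            report.append(f"chain-connectivity: link '{r1}' -> '{r2}' is broken")
        elif not (region_nodes[r1] & region_nodes[r2]):
            report.append(f"chain-connectivity: '{r1}' and '{r2}' share no nodes")

    # face sets must sit on the right regions
    def _faces_on(label: str, faces: np.ndarray, set_name: str):
        if label not in region_nodes or faces.size == 0:
            return
        nodes = region_nodes[label]
        for tri in faces:
            if not all(int(v) in nodes for v in tri):
                report.append(
                    f"set-consistency: a face in '{set_name}' is not on region '{label}'"
                )
                return

    _faces_on("tm", mesh.face_sets.get("tm_load_faces", np.empty((0, 3), int)), "tm_load_faces")
    _faces_on(
        "stapes",
        mesh.face_sets.get("footplate_faces", np.empty((0, 3), int)),
        "footplate_faces",
    )

    # eardrum must carry at least two element layers through its thickness:
    # the flat apex plateau (x in (-t, 0)) must have >= 3 node planes in x
    if "tm" in present:
        tm_nodes = np.unique(mesh.tetrahedra[mesh.region == "tm"].ravel())
        xyz = mesh.node_coordinates[tm_nodes]
        apex = xyz[:, 0] >= xyz[:, 0].max() - 1e-12  # topmost plane
        if apex.any():
            r_apex = np.maximum(np.abs(xyz[:, 1]), np.abs(xyz[:, 2]))
            a_est = r_apex[apex].max()
            plateau = r_apex <= a_est + 1e-12
            planes = np.unique(np.round(xyz[plateau, 0], 12))
            if planes.size < 3:
                report.append(
                    "tm-layers: fewer than two element layers through the eardrum"
                )

    return report


# ---------------------------------------------------------------------------
# VTK export (legacy ASCII unstructured grid)
# ---------------------------------------------------------------------------


def write_vtk(mesh: Mesh, path) -> None:
    """Write the mesh as a legacy-ASCII VTK unstructured grid.

    Region labels are exported as an integer cell array; every named
    node set becomes a 0/1 point mask so sets can be inspected in any
    VTK viewer.
    """
    labels = sorted(set(mesh.region.tolist()))
    label_id = {r: i for i, r in enumerate(labels)}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"otomech middle-ear mesh; regions: {' '.join(labels)}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y, z in mesh.node_coordinates:
            fh.write(f"{x:.9e} {y:.9e} {z:.9e}\n")
        ne = mesh.n_elements
        fh.write(f"CELLS {ne} {5 * ne}\n")
        for tet in mesh.tetrahedra:
            fh.write(f"4 {tet[0]} {tet[1]} {tet[2]} {tet[3]}\n")
        fh.write(f"CELL_TYPES {ne}\n")
        fh.write("\n".join(["10"] * ne) + "\n")
        fh.write(f"CELL_DATA {ne}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(label_id[r]) for r in mesh.region) + "\n")
        if mesh.node_sets:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, nodes in mesh.node_sets.items():
                mask = np.zeros(mesh.n_nodes, dtype=int)
                mask[nodes] = 1
                fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(map(str, mask.tolist())) + "\n")
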