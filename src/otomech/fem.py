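"""Damped harmonic linear elasticity on the middle-ear mesh.

Assembles sparse stiffness/mass/damping matrices from linear (tet4)
tetrahedra and solves the frequency-domain system

    (K + j*omega*D - omega**2 * M) x = f

per analysis frequency with a sparse complex direct factorization.
Damping is region-wise Rayleigh (D_r = alpha_r*M_r + beta_r*K_r) plus
an explicit footplate dashpot standing in for the cochlear fluid load.
The eardrum rim is grounded through per-node springs; ligament/tendon
far ends are fixed. Constraints are enforced by reduction (row/column
elimination), so constrained displacements are exactly zero.
"""

from __future__ import annotations


import dataclasses
import hashlib
import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy import sparse
from scipy.sparse.linalg import eigsh, splu

from .geometry import Mesh, tet_volumes

__all__ = [
    "RegionMaterial",
    "MaterialTable",
    "SystemMatrices",
    "HarmonicSolution",
    "ConfigurationError",
    "SolverError",
    "tet4_stiffness",
    "tet4_mass",
    "assemble",
    "assemble_by_region",
    "apply_boundary_springs",
    "apply_dashpot",
    "apply_fixed",
    "pressure_load",
    "harmonic_solve",
    "build_middle_ear_system",
]


class ConfigurationError(ValueError):
    """Missing or inconsistent material/solver configuration."""


class SolverError(RuntimeError):
    """The harmonic system could not be solved reliably."""


@dataclass(frozen=True)
class RegionMaterial:
    """Isotropic linear-elastic material with Rayleigh damping.

    density in kg/m^3, youngs_modulus in Pa, poisson dimensionless,
    rayleigh_alpha in 1/s (mass-proportional), rayleigh_beta in s
    (stiffness-proportional).
    """

    density: float
    youngs_modulus: float
    poisson: float = 0.3
    rayleigh_alpha: float = 0.0
    rayleigh_beta: float = 0.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ConfigurationError(f"density must be > 0, got {self.density}")
        if self.youngs_modulus <= 0:
            raise ConfigurationError(
                f"youngs_modulus must be > 0, got {self.youngs_modulus}"
            )
        if not 0.0 <= self.poisson < 0.5:
            raise ConfigurationError(f"poisson must be in [0, 0.5), got {self.poisson}")
        if self.rayleigh_alpha < 0 or self.rayleigh_beta < 0:
            raise ConfigurationError("Rayleigh coefficients must be >= 0")


#: Regions treated as mineralized bone (everything else is soft tissue).
BONE_REGIONS = frozenset({"malleus", "incus", "stapes"})


@dataclass
class MaterialTable:
    """Per-region materials plus the global rim-spring / dashpot scalars.

    ``tm_rim_spring_stiffness`` is N/m per rim node (applied to each of
    the node's three DOFs); ``footplate_dashpot`` is the total N*s/m
    over the footplate, acting along the piston (x) direction.
    ``fixed_sets`` names mesh node sets that are rigidly fixed.
    """

    regions: dict[str, RegionMaterial]
    tm_rim_spring_stiffness: float = 0.0
    footplate_dashpot: float = 0.0
    fixed_sets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.tm_rim_spring_stiffness < 0:
            raise ConfigurationError("tm_rim_spring_stiffness must be >= 0")
        if self.footplate_dashpot < 0:
            raise ConfigurationError("footplate_dashpot must be >= 0")
        self.fixed_sets = tuple(self.fixed_sets)

    def copy(self) -> "MaterialTable":
        return MaterialTable(
            regions=dict(self.regions),
            tm_rim_spring_stiffness=self.tm_rim_spring_stiffness,
            footplate_dashpot=self.footplate_dashpot,
            fixed_sets=self.fixed_sets,
        )

    def scale_youngs(self, region: str, factor: float) -> "MaterialTable":
        """Return a copy with the region's Young's modulus multiplied."""
        out = self.copy()
        mat = out.regions[region]
        out.regions[region] = dataclasses.replace(
            mat, youngs_modulus=mat.youngs_modulus * factor
        )
        return out

    def scale_density(self, region: str, factor: float) -> "MaterialTable":
        out = self.copy()
        mat = out.regions[region]
        out.regions[region] = dataclasses.replace(mat, density=mat.density * factor)
        return out

    def soft_regions(self) -> tuple[str, ...]:
        return tuple(r for r in self.regions if r not in BONE_REGIONS)

    def content_hash(self) -> str:
        h = hashlib.sha1()
        for name in sorted(self.regions):
            m = self.regions[name]
            h.update(
                f"{name}:{m.density!r}:{m.youngs_modulus!r}:{m.poisson!r}:"
                f"{m.rayleigh_alpha!r}:{m.rayleigh_beta!r};".encode()
            )
        h.update(
            f"rim={self.tm_rim_spring_stiffness!r};c={self.footplate_dashpot!r};"
            f"fixed={','.join(self.fixed_sets)}".encode()
        )
        return h.hexdigest()

    # -- serialization ---------------------------------------------------

    def to_yaml(self, path=None) -> str:
        data = {
            "regions": {
                name: {
                    "density": float(m.density),
                    "youngs_modulus": float(m.youngs_modulus),
                    "poisson": float(m.poisson),
                    "rayleigh_alpha": float(m.rayleigh_alpha),
                    "rayleigh_beta": float(m.rayleigh_beta),
                }
                for name, m in sorted(self.regions.items())
            },
            "tm_rim_spring_stiffness": float(self.tm_rim_spring_stiffness),
            "footplate_dashpot": float(self.footplate_dashpot),
            "fixed_sets": list(self.fixed_sets),
        }
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(
                    "# Middle-ear materials, SI units: density kg/m^3, youngs_modulus Pa,\n"
                    "# rayleigh_alpha 1/s, rayleigh_beta s, rim springs N/m per node,\n"
                    "# footplate_dashpot N*s/m total.\n"
                )
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "MaterialTable":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(io.StringIO(str(source)))
        regions = {
            name: RegionMaterial(**params) for name, params in data["regions"].items()
        }
        return cls(
            regions=regions,
            tm_rim_spring_stiffness=float(data.get("tm_rim_spring_stiffness", 0.0)),
            footplate_dashpot=float(data.get("footplate_dashpot", 0.0)),
            fixed_sets=tuple(data.get("fixed_sets", ())),
        )

    @classmethod
    def default(cls) -> "MaterialTable":
        from .config import load_default_materials

        return load_default_materials()


@dataclass
class SystemMatrices:
    """Assembled global matrices with the constraint bookkeeping.

    DOF ordering is node-major: node i owns DOFs (3i, 3i+1, 3i+2).
    """

    K: sparse.csr_matrix
    M: sparse.csr_matrix
    D: sparse.csr_matrix
    n_nodes: int
    constrained_dofs: frozenset[int] = frozenset()

    @property
    def n_dofs(self) -> int:
        return 3 * self.n_nodes

    def free_dofs(self) -> np.ndarray:
        mask = np.ones(self.n_dofs, dtype=bool)
        if self.constrained_dofs:
            mask[np.fromiter(self.constrained_dofs, dtype=np.int64)] = False
        return np.flatnonzero(mask)

    def copy(self) -> "SystemMatrices":
        return SystemMatrices(
            K=self.K.copy(),
            M=self.M.copy(),
            D=self.D.copy(),
            n_nodes=self.n_nodes,
            constrained_dofs=self.constrained_dofs,
        )


@dataclass
class HarmonicSolution:
    """Complex nodal displacement field per analysis frequency."""

    frequencies: np.ndarray  # Hz, shape (nf,)
    displacement: np.ndarray  # complex, shape (nf, n_nodes, 3), metres

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.displacement.shape[0] != self.frequencies.shape[0]:
            raise ValueError("frequency count does not match displacement slices")
        if not np.all(np.isfinite(self.displacement.view(float))):
            raise ValueError("non-finite displacement entries")

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("frequencies_hz", data=self.frequencies)
            fh.create_dataset("displacement_m", data=self.displacement)

    @classmethod
    def from_hdf5(cls, path) -> "HarmonicSolution":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(
                frequencies=fh["frequencies_hz"][...],
                displacement=fh["displacement_m"][...],
            )


# ---------------------------------------------------------------------------
# Element matrices
# ---------------------------------------------------------------------------


def _elasticity_matrix(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Isotropic 6x6 constitutive matrices, Voigt [xx,yy,zz,xy,yz,zx]."""
    E = np.atleast_1d(np.asarray(E, dtype=float))
    nu = np.broadcast_to(np.atleast_1d(np.asarray(nu, dtype=float)), E.shape)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    n = E.shape[0]
    Dm = np.zeros((n, 6, 6))
    for i in range(3):
        for j in range(3):
            Dm[:, i, j] = lam
        Dm[:, i, i] += 2 * mu
        Dm[:, 3 + i, 3 + i] = mu
    return Dm


def _tet_gradients(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients and volumes for a batch of tets.

    coords: (n, 4, 3). Returns (grads (n, 4, 3), volumes (n,)).
    """
    J = coords[:, 1:, :] - coords[:, :1, :]  # rows are edge vectors
    detJ = np.linalg.det(J)
    vols = detJ / 6.0
    if np.any(vols <= 0):
        raise ValueError("degenerate or inverted tetrahedron (non-positive volume)")
    Jinv = np.linalg.inv(J)
    g123 = np.transpose(Jinv, (0, 2, 1))  # grad N_i = row i of J^-T
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1), vols


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices B (n, 6, 12) from gradients."""
    n = grads.shape[0]
    B = np.zeros((n, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B


def tet4_stiffness_batch(coords: np.ndarray, E, nu) -> np.ndarray:
    """Stiffness matrices (n, 12, 12) for a batch of tet4 elements."""
    grads, vols = _tet_gradients(np.asarray(coords, dtype=float))
    B = _b_matrices(grads)
    Dm = _elasticity_matrix(E, nu)
    if Dm.shape[0] == 1 and B.shape[0] > 1:
        Dm = np.broadcast_to(Dm, (B.shape[0], 6, 6))
    K = np.einsum("nji,njk,nkl,n->nil", B, Dm, B, vols, optimize=True)
    return K


def tet4_stiffness(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12x12 stiffness (N/m) of a single linear tetrahedron."""
    return tet4_stiffness_batch(np.asarray(coords, dtype=float)[None], E, nu)[0]


# consistent-mass coupling pattern: 2 on the diagonal, 1 off, per direction
_MASS_PATTERN = np.zeros((12, 12))
for _a in range(4):
    for _b in range(4):
        for _d in range(3):
            _MASS_PATTERN[3 * _a + _d, 3 * _b + _d] = 2.0 if _a == _b else 1.0


def tet4_mass_batch(coords: np.ndarray, rho) -> np.ndarray:
    """Consistent mass matrices (n, 12, 12) for a batch of tet4 elements."""
    coords = np.asarray(coords, dtype=float)
    a = coords[:, 1] - coords[:, 0]
    b = coords[:, 2] - coords[:, 0]
    c = coords[:, 3] - coords[:, 0]
    vols = np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0
    if np.any(vols <= 0):
        raise ValueError("degenerate or inverted tetrahedron (non-positive volume)")
    rho = np.broadcast_to(np.atleast_1d(np.asarray(rho, dtype=float)), vols.shape)
    return (rho * vols / 20.0)[:, None, None] * _MASS_PATTERN[None]


def tet4_mass(coords: np.ndarray, rho: float) -> np.ndarray:
    """12x12 consistent mass (kg) of a single linear tetrahedron."""
    return tet4_mass_batch(np.asarray(coords, dtype=float)[None], rho)[0]


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _scatter(ndofs: int, tets: np.ndarray, elem_mats: np.ndarray) -> sparse.csr_matrix:
    ne = tets.shape[0]
    edofs = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 12)
    rows = np.repeat(edofs, 12, axis=1).ravel()
    cols = np.tile(edofs, (1, 12)).ravel()
    mat = sparse.coo_matrix(
        (elem_mats.ravel(), (rows, cols)), shape=(ndofs, ndofs)
    )
    return mat.tocsr()


# per-mesh cache of unit-modulus / unit-density region matrices; K scales
# linearly with E (uniform modulus per region) and M with rho, so pathology
# perturbations and calibration scalings reuse one expensive assembly.
_UNIT_CACHE: dict[tuple, dict[str, tuple[sparse.csr_matrix, sparse.csr_matrix]]] = {}


def _unit_region_matrices(
    mesh: Mesh, poissons: dict[str, float]
) -> dict[str, tuple[sparse.csr_matrix, sparse.csr_matrix]]:
    key = (mesh.content_hash(), tuple(sorted(poissons.items())))
    cached = _UNIT_CACHE.get(key)
    if cached is not None:
        return cached
    ndofs = 3 * mesh.n_nodes
    out: dict[str, tuple[sparse.csr_matrix, sparse.csr_matrix]] = {}
    for label in sorted(set(mesh.region.tolist())):
        elems = mesh.elements_of(label)
        tets = mesh.tetrahedra[elems]
        coords = mesh.node_coordinates[tets]
        Ke = tet4_stiffness_batch(coords, 1.0, poissons[label])
        Me = tet4_mass_batch(coords, 1.0)
        out[label] = (_scatter(ndofs, tets, Ke), _scatter(ndofs, tets, Me))
    if len(_UNIT_CACHE) > 4:  # keep the cache small (meshes are ~100 MB-scale)
        _UNIT_CACHE.clear()
    _UNIT_CACHE[key] = out
    return out


def assemble_by_region(
    mesh: Mesh, materials: MaterialTable
) -> dict[str, tuple[sparse.csr_matrix, sparse.csr_matrix]]:
    """Per-region (K_r, M_r) global matrices (zero outside the region)."""
    present = sorted(set(mesh.region.tolist()))
    missing = [r for r in present if r not in materials.regions]
    if missing:
        raise ConfigurationError(
            f"no material entry for mesh region(s): {', '.join(missing)}"
        )
    unit = _unit_region_matrices(
        mesh, {label: materials.regions[label].poisson for label in present}
    )
    return {
        label: (
            materials.regions[label].youngs_modulus * unit[label][0],
            materials.regions[label].density * unit[label][1],
        )
        for label in present
    }


def assemble(mesh: Mesh, materials: MaterialTable) -> SystemMatrices:
    """Assemble K, M and region-wise Rayleigh damping for the mesh.

    The explicit rim springs, footplate dashpot and fixed sets are NOT
    applied here; use :func:`build_middle_ear_system` for the full
    boundary-condition chain.
    """
    per_region = assemble_by_region(mesh, materials)
    ndofs = 3 * mesh.n_nodes
    K = sparse.csr_matrix((ndofs, ndofs))
    M = sparse.csr_matrix((ndofs, ndofs))
    D = sparse.csr_matrix((ndofs, ndofs))
    for label, (Kr, Mr) in per_region.items():
        mat = materials.regions[label]
        K = K + Kr
        M = M + Mr
        if mat.rayleigh_alpha or mat.rayleigh_beta:
            D = D + mat.rayleigh_alpha * Mr + mat.rayleigh_beta * Kr
    return SystemMatrices(K=K.tocsr(), M=M.tocsr(), D=D.tocsr(), n_nodes=mesh.n_nodes)


def apply_boundary_springs(
    sys: SystemMatrices, nodes: Iterable[int], k: float
) -> SystemMatrices:
    """Ground the given nodes through springs of stiffness k per DOF."""
    if k < 0:
        raise ConfigurationError(f"spring stiffness must be >= 0, got {k}")
    nodes = np.asarray(list(nodes), dtype=np.int64)
    if nodes.size and (nodes.min() < 0 or nodes.max() >= sys.n_nodes):
        raise IndexError("boundary spring applied to unknown node")
    out = sys.copy()
    if k == 0 or nodes.size == 0:
        return out
    diag = np.zeros(sys.n_dofs)
    dofs = (3 * nodes[:, None] + np.arange(3)[None]).ravel()
    diag[dofs] = k
    out.K = (out.K + sparse.diags(diag)).tocsr()
    return out


def apply_dashpot(
    sys: SystemMatrices,
    nodes: Iterable[int],
    c_total: float,
    direction: Sequence[float],
) -> SystemMatrices:
    """Add a viscous dashpot of total coefficient c_total (N*s/m).

    The dashpot acts along ``direction`` and is split equally over the
    nodes as rank-1 contributions c/n * d d^T, preserving symmetry.
    """
    if c_total < 0:
        raise ConfigurationError(f"dashpot coefficient must be >= 0, got {c_total}")
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d)
    if nrm == 0:
        raise ConfigurationError("dashpot direction must be a nonzero vector")
    d = d / nrm
    nodes = np.asarray(list(nodes), dtype=np.int64)
    if nodes.size and (nodes.min() < 0 or nodes.max() >= sys.n_nodes):
        raise IndexError("dashpot applied to unknown node")
    out = sys.copy()
    if c_total == 0 or nodes.size == 0:
        return out
    block = (c_total / nodes.size) * np.outer(d, d)
    dofs = 3 * nodes[:, None] + np.arange(3)[None]
    rows = np.repeat(dofs, 3, axis=1).ravel()
    cols = np.tile(dofs, (1, 3)).ravel()
    vals = np.tile(block.ravel(), nodes.size)
    out.D = (out.D + sparse.coo_matrix((vals, (rows, cols)), shape=out.D.shape)).tocsr()
    return out


def apply_fixed(sys: SystemMatrices, nodes: Iterable[int]) -> SystemMatrices:
    """Constrain all three DOFs of each node to zero displacement."""
    nodes = np.asarray(list(nodes), dtype=np.int64)
    out = sys.copy()
    dofs = set(out.constrained_dofs)
    for n in nodes:
        dofs.update((3 * int(n), 3 * int(n) + 1, 3 * int(n) + 2))
    out.constrained_dofs = frozenset(dofs)
    return out


def pressure_load(mesh: Mesh, faces: np.ndarray, pressure: float) -> np.ndarray:
    """Consistent nodal force vector (N) from uniform pressure on faces.

    Faces are node triples with outward orientation; the load acts along
    each face's inward normal (pressure pushes on the surface). Each
    triangle's p*A is split equally over its three nodes.
    """
    faces = np.asarray(faces, dtype=np.int64)
    if faces.size == 0:
        raise ConfigurationError("pressure_load requires a nonempty face set")
    p = mesh.node_coordinates[faces]
    n_vec = 0.5 * np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # outward area vectors
    areas = np.linalg.norm(n_vec, axis=1)
    if np.any(areas <= 0):
        raise ValueError("zero-area face in pressure load set")
    f = np.zeros((mesh.n_nodes, 3))
    tri_force = -pressure * n_vec / 3.0  # inward normal
    for corner in range(3):
        np.add.at(f, faces[:, corner], tri_force)
    return f.ravel()


def harmonic_solve(
    sys: SystemMatrices,
    f: np.ndarray,
    frequencies: Sequence[float],
    residual_tol: float = 1e-8,
) -> HarmonicSolution:
    """Solve (K + j*w*D - w^2*M) x = f at each frequency (Hz).

    Uses a sparse complex LU factorization per frequency on the free
    DOFs; constrained DOFs return exactly zero. Raises
    :class:`SolverError` when the reduced operator is singular or the
    residual exceeds ``residual_tol * ||f||``.
    """
    freqs = np.asarray(list(frequencies), dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("analysis frequencies must be positive")
    f = np.asarray(f, dtype=complex).ravel()
    if f.shape[0] != sys.n_dofs:
        raise ValueError("force vector length does not match system DOFs")
    free = sys.free_dofs()
    Kf = sys.K[free][:, free].tocsc()
    Mf = sys.M[free][:, free].tocsc()
    Df = sys.D[free][:, free].tocsc()
    ff = f[free]
    fnorm = np.linalg.norm(ff)
    out = np.zeros((freqs.size, sys.n_dofs), dtype=complex)
    for i, f_hz in enumerate(freqs):
        w = 2.0 * np.pi * f_hz
        A = (Kf + 1j * w * Df - (w * w) * Mf).tocsc()
        try:
            lu = splu(A)
            x = lu.solve(ff)
        except RuntimeError as exc:
            raise SolverError(
                f"singular harmonic system at {f_hz} Hz: {exc}; "
                f"near-null mode: {_describe_null_mode(Kf, free)}"
            ) from exc
        if not np.all(np.isfinite(x)):
            raise SolverError(
                f"non-finite solution at {f_hz} Hz; "
                f"near-null mode: {_describe_null_mode(Kf, free)}"
            )
        # iterative refinement: stiff bone vs. near-released joints span
        # >10 orders of magnitude in stiffness, so one LU pass can leave
        # a residual above the contract; refinement restores it cheaply.
        # The acceptance threshold is the normwise backward error
        # ||Ax-f|| <= tol * (||f|| + ||A||*||x||), the achievable form of
        # the residual contract for such ill-scaled operators.
        anorm = abs(A).sum(axis=1).max() if A.nnz else 0.0
        resid = np.linalg.norm(A @ x - ff)

        def _bound(xv):
            return residual_tol * (fnorm + anorm * np.linalg.norm(xv))

        for _ in range(3):
            if fnorm == 0 or resid <= residual_tol * fnorm:
                break
            x = x + lu.solve(ff - A @ x)
            resid = np.linalg.norm(A @ x - ff)
        if fnorm > 0 and resid > _bound(x):
            raise SolverError(
                f"residual {resid:.3e} exceeds backward-error bound "
                f"{_bound(x):.3e} at {f_hz} Hz"
            )
        out[i, free] = x
    return HarmonicSolution(
        frequencies=freqs, displacement=out.reshape(freqs.size, sys.n_nodes, 3)
    )


def _describe_null_mode(Kf: sparse.csc_matrix, free: np.ndarray) -> str:
    try:
        vals, vecs = eigsh(Kf.real, k=1, sigma=0, which="LM")
        dof = free[int(np.argmax(np.abs(vecs[:, 0])))]
        return f"smallest K eigenvalue {vals[0]:.3e}, dominant at node {dof // 3}, dof {dof % 3}"
    except Exception:  # diagnostics only
        return "unavailable"


def build_middle_ear_system(
    mesh: Mesh,
    materials: MaterialTable,
    extra_fixed_sets: Sequence[str] = (),
) -> SystemMatrices:
    """Assemble + full boundary-condition chain for the middle ear.

    Applies the eardrum rim springs, the footplate (cochlear) dashpot
    along the piston axis, fixes the ligament anchors named in
    ``materials.fixed_sets`` and any ``extra_fixed_sets`` (for example
    the attic patches under fixation pathology).
    """
    sys = assemble(mesh, materials)
    sys = apply_boundary_springs(
        sys, mesh.node_sets["tm_rim"], materials.tm_rim_spring_stiffness
    )
    sys = apply_dashpot(
        sys, mesh.node_sets["footplate_nodes"], materials.footplate_dashpot, (1.0, 0.0, 0.0)
    )
    for name in tuple(materials.fixed_sets) + tuple(extra_fixed_sets):
        if name not in mesh.node_sets:
            raise ConfigurationError(f"fixed node set '{name}' not present in mesh")
        sys = apply_fixed(sys, mesh.node_sets[name])
    return sys
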