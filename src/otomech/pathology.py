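"""Ossicular-chain lesions as perturbations of the normal model.

Each pathology is a multiplicative perturbation of the normal middle
ear: otosclerosis stiffens the stapedial annular ligament (Young's
modulus x factor), incudostapedial-joint disease scales the joint
modulus up (post-surgical/inflammatory adhesion) or down (incomplete
traumatic or malformative discontinuity), attic fixation pins part of
the superior malleus/incus surface, and ossicular mass change scales
the malleus+incus density. A complete discontinuity (modulus -> 0)
cannot be represented because the model requires mechanical
transmission across the chain; a vanishing pathologic displacement is
reported as a +inf air-bone gap sentinel instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .audiogram import (
    Audiogram,
    CalibrationTable,
    FEM_FREQUENCIES_HZ,
    abg_from_displacement,
    eardrum_pressure,
    footplate_displacement,
)
from .fem import (
    ConfigurationError,
    MaterialTable,
    build_middle_ear_system,
    harmonic_solve,
    pressure_load,
)
from .geometry import Mesh

__all__ = ["Lesion", "PathologySpec", "apply_pathology", "simulate_abg", "LESION_KINDS"]

LESION_KINDS = (
    "annular_stiffen",
    "is_joint_scale",
    "attic_fix_malleus",
    "attic_fix_incus",
    "mass_scale_malleus_incus",
)

_ATTIC_SETS = {
    "attic_fix_malleus": "attic_patch_malleus",
    "attic_fix_incus": "attic_patch_incus",
}


@dataclass(frozen=True)
class Lesion:
    """A single lesion: a kind and a positive multiplier.

    The factor is ignored for the attic-fixation kinds (fixation is a
    kinematic constraint, not a scaling).
    """

    kind: str
    factor: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ConfigurationError(
                f"unknown lesion kind {self.kind!r}; expected one of {LESION_KINDS}"
            )
        if not self.factor > 0:
            raise ConfigurationError(f"lesion factor must be > 0, got {self.factor}")


@dataclass(frozen=True)
class PathologySpec:
    """A set of co-existing lesions (empty = normal ear)."""

    lesions: tuple[Lesion, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "lesions",
            tuple(
                l if isinstance(l, Lesion) else Lesion(*l) for l in self.lesions
            ),
        )
        kinds = [l.kind for l in self.lesions]
        if len(kinds) != len(set(kinds)):
            raise ConfigurationError("duplicate lesion kinds in pathology spec")

    @classmethod
    def of(cls, *pairs) -> "PathologySpec":
        return cls(tuple(Lesion(k, f) for k, f in pairs))

    def describe(self) -> str:
        if not self.lesions:
            return "normal"
        return "+".join(
            l.kind if l.kind in _ATTIC_SETS else f"{l.kind}x{l.factor:g}"
            for l in self.lesions
        )


def apply_pathology(
    mesh: Mesh, materials: MaterialTable, spec: PathologySpec
) -> tuple[MaterialTable, tuple[str, ...]]:
    """Perturbed materials and extra fixed node-set names for a spec."""
    out = materials.copy()
    extra_fixed: list[str] = []
    for lesion in spec.lesions:
        if lesion.kind == "annular_stiffen":
            out = out.scale_youngs("annular_ligament", lesion.factor)
        elif lesion.kind == "is_joint_scale":
            out = out.scale_youngs("is_joint", lesion.factor)
        elif lesion.kind == "mass_scale_malleus_incus":
            out = out.scale_density("malleus", lesion.factor)
            out = out.scale_density("incus", lesion.factor)
        else:  # attic fixation
            set_name = _ATTIC_SETS[lesion.kind]
            if set_name not in mesh.node_sets:
                raise ConfigurationError(f"mesh lacks node set {set_name!r}")
            extra_fixed.append(set_name)
    return out, tuple(extra_fixed)


# cache of normal-model footplate displacements keyed by
# (mesh hash, material hash, frequency grid, calibration id)
_NORMAL_CACHE: dict[tuple, np.ndarray] = {}


def _footplate_response(
    mesh: Mesh,
    materials: MaterialTable,
    extra_fixed: Sequence[str],
    cal: CalibrationTable,
    frequencies: Sequence[float],
) -> np.ndarray:
    """Footplate piston displacement under threshold drive per frequency."""
    sys = build_middle_ear_system(mesh, materials, extra_fixed_sets=extra_fixed)
    unit_f = pressure_load(mesh, mesh.face_sets["tm_load_faces"], 1.0)
    sol = harmonic_solve(sys, unit_f, frequencies)
    d = footplate_displacement(sol, mesh.face_sets["footplate_faces"], mesh)
    pressures = np.array([eardrum_pressure(f, cal) for f in frequencies])
    return d * pressures


def clear_normal_cache() -> None:
    _NORMAL_CACHE.clear()


def simulate_abg(
    mesh: Mesh,
    materials: MaterialTable,
    spec: PathologySpec,
    cal: CalibrationTable | None = None,
    frequencies: Sequence[float] = FEM_FREQUENCIES_HZ,
) -> Audiogram:
    """Simulated air-bone-gap audiogram for a pathology spec.

    Runs the full chain (assemble, boundary conditions, threshold
    pressure load, harmonic solve) for both the normal and the
    perturbed model and converts the footplate displacement ratio to
    decibels. The normal solution is cached across calls for a given
    mesh/material/grid combination.
    """
    cal = cal or CalibrationTable.default()
    freqs = tuple(float(f) for f in frequencies)
    key = (mesh.content_hash(), materials.content_hash(), freqs, id(type(cal)), cal.frequencies_hz, cal.retspl_db_spl, cal.ear_canal_gain_db)
    d_normal = _NORMAL_CACHE.get(key)
    if d_normal is None:
        d_normal = _footplate_response(mesh, materials, (), cal, freqs)
        _NORMAL_CACHE[key] = d_normal
    if not spec.lesions:
        d_path = d_normal
    else:
        mats_p, extra_fixed = apply_pathology(mesh, materials, spec)
        d_path = _footplate_response(mesh, mats_p, extra_fixed, cal, freqs)
    return abg_from_displacement(d_normal, d_path, freqs)
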