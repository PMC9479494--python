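"""Audiogram types and the displacement-to-air-bone-gap conversion.

The simulated audiogram mimics pure-tone audiometry: for each test
frequency the eardrum is driven at the pressure corresponding to the
normal hearing threshold (RETSPL of the audiometer plus the ear-canal
gain), and the hearing level of a pathologic ear is the decibel ratio
of normal to pathologic stapes-footplate displacement,

    ABG(f) = 20 log10(|d_normal(f)| / |d_pathologic(f)|),

which corresponds to the air-bone gap of a purely conductive lesion.
Because the model is linear, the ABG is independent of the absolute
drive level; the calibration table only sets absolute displacements.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .fem import ConfigurationError, HarmonicSolution
from .geometry import Mesh

__all__ = [
    "FEM_FREQUENCIES_HZ",
    "CLINICAL_FREQUENCIES_HZ",
    "CalibrationTable",
    "Audiogram",
    "eardrum_pressure",
    "footplate_displacement",
    "abg_from_displacement",
]

#: Analysis grid for simulated audiograms (clinical five + intermediates).
FEM_FREQUENCIES_HZ = (250.0, 500.0, 750.0, 1000.0, 1500.0, 2000.0, 3000.0, 4000.0)

#: The five frequencies at which the clinical ABG is measured.
CLINICAL_FREQUENCIES_HZ = (250.0, 500.0, 1000.0, 2000.0, 4000.0)

#: Sentinel for a complete transmission block (zero pathologic motion).
ABG_BLOCKED = math.inf


@dataclass(frozen=True)
class CalibrationTable:
    """Per-frequency RETSPL and ear-canal gain, plus p0 = 20 uPa."""

    frequencies_hz: tuple[float, ...]
    retspl_db_spl: tuple[float, ...]
    ear_canal_gain_db: tuple[float, ...]
    reference_pressure_pa: float = 20e-6

    def __post_init__(self) -> None:
        n = len(self.frequencies_hz)
        if len(self.retspl_db_spl) != n or len(self.ear_canal_gain_db) != n:
            raise ConfigurationError("calibration table columns have unequal lengths")
        if not all(map(math.isfinite, self.retspl_db_spl + self.ear_canal_gain_db)):
            raise ConfigurationError("calibration table contains non-finite values")

    def _index(self, freq: float) -> int:
        for i, f in enumerate(self.frequencies_hz):
            if math.isclose(f, freq, rel_tol=1e-9):
                return i
        raise ConfigurationError(f"frequency {freq} Hz missing from calibration table")

    def retspl(self, freq: float) -> float:
        return self.retspl_db_spl[self._index(freq)]

    def gain(self, freq: float) -> float:
        return self.ear_canal_gain_db[self._index(freq)]

    @classmethod
    def from_yaml(cls, source) -> "CalibrationTable":
        data = yaml.safe_load(source.read() if hasattr(source, "read") else open(source).read())
        return cls(
            frequencies_hz=tuple(float(f) for f in data["frequencies_hz"]),
            retspl_db_spl=tuple(float(v) for v in data["retspl_db_spl"]),
            ear_canal_gain_db=tuple(float(v) for v in data["ear_canal_gain_db"]),
            reference_pressure_pa=float(data.get("reference_pressure_pa", 20e-6)),
        )

    @classmethod
    def default(cls) -> "CalibrationTable":
        from .config import load_default_calibration

        return load_default_calibration()


@dataclass
class Audiogram:
    """Per-frequency decibel values (simulated ABG or measured HL)."""

    frequencies: np.ndarray
    values: np.ndarray
    kind: str = "simulated_abg"  # simulated_abg | air_conduction | bone_conduction

    KINDS = ("simulated_abg", "air_conduction", "bone_conduction")

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown audiogram kind {self.kind!r}")
        if self.frequencies.shape != self.values.shape:
            raise ValueError("frequency/value length mismatch")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def at(self, freq: float) -> float:
        idx = np.flatnonzero(np.isclose(self.frequencies, freq))
        if idx.size == 0:
            raise KeyError(f"frequency {freq} Hz not in audiogram")
        return float(self.values[idx[0]])

    def restrict(self, freqs: Sequence[float]) -> "Audiogram":
        vals = [self.at(f) for f in freqs]
        return Audiogram(np.asarray(freqs, float), np.asarray(vals), kind=self.kind)

    def copy(self) -> "Audiogram":
        return Audiogram(self.frequencies.copy(), self.values.copy(), kind=self.kind)

    def mean_over(self, lo: float, hi: float) -> float:
        sel = (self.frequencies >= lo - 1e-9) & (self.frequencies <= hi + 1e-9)
        return float(self.values[sel].mean())

    # -- CSV round trip --------------------------------------------------

    def to_csv(self, path=None):
        df = pd.DataFrame(
            {
                "frequency_hz": self.frequencies,
                "value_db": self.values,
                "kind": self.kind,
            }
        )
        if path is None:
            return df.to_csv(index=False)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, source) -> "Audiogram":
        df = pd.read_csv(source)
        kinds = df["kind"].unique()
        if len(kinds) != 1:
            raise ValueError("audiogram CSV must contain a single kind")
        df = df.sort_values("frequency_hz")
        return cls(
            frequencies=df["frequency_hz"].to_numpy(float),
            values=df["value_db"].to_numpy(float),
            kind=str(kinds[0]),
        )


def eardrum_pressure(freq: float, cal: CalibrationTable) -> float:
    """Threshold (0 dB HL) sound pressure in Pa on the eardrum at ``freq``."""
    level_db = cal.retspl(freq) + cal.gain(freq)
    return cal.reference_pressure_pa * 10.0 ** (level_db / 20.0)


def footplate_displacement(
    sol: HarmonicSolution,
    footplate_faces: np.ndarray,
    node_coordinates: np.ndarray | Mesh,
) -> np.ndarray:
    """Piston-direction footplate displacement per frequency (complex, m).

    Area-weighted mean over the footplate faces of the displacement
    component along each face's outward normal; rigid tilt components
    average out, leaving the piston drive delivered to the cochlea.
    ``node_coordinates`` may be the coordinate array or the mesh itself.
    """
    faces = np.asarray(footplate_faces, dtype=np.int64)
    if faces.size == 0:
        raise ConfigurationError("footplate face set is empty")
    coords = (
        node_coordinates.node_coordinates
        if isinstance(node_coordinates, Mesh)
        else np.asarray(node_coordinates, dtype=float)
    )
    p = coords[faces]
    nvec = 0.5 * np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    areas = np.linalg.norm(nvec, axis=1)
    if np.any(areas <= 0):
        raise ValueError("zero-area footplate face")
    normals = nvec / areas[:, None]
    out = np.empty(sol.frequencies.size, dtype=complex)
    for i in range(sol.frequencies.size):
        disp = sol.displacement[i]
        node_n = np.einsum("fcj,fj->fc", disp[faces], normals)  # per-corner normal comps
        out[i] = complex((node_n.mean(axis=1) * areas).sum() / areas.sum())
    return out


def abg_from_displacement(
    d_normal: np.ndarray,
    d_pathologic: np.ndarray,
    frequencies: Sequence[float] = FEM_FREQUENCIES_HZ,
) -> Audiogram:
    """Air-bone gap audiogram from normal vs pathologic footplate motion."""
    d_normal = np.asarray(d_normal, dtype=complex)
    d_pathologic = np.asarray(d_pathologic, dtype=complex)
    freqs = np.asarray(list(frequencies), dtype=float)
    if d_normal.shape != d_pathologic.shape or d_normal.shape[0] != freqs.size:
        raise ValueError("displacement arrays must share the frequency grid")
    if np.any(d_normal == 0):
        raise ValueError("normal-model displacement must be nonzero")
    mag_p = np.abs(d_pathologic)
    values = np.full(freqs.size, ABG_BLOCKED)
    ok = mag_p > 0
    values[ok] = 20.0 * np.log10(np.abs(d_normal[ok]) / mag_p[ok])
    if not ok.all():
        warnings.warn(
            "zero pathologic displacement: complete transmission block, "
            "ABG reported as +inf",
            RuntimeWarning,
            stacklevel=2,
        )
    return Audiogram(freqs, values, kind="simulated_abg")
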