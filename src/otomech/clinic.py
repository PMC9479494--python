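"""Synthetic audiometric cohorts for exercising the analytics pipeline.

Real preoperative audiograms are not redistributable, so cohorts are
drawn from per-diagnosis templates that reproduce the published group
statistics: the mean air-bone gap and its between-patient standard
deviation per diagnosis, a Carhart notch in the otosclerosis
bone-conduction curve (raw means 25.0 / 35.2 / 26.3 dB HL at
1000 / 2000 / 4000 Hz), 5-dB threshold quantization, and the five
clinical frequencies. ABG curve *shapes* are taken from the
finite-element pathology scenarios (bundled, regenerable with
``otomech shapes``) and rescaled to the published group means, tying
the mechanical and clinical halves of the pipeline together.

Thresholds are modelled as independent Gaussians across frequencies
(the published data constrain only means and SDs); the correlation
structure is deliberately left out and documented as a limitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .audiogram import Audiogram, CLINICAL_FREQUENCIES_HZ

__all__ = [
    "CohortTemplate",
    "PatientRecord",
    "generate_cohort",
    "cohort_summary",
    "default_templates",
    "records_to_frame",
    "records_from_frame",
]

#: Published per-diagnosis mean +/- SD of the five-frequency average ABG.
GROUP_ABG_STATS = {
    "otosclerosis": (28.3, 11.4),
    "attic_fixation": (42.8, 11.2),
    "is_discontinuity_trauma": (24.6, 9.7),
    "is_discontinuity_malformation": (43.0, 9.74),
}

#: Raw otosclerosis bone-conduction means (dB HL) showing the Carhart notch.
OTOSCLEROSIS_BC_RAW = {250.0: 25.0, 500.0: 25.0, 1000.0: 25.0, 2000.0: 35.2, 4000.0: 26.3}

_THRESHOLD_FLOOR = -10.0
_THRESHOLD_CEIL = 120.0
_STEP = 5.0


@dataclass(frozen=True)
class CohortTemplate:
    """Statistical template for one diagnosis group.

    ``abg_curve`` and ``bc_curve`` are dB values on the five clinical
    frequencies; ``sd`` is the between-patient SD of the air-bone gap
    and ``sd_bc`` that of the bone-conduction threshold.
    """

    diagnosis: str
    abg_curve: tuple[float, ...]
    bc_curve: tuple[float, ...]
    sd: float
    sd_bc: float = 10.0
    frequencies: tuple[float, ...] = CLINICAL_FREQUENCIES_HZ

    def __post_init__(self) -> None:
        if self.sd < 0 or self.sd_bc < 0:
            raise ValueError("template SDs must be >= 0")
        if tuple(self.frequencies) != CLINICAL_FREQUENCIES_HZ:
            raise ValueError("templates are defined on the clinical 5-frequency grid")
        if len(self.abg_curve) != 5 or len(self.bc_curve) != 5:
            raise ValueError("curves must cover the five clinical frequencies")

    @property
    def mean_abg(self) -> float:
        return float(np.mean(self.abg_curve))


@dataclass(frozen=True)
class PatientRecord:
    """Synthetic patient: AC/BC thresholds (dB HL) and diagnosis label."""

    id: str
    diagnosis: str
    ac_db: tuple[float, ...]
    bc_db: tuple[float, ...]
    frequencies: tuple[float, ...] = CLINICAL_FREQUENCIES_HZ

    def air_conduction(self) -> Audiogram:
        return Audiogram(np.asarray(self.frequencies), np.asarray(self.ac_db), "air_conduction")

    def bone_conduction(self) -> Audiogram:
        return Audiogram(np.asarray(self.frequencies), np.asarray(self.bc_db), "bone_conduction")

    def abg(self, bc: Audiogram | None = None) -> Audiogram:
        """Air-bone gap, optionally against a corrected BC audiogram."""
        bc_vals = np.asarray(self.bc_db) if bc is None else bc.values
        return Audiogram(
            np.asarray(self.frequencies),
            np.asarray(self.ac_db) - bc_vals,
            "simulated_abg",
        )


def _quantize(x: np.ndarray) -> np.ndarray:
    return _STEP * np.round(x / _STEP)


def generate_cohort(
    template: CohortTemplate, n: int, seed: int
) -> list[PatientRecord]:
    """Draw ``n`` synthetic patients from a template, reproducibly.

    Per patient and frequency: BC = template BC + N(0, sd_bc);
    AC = BC + template ABG + N(0, sd); both clamped to [-10, 120] dB HL
    and quantized to 5-dB steps, with AC floored at BC so the recorded
    air-bone gap is never negative.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    abg = np.asarray(template.abg_curve)
    bc0 = np.asarray(template.bc_curve)
    records = []
    for i in range(n):
        bc = bc0 + rng.normal(0.0, template.sd_bc, size=5)
        ac = bc + abg + rng.normal(0.0, template.sd, size=5)
        bc = _quantize(np.clip(bc, _THRESHOLD_FLOOR, _THRESHOLD_CEIL))
        ac = _quantize(np.clip(ac, _THRESHOLD_FLOOR, _THRESHOLD_CEIL))
        ac = np.maximum(ac, bc)
        records.append(
            PatientRecord(
                id=f"{template.diagnosis}-{i:05d}",
                diagnosis=template.diagnosis,
                ac_db=tuple(ac.tolist()),
                bc_db=tuple(bc.tolist()),
            )
        )
    return records


def cohort_summary(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-diagnosis mean and SD of the per-patient average ABG.

    SD is the sample standard deviation (ddof=1); a single-patient
    group reports NaN, mirroring an undefined sample SD.
    """
    if not records:
        raise ValueError("cohort_summary requires at least one record")
    rows = [
        {
            "diagnosis": r.diagnosis,
            "mean_abg_db": float(np.mean(np.asarray(r.ac_db) - np.asarray(r.bc_db))),
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    out = df.groupby("diagnosis")["mean_abg_db"].agg(
        n="count", mean_abg_db="mean", sd_abg_db=lambda v: v.std(ddof=1)
    )
    return out.reset_index()


def _rescale(shape: np.ndarray, target_mean: float) -> tuple[float, ...]:
    """Scale a nonnegative curve so its mean equals the target."""
    m = float(np.mean(shape))
    if m <= 0:
        raise ValueError("curve shape must have positive mean")
    return tuple((shape * (target_mean / m)).tolist())


def default_templates(
    scenario_shapes: Mapping[str, Sequence[float]] | None = None,
) -> list[CohortTemplate]:
    """The four published diagnosis groups as cohort templates.

    ABG curve shapes come from the finite-element pathology scenarios
    (otosclerosis: 100-fold annular-ligament stiffening; attic
    fixation: malleus+incus fixation; traumatic incomplete
    incudostapedial discontinuity: 10-fold joint loosening;
    malformative discontinuity: 100-fold loosening combined with
    10-fold annular stiffening), rescaled to the published group mean
    ABGs. Pass ``scenario_shapes`` (diagnosis -> 5 ABG values) to use
    freshly simulated shapes instead of the bundled table.
    """
    if scenario_shapes is None:
        from .config import load_template_shapes

        df = load_template_shapes()
        scenario_shapes = {
            d: g.sort_values("frequency_hz")["abg_db"].to_numpy()
            for d, g in df.groupby("diagnosis")
        }
    flat_bc = (10.0,) * 5
    oto_bc = tuple(OTOSCLEROSIS_BC_RAW[f] for f in CLINICAL_FREQUENCIES_HZ)
    templates = []
    for diagnosis, (mean_abg, sd) in GROUP_ABG_STATS.items():
        shape = np.asarray(scenario_shapes[diagnosis], dtype=float)
        templates.append(
            CohortTemplate(
                diagnosis=diagnosis,
                abg_curve=_rescale(shape, mean_abg),
                bc_curve=oto_bc if diagnosis == "otosclerosis" else flat_bc,
                sd=sd,
            )
        )
    return templates


# -- long-format CSV interchange ---------------------------------------------


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        for f, ac, bc in zip(r.frequencies, r.ac_db, r.bc_db):
            rows.append(
                {
                    "patient_id": r.id,
                    "diagnosis": r.diagnosis,
                    "frequency_hz": f,
                    "ac_db": ac,
                    "bc_db": bc,
                }
            )
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for (pid, diag), g in df.groupby(["patient_id", "diagnosis"], sort=False):
        g = g.sort_values("frequency_hz")
        records.append(
            PatientRecord(
                id=str(pid),
                diagnosis=str(diag),
                ac_db=tuple(g["ac_db"].tolist()),
                bc_db=tuple(g["bc_db"].tolist()),
            )
        )
    return records
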