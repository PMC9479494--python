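"""Bundled default configuration loaders."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml


def _config_path(name: str):
    return resources.files("otomech.configs").joinpath(name)


def load_default_materials():
    from .fem import MaterialTable

    with _config_path("materials.yaml").open() as fh:
        return MaterialTable.from_yaml(fh)


def load_default_geometry():
    from .geometry import GeometrySpec

    with _config_path("geometry.yaml").open() as fh:
        return GeometrySpec.from_yaml(fh)


def load_default_calibration():
    from .audiogram import CalibrationTable

    with _config_path("audiometry.yaml").open() as fh:
        return CalibrationTable.from_yaml(fh)


def load_displacement_corridor() -> pd.DataFrame:
    """Literature envelope for footplate displacement at 80 dB SPL."""
    with _config_path("displacement_corridor.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def load_template_shapes() -> pd.DataFrame:
    """Bundled per-diagnosis ABG curve shapes (model scenario outputs)."""
    with _config_path("template_shapes.csv").open() as fh:
        return pd.read_csv(fh, comment="#")
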