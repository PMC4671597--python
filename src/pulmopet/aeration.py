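"""CT density to fractional gas content (Fgas) and lobe-relative aeration.

A voxel is modelled as a mixture of gas and tissue/blood: with blood at
65 HU and air at −1000 HU, the gas fraction is the affine map

    Fgas = (HU_blood − HU_voxel) / (HU_blood − HU_air)

so HU = 65 gives Fgas = 0 (airless) and HU = −1000 gives Fgas = 1.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import LobeMaskVolume, ScalarVolume

log = logging.getLogger(__name__)

__all__ = ["AerationConstants", "hu_to_fgas", "fgas_to_hu", "lobe_relative_fgas"]


@dataclass(frozen=True)
class AerationConstants:
    density_blood: float = 65.0  # HU
    density_air: float = -1000.0  # HU

    def __post_init__(self) -> None:
        if self.density_blood <= self.density_air:
            raise ValueError("density_blood must exceed density_air")


def hu_to_fgas(
    hu: ScalarVolume, constants: AerationConstants = AerationConstants()
) -> ScalarVolume:
    """Convert a HU volume to gas fraction, clamping to [0, 1].

    Voxels outside the physical range (HU above blood or below air — bone,
    calibration outliers) are clamped and counted in a log message rather
    than rejected.
    """
    if hu.kind != "hu":
        raise ValueError(f"expected a volume of kind 'hu', got {hu.kind!r}")
    c = constants
    fgas = (c.density_blood - hu.values) / (c.density_blood - c.density_air)
    n_clamped = int(np.sum((fgas < 0) | (fgas > 1)))
    if n_clamped:
        log.info("hu_to_fgas: clamped %d voxels outside [0, 1]", n_clamped)
    return ScalarVolume(hu.grid, np.clip(fgas, 0.0, 1.0), "fgas")


def fgas_to_hu(
    fgas: ScalarVolume, constants: AerationConstants = AerationConstants()
) -> ScalarVolume:
    """Inverse of :func:`hu_to_fgas` on [0, 1]: HU = blood − Fgas·(blood − air)."""
    if fgas.kind != "fgas":
        raise ValueError(f"expected a volume of kind 'fgas', got {fgas.kind!r}")
    c = constants
    hu = c.density_blood - fgas.values * (c.density_blood - c.density_air)
    return ScalarVolume(fgas.grid, hu, "hu")


def lobe_relative_fgas(fgas: ScalarVolume, mask: LobeMaskVolume) -> dict[str, float]:
    """Per-lobe mean Fgas relative to the mean Fgas of the whole lung.

    The whole-lung mean runs over every labelled lung voxel (all labels,
    not just the three study lobes).
    """
    if fgas.kind != "fgas":
        raise ValueError(f"expected a volume of kind 'fgas', got {fgas.kind!r}")
    if fgas.grid.dims != mask.grid.dims:
        raise ValueError("fgas and mask are on different grids")
    lung = mask.lung_mask
    if not lung.any():
        raise ValueError("mask contains no lung voxels")
    lung_mean = float(fgas.values[lung].mean())
    if lung_mean == 0:
        raise ValueError("whole-lung mean Fgas is zero")
    out: dict[str, float] = {}
    for role in mask.role_labels:
        m = mask.role_mask(role)
        if not m.any():
            raise ValueError(f"lobe {role!r} is empty")
        out[role] = float(fgas.values[m].mean()) / lung_mean
    return out
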