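"""Moens-Korteweg pressure estimation and mean-arterial-pressure
arithmetic.

The Moens-Korteweg relation ties the pulse wave velocity to the arterial
wall's incremental elastic modulus:

    PWV^2 = E_inc * h / (D * rho)

with wall thickness ``h``, lumen diameter ``D`` and blood density
``rho`` (1061 kg/m^3 for whole blood).  The modulus in turn grows
exponentially with distending pressure, ``E_inc = E0 * exp(xi * P)``
with ``P`` in mmHg, so inverting the pair maps a measured PWV to a
pressure estimate:

    P = ln(E_inc / E0) / xi

``P`` approximates the mean arterial pressure (MAP), since systole
occupies about a third of the cycle; the cuff reference is accordingly
``MAP = (SBP + 2*DBP) / 3``.

The coefficients ``E0 = 1428.7`` and ``xi = 0.031 /mmHg`` come from
aortic pressure-volume calibration and are quoted without units for
``E0``; they reproduce the per-subject MAP round trips only when the
SI-computed modulus (Pa) is scaled by ``unit_scale = 0.1`` before the
logarithm.  That factor is an inherited unit convention, stored
explicitly on :class:`ArteryModel` and applied nowhere else — it is a
calibration, not physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ArteryModel",
    "elastic_modulus_from_pwv",
    "pressure_from_pwv",
    "pwv_from_pressure",
    "map_from_cuff",
    "mean_difference",
]


@dataclass(frozen=True)
class ArteryModel:
    """Radial-artery geometry plus wall-elasticity calibration."""

    diameter_m: float
    wall_thickness_m: float
    blood_density: float = 1061.0
    E0: float = 1428.7
    xi: float = 0.031
    unit_scale: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "diameter_m",
            "wall_thickness_m",
            "blood_density",
            "E0",
            "xi",
            "unit_scale",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"ArteryModel.{name} must be > 0")
        if not self.wall_thickness_m < self.diameter_m:
            raise ValueError("wall thickness must be smaller than the diameter")


def elastic_modulus_from_pwv(pwv: float, artery: ArteryModel) -> float:
    """Incremental elastic modulus from PWV (calibrated units).

    ``E_inc = PWV^2 * D * rho / h`` in SI, then scaled by ``unit_scale``.
    """
    if not pwv > 0:
        raise ValueError("pwv must be > 0")
    e_si = pwv**2 * artery.diameter_m * artery.blood_density / artery.wall_thickness_m
    return e_si * artery.unit_scale


def pressure_from_pwv(pwv: float, artery: ArteryModel) -> float:
    """Pressure estimate (mmHg) from a measured PWV.

    Raises if the calibrated modulus does not exceed ``E0`` (the estimate
    would be non-positive — usually a sign the calibration or geometry is
    off).
    """
    e = elastic_modulus_from_pwv(pwv, artery)
    if e <= artery.E0:
        raise ValueError(
            f"calibrated modulus {e:.4g} <= E0 ({artery.E0}); pressure would be "
            "non-positive — check artery geometry and unit_scale calibration"
        )
    return math.log(e / artery.E0) / artery.xi


def pwv_from_pressure(p: float, artery: ArteryModel) -> float:
    """Forward model: PWV (m/s) at pressure ``p`` mmHg.

    Exact inverse of :func:`pressure_from_pwv`; monotone increasing in p.
    """
    e_si = artery.E0 * math.exp(artery.xi * p) / artery.unit_scale
    return math.sqrt(
        e_si * artery.wall_thickness_m / (artery.diameter_m * artery.blood_density)
    )


def map_from_cuff(sbp: float, dbp: float, strict: bool = True) -> float:
    """Cuff-derived mean arterial pressure ``(SBP + 2*DBP)/3``.

    With ``strict`` (default), requires ``sbp > dbp > 0``; pass
    ``strict=False`` to allow the degenerate ``sbp == dbp`` fixed point.
    """
    if not dbp > 0:
        raise ValueError("dbp must be > 0")
    if strict and not sbp > dbp:
        raise ValueError("sbp must exceed dbp")
    if not strict and sbp < dbp:
        raise ValueError("sbp must be >= dbp")
    return (sbp + 2.0 * dbp) / 3.0


def mean_difference(
    reference_map: float, estimated_maps: Sequence[float]
) -> float:
    """Signed difference ``reference - mean(estimates)`` in mmHg."""
    estimated_maps = np.asarray(estimated_maps, dtype=np.float64)
    if estimated_maps.size == 0:
        raise ValueError("estimated_maps must be non-empty")
    return float(reference_map - estimated_maps.mean())
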