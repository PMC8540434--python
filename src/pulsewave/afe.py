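"""Design calculators for the sensor cavity and analog front end (AFE).

These are pure-function verification formulas for the acquisition chain in
front of the ADC — the pressurized piezoelectric cavity, the load resistor
forming a first-order high-pass with the sensor's parasitic capacitance,
the gain stage, and the two second-order Sallen–Key filters.  They compute
corner frequencies and small-signal responses; they are not a circuit
simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CavityModel",
    "SallenKeyStage",
    "load_resistor",
    "amplifier_gain",
    "sallen_key_cutoff",
    "sallen_key_magnitude",
    "cavity_acceleration",
    "cavity_natural_frequency",
]


@dataclass(frozen=True)
class CavityModel:
    """Pressurized air cavity behind the piezoelectric disc.

    Attributes
    ----------
    V : float
        Cavity volume before pressurization (m^3).
    S : float
        Section area (m^2).
    L : float
        Neck/displacement length (m).
    P_A : float
        Static pressure (Pa).
    gamma : float
        Ratio of specific heats; ~1.4 for air.
    rho_air : float
        Air density (kg/m^3); 1.2 at room conditions.
    """

    V: float
    S: float
    L: float
    P_A: float
    gamma: float = 1.4
    rho_air: float = 1.2

    def __post_init__(self) -> None:
        for name in ("V", "S", "L", "P_A", "gamma", "rho_air"):
            if not getattr(self, name) > 0:
                raise ValueError(f"CavityModel.{name} must be > 0")


@dataclass(frozen=True)
class SallenKeyStage:
    """Component values of one second-order Sallen–Key stage."""

    R_a: float
    R_b: float
    C_a: float
    C_b: float
    topology: str = "highpass"

    def __post_init__(self) -> None:
        for name in ("R_a", "R_b", "C_a", "C_b"):
            if not getattr(self, name) > 0:
                raise ValueError(f"SallenKeyStage.{name} must be > 0")
        if self.topology not in ("highpass", "lowpass"):
            raise ValueError(f"unknown topology {self.topology!r}")


def load_resistor(C_p: float, f_c: float) -> float:
    """Load resistance R = 1/(2*pi*f_c*C_p) for a first-order RC corner.

    Parameters
    ----------
    C_p : float
        Parasitic capacitance of the piezoelectric element (F).
    f_c : float
        Desired high-pass corner frequency (Hz).
    """
    if not (C_p > 0 and f_c > 0):
        raise ValueError("C_p and f_c must be > 0")
    return 1.0 / (2.0 * math.pi * f_c * C_p)


def amplifier_gain(R2: float, R3: float) -> float:
    """Voltage gain of the amplifier stage, R2/R3."""
    if not (R2 > 0 and R3 > 0):
        raise ValueError("R2 and R3 must be > 0")
    return R2 / R3


def sallen_key_cutoff(stage: SallenKeyStage) -> float:
    """Corner frequency 1/(2*pi*sqrt(Ra*Ca*Rb*Cb)); same for both topologies."""
    return 1.0 / (
        2.0 * math.pi * math.sqrt(stage.R_a * stage.C_a * stage.R_b * stage.C_b)
    )


def sallen_key_magnitude(stage: SallenKeyStage, f: float) -> float:
    """|H(j*2*pi*f)| of the stage's second-order transfer function.

    The high-pass numerator is s^2; the low-pass numerator is the
    denominator's constant term, so the DC gain of the low-pass and the
    high-frequency asymptote of the high-pass are both 1.  With equal
    resistor and capacitor pairs the stage has Q = 1/2, so the magnitude
    at the corner frequency is 0.5.
    """
    if not f > 0:
        raise ValueError("f must be > 0")
    s = 2j * math.pi * f
    w0_sq = 1.0 / (stage.R_a * stage.C_a * stage.R_b * stage.C_b)
    if stage.topology == "highpass":
        # damping term: s*(1/(Ra*Ca) + 1/(Ra*Cb))
        damp = 1.0 / (stage.R_a * stage.C_a) + 1.0 / (stage.R_a * stage.C_b)
        num = s * s
    else:
        # damping term: s*(1/(Rb*Ca) + 1/(Ra*Ca))
        damp = 1.0 / (stage.R_b * stage.C_a) + 1.0 / (stage.R_a * stage.C_a)
        num = w0_sq
    den = s * s + s * damp + w0_sq
    return abs(num / den)


def cavity_acceleration(displacement: float, cav: CavityModel) -> float:
    """Restoring acceleration of the cavity air mass, m/s^2.

    a(x) = -(gamma*S*P_A / (rho_air*V*L)) * x: linear and opposite in sign
    to the displacement, i.e. the cavity behaves as a Helmholtz spring.
    Valid in the small-signal regime |x| << V/S (not enforced).
    """
    coeff = (cav.gamma * cav.S * cav.P_A) / (cav.rho_air * cav.V * cav.L)
    return -coeff * displacement


def cavity_natural_frequency(cav: CavityModel) -> float:
    """Natural frequency (Hz) of the cavity's restoring-force law."""
    coeff = (cav.gamma * cav.S * cav.P_A) / (cav.rho_air * cav.V * cav.L)
    return math.sqrt(coeff) / (2.0 * math.pi)
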