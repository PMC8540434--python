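"""Verify the analog-front-end design arithmetic.

The piezoelectric disc (8000 pF parasitic capacitance) plus an external
load resistor forms a first-order high-pass; we pick the resistor for a
1 Hz corner, then check the two second-order Sallen-Key stages and the
sensor cavity's natural frequency.
"""

from pulsewave import (
    CavityModel,
    SallenKeyStage,
    cavity_natural_frequency,
    load_resistor,
    sallen_key_cutoff,
    sallen_key_magnitude,
)

r1 = load_resistor(C_p=8000e-12, f_c=1.0)
print(f"load resistor for a 1 Hz corner : {r1 / 1e6:.2f} Mohm (~20 Mohm)")

hpf = SallenKeyStage(1e6, 1e6, 274e-9, 274e-9, "highpass")
lpf = SallenKeyStage(150e3, 150e3, 100e-9, 100e-9, "lowpass")
f_hp, f_lp = sallen_key_cutoff(hpf), sallen_key_cutoff(lpf)
print(f"Sallen-Key high-pass corner     : {f_hp:.3f} Hz (removes DC/baseline)")
print(f"Sallen-Key low-pass corner      : {f_lp:.2f} Hz (removes mains)")
print(f"|H| at each corner              : {sallen_key_magnitude(hpf, f_hp):.3f}"
      f" / {sallen_key_magnitude(lpf, f_lp):.3f}  (Q = 1/2 stages)")

cavity = CavityModel(V=1e-6, S=1e-4, L=1e-3, P_A=101325.0)
f0 = cavity_natural_frequency(cavity)
print(f"cavity natural frequency        : {f0 / 1e3:.1f} kHz "
      "(far above the <10 Hz pulse band, so the sensor responds flat)")
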