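"""Attenuation-dB scale and cross-device rescaling.

Shows the forward conversion from a luminance increment to differential
light sensitivity (DLS), and how raw dB values from a Humphrey-type
reference perimeter (maximal pedestal 3183.1 cd/m^2) are re-expressed on
the screen's 0-34 dB scale, with negative rescaled values rounded up to 0.
"""

from gazeperim.units import (LuminanceConfig, dls_from_increment,
                             hfa_to_screen_db, increment_from_db)

cfg = LuminanceConfig()
print(f"background luminance      : {cfg.background_cd_m2} cd/m^2")
print(f"maximal screen increment  : {cfg.max_increment_cd_m2} cd/m^2")

for inc in (225.0, 22.5, 2.25, 0.09):
    print(f"increment {inc:7.2f} cd/m^2 -> DLS {dls_from_increment(inc, cfg):6.2f} dB")

print()
print("reference-device dB -> screen dB (clamped at 0):")
for hfa_db in (0.0, 10.0, 20.0, 30.0, 35.0):
    out = hfa_to_screen_db(hfa_db, cfg)
    print(f"  HFA {hfa_db:5.1f} dB -> {out:5.2f} dB")

# a 20 dB threshold corresponds to a 2.25 cd/m^2 just-noticeable increment
print(f"\nincrement at 20 dB        : {increment_from_db(20.0, cfg):.4f} cd/m^2")
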