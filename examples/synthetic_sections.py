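"""Generate one synthetic thrombus section per compositional subgroup.

Builds 10-mm sections at three target fibrin fractions, prints the
realised composition and subgroup, and writes the label masks (PNG with a
.meta sidecar) next to this script. Fractions are computed over thrombus
pixels; subgroups use the strict >75% rule.
"""

from pathlib import Path

from thrombosim import composition, generate_section, write_label_mask

here = Path(__file__).parent
for name, target in [("fibrin_dominant", 0.85), ("half_half", 0.5),
                     ("rbc_dominant", 0.15)]:
    sec = generate_section(target_fibrin_fraction=target, extent_mm=10.0,
                           pixel_size_um=30.0, seed=1)
    c = composition(sec)
    print(f"{name}: fibrin {c.fibrin_fraction:.3f}, RBC {c.rbc_fraction:.3f}, "
          f"area {c.thrombus_area_mm2:.1f} mm^2 -> {c.subgroup.value}")
    write_label_mask(sec, here / f"{name}.png")
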