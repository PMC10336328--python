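"""Steady rt-PA field around the infusion catheter, with and without ablation.

Solves the quenched perfusion-diffusion equation on the annulus (catheter
radius 0.84 mm) for intact thrombus, then again after a histotripsy
treatment has liquefied a focal channel. PAI-1 quenching confines the
drug to within ~2 mm of the catheter; the liquefied channel carries it
deeper and raises the fibrin-degradation total.
"""

from thrombosim import (
    PolarGrid,
    SourceSpec,
    elliptical_gaussian_field,
    fdp_map,
    generate_section,
    penetration_depth,
    run_treatment,
    solve,
)

sec = generate_section(0.15, extent_mm=10.0, pixel_size_um=30.0, seed=1)
grid = PolarGrid.for_section(sec)

baseline = solve(sec, None, grid=grid, duration_s=20.0)
_, fdp0 = fdp_map(baseline, sec)
print(f"intact thrombus: steady after {baseline.steady_time_s:.2f} s, "
      f"1% penetration {penetration_depth(baseline):.2f} mm, "
      f"FDP total {fdp0:.0f} nMol-px")

field = elliptical_gaussian_field(SourceSpec(peak_negative_pressure_mpa=40.0), sec)
res = run_treatment(sec, field, n_pulses=1000, n_repeats=1, seed=3)
treated = solve(sec, res.ablated_masks[0], grid=grid, duration_s=20.0)
_, fdp1 = fdp_map(treated, sec, res.ablated_masks[0])
print(f"after histotripsy: 1% penetration {penetration_depth(treated):.2f} mm, "
      f"FDP total {fdp1:.0f} nMol-px (relative FDP {fdp1 / fdp0:.3f})")
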