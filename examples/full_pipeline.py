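"""Small end-to-end dose-response sweep with cohort statistics.

One RBC-dominant and one half-half synthetic section, swept over
0/32/40 MPa (0 MPa is the no-histotripsy baseline for relative FDP).
Prints the per-(section, pressure) summary and the z-score linear
regression coefficient coupling hemolysis to fibrinolysis. Scaled down
(30-um pixels, 300 pulses, 2 repeats) so it runs in about a minute.

Note the half-half section in this draw: its (small) ablation zone falls
entirely inside the catheter cross-section, so the drug field and FDP
total are unchanged across pressures and the coefficient is reported as
missing (NaN) rather than coerced to a number.
"""

from thrombosim import ExperimentConfig, run_experiment, summarize, zlrc_by_section

cfg = ExperimentConfig(
    n_fibrin_dominant=0, n_half_half=1, n_rbc_dominant=1,
    pressures_mpa=(0.0, 32.0, 40.0),
    n_pulses=300, n_repeats=2, pixel_size_um=30.0, extent_mm=10.0, seed=11,
)
table = run_experiment(cfg)
print(summarize(table).to_string(index=False))
print("\nz-score linear regression coefficient (Hg vs FDP) per section:")
print(zlrc_by_section(table).to_string())
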