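# thrombosim

Coupled in-silico model of **histotripsy clot ablation** and
**catheter-directed thrombolysis** in venous thrombus.

Catheter-infused rt-PA (recombinant tissue plasminogen activator) is the
standard of care for critical venous thrombosis, but the drug barely
penetrates the dense clot before PAI-1 quenches it. Histotripsy — focused
ultrasound that lyses tissue through clouds of spontaneously nucleated
bubbles — preferentially destroys red blood cells while leaving the fibrin
mesh intact, and the liquefied lesion is far more permeable to drug. This
package simulates that interplay on 2D labelled thrombus sections so that
dose-response questions (pulse pressure, clot composition, drug exposure)
can be explored computationally by therapeutic-ultrasound and drug-delivery
researchers.

## Model core

1. **Synthetic histology** — sections are labelled grids (fibrin / RBC /
   background, default 7.4 µm pixels) generated as thresholded correlated
   random fields with controlled fibrin fraction; subgroups follow the
   clinical rule (>75% fibrin = fibrin-dominant, >75% RBC = RBC-dominant,
   else half-half).
2. **Monte Carlo bubble ablation** — per pulse, every thrombus pixel
   nucleates with probability Φ((p⁻ − 26.8 MPa)/1.2 MPa) (intrinsic
   threshold for clot); a nucleated bubble grows in a Kelvin–Voigt medium to

       R_MAX = R₀ + √(2 P₀ ξ / 9ρ) · τ · (ξ P₀ / 3 p_EFF + 1)^{1/3},
       ξ = (p⁻ − P₀)/P₀ − 6G/P₀,   p_EFF = P₀(1 + 4G/3P₀),

   with G the mean elastic modulus within 500 µm (fibrin 14 MPa, RBC 4 kPa,
   liquefied 0). RBC pixels inside the bubble footprint are re-labelled
   liquefied; fibrin never changes. Release of ~0.03 ng hemoglobin per
   ablated cell-sized pixel quantifies hemolysis.
3. **rt-PA transport** — explicit FDTD solution of the perfusion–diffusion
   equation ∂C/∂t = D_r ∂²C/∂r² + (D_θ/r²) ∂²C/∂θ² − v(r) ∂C/∂r − k₂C_p C
   on an annulus around the 0.84-mm catheter: porous intact clot carries
   dispersion a_I/a_II = 9.4/3.4 ×10⁻⁶ cm²/s and radial outflow
   v = U·r_c/r (U = 0.87 cm/s at the catheter); liquefied regions are fluid
   (D = 25×10⁻⁶ cm²/s, plug flow at U); PAI-1 quenches rt-PA at k₂C_p.
4. **Fibrinolysis** — fibrin pixels degrade by the closed-form two-step
   kinetics C_FDP = C_FIB(1 − exp(−k₁k₄C·C_Pm/(k₃C_AP)·t)) over a 20-min
   exposure at the steady drug field; totals relative to the 0-MPa baseline
   give the relative-FDP enhancement.
5. **Statistics** — ANOVA/Tukey across arms, Pearson correlations, and the
   z-score linear-regression coefficient between hemoglobin and FDP (≈1
   when histotripsy promotes hemolysis and fibrinolysis proportionally).

## Worked example

```sh
python examples/drug_transport.py
```

```
intact thrombus: steady after 0.45 s, 1% penetration 1.18 mm, FDP total 84296 nMol-px
after histotripsy: 1% penetration 1.36 mm, FDP total 85542 nMol-px (relative FDP 1.015)
```

Without histotripsy the quenched drug stalls ~1.2 mm from the catheter
surface; after 1000 pulses at 40 MPa the liquefied focal channel carries it
deeper and the fibrin-degradation total rises by 1.5% on this RBC-dominant
section. `examples/ablation_treatment.py` shows the ablation side: the
lesion area (here 1.17 mm² at 36 MPa) saturates within the first ~50
pulses, and hemoglobin release is compared against catheter-insertion
hemolysis. `examples/full_pipeline.py` runs a small cohort sweep and prints
the dose-response table with the hemolysis–fibrinolysis coupling
coefficient (≈1 for RBC-dominant sections).

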