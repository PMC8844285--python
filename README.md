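# mtpef

Quantification and biophysical modelling of microsecond pulsed-electric-field
(µs-PEF) effects on dense, surface-anchored microtubule networks imaged by
TIRF microscopy.

## The problem

Microtubules (MTs) carry a strong net negative charge, so a sufficiently
intense electric field can rip them off an antibody-functionalised coverslip
and sweep them toward the anode.  In a dense network (several MTs/µm²,
comparable to animal cells) single-filament segmentation and tracking is
impractical — filaments overlap, backgrounds are inhomogeneous, and the
camera's auto-gain drifts.  This package implements segmentation-free
measures of the network response together with the force-balance model that
explains the observed voltage threshold, and a synthetic TIRF time-lapse
generator with exact ground truth so the whole analysis chain can be
validated end to end.

## Measures and model

**Microtubule displacement index (MDI).**  For frames at times t₁, t₂ and a
region of interest:

    MDI = (1/|ROI|) Σ_{[i j]∈ROI} |I_ij(t₂) − I_ij(t₁)|

Taken across a whole pulse train it measures overall displacement; applied
frame-to-frame and rescaled by the frame interval it becomes the *MDI speed*
(s⁻¹), a time-resolved displacement trace.  Before any differencing, every
frame is divided by the mean intensity of a background region where
filaments stay put, which cancels per-frame camera gain exactly.

**Microtubule overlap rate (MOR).**  With a binarisation threshold *th* from
a modified Otsu method (standard between-class-variance maximisation after
excluding the brightest 0.1 % of ROI pixels):

    MOR = #{I(t₁) > th} / #{I(t₂) > th}

Fluorescence is additive, so stacked filaments occupy fewer, brighter
pixels: MOR > 1 signals accumulation/overlap.

**Force balance.**  A filament detaches when the electrophoretic pull per
unit length exceeds the anchoring force per unit length:

    E · ρ_MT > D_AB · F_AB,   ρ_MT = N · Q_TUB / L_TUB

With N = 13 protofilaments, Q_TUB = 23 e per 8 nm dimer and F_AB = 50 pN
per antibody, the field at 210 V (17.5 kV/cm, from the linear 300 V ↔
25 kV/cm chip calibration) balances ≈ 210 antibodies per µm of MT length —
which is why displacement starts abruptly at that voltage when anchoring
densities are in that range.

## Worked example

Simulate the cumulative seven-train voltage sweep (45 → 300 V, 100 × 5 µs
pulses at 10 Hz per train, 600 filaments, anchoring mean set by the force
balance) and analyse it:

```python
from mtpef.experiment import build_sweep_scene, simulate_sweep
from mtpef.pipeline import run_analysis

design = build_sweep_scene(seed=11)
stack, truth = simulate_sweep(design, seed=11)
report = run_analysis(stack, design.protocols, regions=design.regions)
print(report.per_voltage[["voltage_v", "endpoint_mdi", "mor_cumulative",
                          "peak_mdi_speed_per_s"]].round(3))
print(report.threshold_voltage_v)
```

Output:

```
 voltage_v  endpoint_mdi  mor_cumulative  peak_mdi_speed_per_s
      45.0         0.041           0.999                 0.103
      85.0         0.042           0.997                 0.103
     125.0         0.042           0.999                 0.103
     170.0         0.042           1.002                 0.103
     210.0         0.431           0.990                 0.457
     255.0         0.805           0.976                 0.818
     300.0         0.885           1.533                 0.948
210.0
```

Below 210 V nothing moves: endpoint MDI sits at the noise floor
(MDI speed ≈ 0.10 s⁻¹) and MOR ≈ 1.  At 210 V roughly half the network
detaches (peak speed 4.5 × the floor), peaks then grow with voltage as more
filaments move faster, and by 300 V the swept filaments pile up in the
weak-field margin beyond the electrode edge — cumulative MOR 1.53, i.e.
one-third fewer supra-threshold pixels than before pulsing.  The estimated
displacement threshold (first peak exceeding 3 × the pre-pulse floor) is
210 V, recovering the anchoring density put into the simulation through the
force balance.

The same workflow is available from the shell:

```bash
mtpef simulate --seed 11 --out run/       # TIFF stack + ground truth + config
mtpef analyze run/analysis_config.yaml    # CSVs + JSON report
mtpef calc field 210                      # -> 17.5 (kV/cm)
mtpef calc detachment-density 17.5        # -> 209.585 (antibodies/µm)
```

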