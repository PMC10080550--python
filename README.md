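# silbind

Analysis toolkit for silver-ion binding to model peptides of SilE, the
periplasmic silver-sponge protein of the bacterial *sil* resistance system.
It is aimed at NMR/MS spectroscopists studying metal–peptide interactions and
covers the four computational stages of a combined 2D-NMR / native ESI–MS
titration study:

1. **Chemical-shift-perturbation (CSP) mapping.** For a homonuclear TOCSY
   titration, CSP = √(Δδ²_H(F1) + Δδ²_H(F2)); for a ¹H–¹³C HSQC titration the
   carbon axis is scaled, CSP = √(Δδ²_H + α·Δδ²_C) with α = 0.3. Cross-peaks
   are binned into signal groups (Cα/Hα, Cβ/Hβ, Cγ/Hγ, methyl-region), and
   per-group mean μ and standard deviation σ classify each peak as a weak
   (< μ), medium ([μ, μ+σ)) or strong (≥ μ+σ) mover.
2. **Secondary ¹³Cα shifts.** δ_obs − δ_rc against a packaged random-coil
   reference (positive = helical tendency), plus an ideal helical-wheel test
   (100°/residue) for whether two residues present side chains on the same
   helix face (the i+3 / i+4 register).
3. **Titration-trajectory analysis.** Under fast exchange a single binding
   mode moves a cross-peak along a straight line; a turn in the path reveals
   a second binding mode. The detector measures turning angles between
   successive displacement vectors (noise-guarded) and reports the
   equivalence point at the vertex of the first qualifying turn.
4. **ESI–MS stoichiometry and affinity.** Centroids are annotated as
   (oligomer, Ag_n, charge) species via the positive-mode adduct convention
   m/z = (k·M + n·m(Ag⁺) + (z−n)·m(H⁺))/z, quantified into peptide mole
   fractions (dimers = nonspecific gas-phase artifacts, counted into the apo
   pool), and fitted to the sequential two-site scheme

       P + Ag⁺ ⇌ P·Ag    (K_D1)      P·Ag + Ag⁺ ⇌ P·Ag₂    (K_D2)

   by deterministic least squares on the mole fractions, with the species
   concentrations solved from the exact mass balances at every step.

A synthetic-data generator produces assigned peak lists and stick spectra
with the statistical structure these analyses assume, so the whole pipeline
is exercised by parameter recovery without instrument data.

## Worked example

Fit the dissociation constants from a synthetic ESI–MS titration of the
19-residue peptide SP3 (100 μM, Ag⁺:peptide ratios 0, 0.5, 1, 2):

```python
from silbind import AgBindingTitration, generate_ms_titration
from silbind.synthetic import load_preset

config = load_preset("sp3-paper")          # 100 uM, ratios 0/0.5/1/2, noiseless
spectra = generate_ms_titration(config)
model = AgBindingTitration.from_spectra(spectra, config.sequence)
print(model.fit().summary())
```

```
Sequential two-site Ag+ binding fit
====================================================
titration points                                   4
converged                                       True
SSE (mole fractions)                       1.224e-31
----------------------------------------------------
parameter          estimate (uM)        std err (uM)
K_D1                         0.2            2.93e-16
K_D2                        24.5            1.31e-14
----------------------------------------------------
```

The fit recovers the generator's ground truth exactly: a sub-micromolar
first site (K_D1 = 0.2 μM) and a weaker second site (K_D2 = 24.5 μM) — two
silver sites of clearly different affinity on one peptide.

The same stages are scriptable from the shell:

```bash
silbind masscalc --seq ADAHQKMVESHQRMMG
# 1856.118                                  <- average MW (Da)
silbind simulate-nmr --preset sp2-paper --out nmr/
silbind trajectory --series nmr/series.yaml --assignment 8:V:H:HG
# has_break=True break_ratio=0.5 max_turn_deg=77.5
```

The valine amide/Hγ cross-peak runs straight up to 0.5 Ag⁺ equivalents and
then turns by ~78° — the signature of two sequential binding modes.

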