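# quadbind

Quantitative analysis of weak peptide–nucleic-acid binding and
G-quadruplex (G4) thermal stability. The package implements the two
workhorse measurements of host–guest studies on RNA/DNA quadruplexes:

* **NMR chemical-shift titrations** in the fast-exchange regime —
  equilibrium speciation for 1:1 and 2:1 receptor–ligand models, global
  nonlinear isotherm fitting, AICc model selection, and replicate
  averaging;
* **CD melting curves** — asymmetric-sigmoid fits, melting temperature
  (Tm) at the half-denaturation point, fraction-folded normalization,
  per-sequence ΔTm stabilization tables, and parallel/antiparallel G4
  topology classification from CD band signs.

It is written for spectroscopists and supramolecular/nucleic-acid chemists
who want a scriptable, testable alternative to web fitters and vendor
regression tools, plus seeded synthetic-data generators so every stage of
the pipeline can be validated without instrument data.

## The models

**Binding.** With receptor R (the nucleic-acid strand) and ligand L (the
peptide), the stepwise equilibria are R + L ⇌ RL (K1) and RL + L ⇌ RL2
(K2), in M⁻¹. The *statistical* 2:1 model is two equivalent independent
sites with one microscopic constant k, so K1 = 2k, K2 = k/2 and the
cooperativity index α = 4K2/K1 = 1. Free ligand solves the monotone mass
balance

    p + R_tot (K1 p + 2 K1 K2 p²)/(1 + K1 p + K1 K2 p²) = L_tot

by bracketed root finding. Observed shifts follow the fast-exchange
population average δ_obs = (δ_free[L] + δ_b1[RL] + δ_b2·2[RL2])/L_tot;
constants are fit in log₁₀ space with the linear shift parameters profiled
out, and candidate stoichiometries are ranked by
AICc = n ln(rss/n) + 2p + 2p(p+1)/(n−p−1).

**Melting.** Ellipticity versus temperature is fit to
y(T) = A_u + (A_f − A_u)/(1 + exp((T − T_half)/w))^s and Tm is the
temperature where y crosses (A_f + A_u)/2 — the 50 %-denatured point.
ΔTm tables compare each condition against its control.

**Thermodynamics.** ΔG = −RT ln K and ΔΔG = −RT ln(K_a/K_b) in kJ/mol
(R = 8.314 J mol⁻¹ K⁻¹); `design_saturation` inverts the occupancy curve
to find the ligand excess reaching a target site saturation.

## Worked example

Fit a duplicate titration globally, compare stoichiometries, and build a
stabilization table:

```python
import quadbind as qb

# simulate a duplicate titration: 125 uM peptide, 0-2 equivalents of RNA,
# statistical 2:1 truth k = 5000 M^-1, 0.002 ppm shift noise
series_list, truth = qb.gen_titration(qb.TitrationDesign(noise_sd=0.002, seed=7))

joint = qb.merge_replicates(series_list)          # global fit across replicates
comp = qb.compare_models(joint, ["2:1-statistical", "2:1-full"])
print(comp.table().to_string(index=False))
best = comp.best
print(f"k_micro = {best.primary_constant:.0f} +/- {best.primary_constant_se:.0f} M^-1")
print(f"dG(25 C) = {qb.free_energy(best.primary_constant).delta_G:.1f} kJ/mol")
```

prints

```
          model  n_params      rss        aicc  delta_aicc
2:1-statistical         5 0.000082 -288.612640    0.000000
       2:1-full         8 0.000076 -278.223433   10.389207
k_micro = 4843 +/- 670 M^-1
dG(25 C) = -21.0 kJ/mol
```

The statistical (non-cooperative) 2:1 model wins the AICc comparison by
10.4 units over the full 2:1 model — the extra stepwise constant and bound
shift are not supported by the data — and the recovered per-site constant
brackets the generating truth of 5000 M⁻¹. For the melting side:

```python
ctrl  = qb.gen_melt(qb.MeltDesign(Tm=24.7, s=1.5, noise_sd=0.2, seed=7))
treat = qb.gen_melt(qb.MeltDesign(Tm=34.0, s=1.5, noise_sd=0.2, seed=7,
                                  condition_label="peptide_16x"))
table = qb.build_stabilization_table([
    ("TERRA", "control", qb.fit_melt(ctrl)),
    ("TERRA", "peptide_16x", qb.fit_melt(treat)),
])
print(table.to_frame().to_string(index=False))
```

```
sequence  Tm_control  Tm_condition  delta_T   condition error
   TERRA        24.7          34.0      9.3 peptide_16x
```

a ΔTm of +9.3 °C, i.e. the treated condition melts 9.3 °C higher than the
control — substantial stabilization of the folded quadruplex.

## Command line

The same pipeline is scriptable via `quadbind` (`gen-synth`,
`fit-titration`, `fit-melt`, `classify-cd`, `simulate`); results go to
files, logs to stderr, and exit codes are 0 (success), 2 (schema/config
violation) and 3 (fit failure, partial results written):

```bash
quadbind gen-synth --seed 1 --out study/
quadbind fit-titration study/titrations.csv --out fits/
quadbind fit-melt study/melts.csv --out stabilization.csv
quadbind simulate --k-micro 5e3 --receptor-total 2e-5 --target-fraction 0.9 --out sat.csv
```

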