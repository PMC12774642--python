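# Methods

`quadbind` analyses weak peptide–nucleic-acid binding with the two
measurement types this problem is usually studied with: fast-exchange NMR
chemical-shift titrations, and circular-dichroism (CD) thermal denaturation
of G-quadruplex (G4) structures. This note records the models, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
generators do and do not emulate.

## Equilibrium model

The receptor R is the single-copy species (the folded nucleic-acid strand)
and the ligand L the species that can bind twice (the peptide). The stepwise
mass-action system is

    R + L  ⇌ RL     K1 = [RL] / ([R][L])        (M⁻¹)
    RL + L ⇌ RL2    K2 = [RL2] / ([RL][L])      (M⁻¹)

Three stoichiometric models are supported:

* **1:1** — single site, closed-form quadratic solution.
* **2:1 full** — independent K1 and K2.
* **2:1 statistical** — two equivalent, independent sites with one
  microscopic per-site constant k; the statistical factors force K1 = 2k and
  K2 = k/2, so K1/K2 = 4 and the cooperativity index α = 4K2/K1 = 1.

Speciation for the 2:1 models reduces to one scalar equation in the free
ligand p:

    h(p) = p + R_tot · (K1 p + 2 K1 K2 p²) / (1 + K1 p + K1 K2 p²) − L_tot = 0

h is strictly increasing with h(0) = −L_tot ≤ 0 and h(L_tot) ≥ 0, so the
root on [0, L_tot] exists and is unique. It is found by Brent's method at
machine-precision tolerances and then polished with a few Newton steps with
a relative stopping rule; the polish matters when R_tot·K1 is large, where
p can be ten orders of magnitude below L_tot and an absolute tolerance on p
would leave a visible mass-balance defect. Mass balance closes to better
than 1e-10 relative over the full tested regime (K ∈ [1, 10⁸] M⁻¹,
concentrations ∈ [10⁻⁸, 10⁻²] M); in practice it closes near machine
precision. The 1:1 closed form uses the cancellation-free root
2c/(b + √(b² − 4ac)), because the textbook (b − √disc)/2a form loses seven
digits at trace-complex compositions.

All internal concentrations are mol/L and constants M⁻¹; micromolar
conversions happen only at the I/O boundary. Receptor and ligand roles are
fixed by the thermodynamic model, not by which species is titrated: in the
NMR experiment the peptide (ligand) is held constant and the nucleic acid
(receptor) is dosed, and the same speciation routine serves both the
isotherm fits and the saturation simulations.

## Fast-exchange observation model and titration fitting

In fast exchange each nucleus shows one population-weighted resonance:

    δ_obs = (δ_free·[L] + δ_b1·[RL] + δ_b2·2[RL2]) / L_tot

For the statistical model the two bound environments are identical, so
δ_b2 = δ_b1 is imposed; the full 2:1 model frees both. With no titrant the
ligand is entirely free and the prediction is δ_free exactly.

`fit_titration` minimizes the summed squared shift residuals over all
nuclei and points. Equilibrium constants are optimized in log10 space
(constants are scale parameters; the log parametrization makes the search
well-conditioned and enforces positivity). The shift parameters enter the
model linearly, so at every constant evaluation they are profiled out by
ordinary linear least squares — the optimizer only ever sees a 1- or
2-dimensional problem. A coarse grid over log10 K ∈ {1,…,8} (with
K2 = K1/4 as the starting ratio for the full model) seeds the optimizer to
avoid local minima. Standard errors come from the numerical Jacobian of the
full parameter vector at the optimum, with the constant's error mapped back
from log space by the delta method.

Two degeneracies are detected and flagged `unidentifiable` rather than
reported as confident estimates:

* flat traces, where the total shift excursion is below the noise floor
  (default 0.005 ppm);
* the weak-binding ridge K → 0 with δ_bound → ∞ (K · Δδ fixed), which is a
  genuine boundary maximum of the likelihood for some noise realizations.
  It is recognized by a fitted |δ_bound − δ_free| beyond 20 ppm (far outside
  any plausible ¹H shift change) or a constant pinned at the search bounds.

Flagged fits report their constants without confidence intervals and carry
no weight in replicate averaging.

Model comparison ranks candidate fits by the small-sample corrected Akaike
criterion AICc = n ln(rss/n) + 2p + 2p(p+1)/(n−p−1); candidates within 2
AICc units of the best are re-ordered by parameter count so the simplest
adequate model wins. Replicate summaries use the inverse-variance weighted
mean Σ(K/se²)/Σ(1/se²) with propagated error √(1/Σ(1/se²)). For parameter
recovery the preferred route is a **global fit** across duplicates
(`merge_replicates`): one shared constant, per-replicate shift parameters.
It uses the data jointly and gives both lower estimation error and
better-calibrated intervals than averaging separately fitted constants,
which is why the recovery studies use it.

No dilution correction is applied by default (the titrant is assumed added
without changing the fixed-species concentration); an explicit per-point
titrant-concentration column overrides the equivalents-based schedule.

## CD melting curves and Tm

Melting curves are fit to an asymmetric five-parameter logistic

    y(T) = A_unfolded + (A_folded − A_unfolded) / (1 + exp((T − T_half)/w))^s

with plateaus A (mdeg), position T_half (°C), width w (°C) and asymmetry
exponent s > 0. Any strictly monotone asymmetric sigmoid serves here,
because the melting temperature is defined operationally — Tm is the
temperature where the fitted signal crosses the midpoint of the plateaus,
i.e. where half the structure has denatured — and is found by bracketed
root finding inside the measured range, not read off the inflection. For
s = 1 the form collapses to the symmetric Boltzmann sigmoid and Tm = T_half.
w and s are kept positive by log-parametrization, so a "negative width" can
never be reported. The tail factor (1+e^z)^(−s) is evaluated in log space to
avoid overflow. Tm's standard error uses the delta method on the implicit
half-signal equation, with dTm/dθ computed by re-solving the root under
parameter perturbations.

Plateaus are constant (no sloping baselines): the analysis targets curves
with well-expressed plateaus, and a baseline treatment would add parameters
the 5–95 °C design does not constrain. Curves whose excursion is below the
amplitude floor (default 1 mdeg), or whose fitted half-signal point falls
outside the measured range, raise a transition-out-of-range error instead
of returning an extrapolated Tm.

Fraction folded is the linear normalization
θ = (y − y_unfolded)/(y_folded − y_unfolded) against a designated 100 %-
folded reference; values slightly outside [0, 1] are reported, not clipped.
Stabilization tables compute ΔTm = Tm(condition) − Tm(control) from
unrounded fits, rounding to 0.1 °C only at serialization.

Topology classification uses the canonical CD band signs: parallel G4s show
a positive band near 262 nm with a negative band near 245 nm; antiparallel
G4s a positive band near 295 nm with a trough near 232 nm. Band values are
means over ±3 nm windows and must exceed a configurable magnitude threshold
(default 1 mdeg); anything else is `undetermined`.

## Thermodynamics and saturation design

ΔG = −RT ln K with R = 8.314 J/(mol·K) and 25 °C taken as 298.15 K, in
kJ/mol. Selectivity between partners is the ratio K_a/K_b with
ΔΔG = −RT ln(K_a/K_b); a 50-fold ratio at 298.15 K is −9.70 kJ/mol by this
closed form (a "~50-fold / −10.0 kJ/mol" pairing is only consistent for an
unrounded ratio near 56 — the arithmetic here is left exact rather than
reconciled to rounded headline numbers). "Saturation" is interpreted as
receptor **site occupancy** (bound sites / 2·R_tot for the 2:1 models); the
ligand-bound fraction is reported alongside. `design_saturation` inverts the
monotone occupancy-vs-equivalents curve by bisection, with a 10⁴-equivalent
cap beyond which a target is declared unreachable.

## Synthetic data

The generators emulate the standard experimental designs:

* **Titrations** — 125 μM fixed observed species, titrant from 0 to 2
  equivalents in 12 steps, duplicate runs, one monitored aromatic-proton
  trace (δ_free 7.300 ppm, full-binding excursion −0.120 ppm), i.i.d.
  Gaussian shift noise of 0.002 ppm, statistical 2:1 truth with
  k = 5×10³ M⁻¹. The truth constants are synthetic, order-of-magnitude
  plausible values in the 10³–10⁵ M⁻¹ band typical of weak peptide–RNA
  association.
* **Melt curves** — ellipticity every 0.2 °C from 5 to 95 °C (451 points),
  5PL truth, Gaussian noise 0.2 mdeg. The study bundle's design matrix is
  seven loop-variant G4 sequences × three conditions (control, 16
  equivalents of peptide, added K⁺), with true Tm values spanning
  stabilizing and destabilizing shifts so the pipeline's sign recovery is
  exercised in both directions.
* **Spectra** — a four-band Gaussian template sufficient to exercise the
  topology classifier.

One global integer seed fans out to per-series substreams keyed by a stable
CRC-32 hash of the sample label, so adding or removing a series never
changes another's noise, and bundles are byte-identical per seed.

What the generators do **not** emulate: heteroscedastic or correlated
noise, baseline drift and sloping plateaus, dilution, slow/intermediate
exchange lineshapes, wavelength-resolved CD band shapes, or concentration
errors. Passing the recovery suites therefore demonstrates correctness of
the estimators under the assumed observation models, not robustness to
every artefact of real instrument data.

## Problem sizes used in the validation suites

The Monte-Carlo studies use 100 simulated datasets per study (titration
recovery, model selection, melt-curve recovery) and 10⁴ random systems for
the speciation error bounds; these sizes give stable pass/fail margins for
the stated thresholds while keeping the full validation run to a few
seconds on one CPU.

## Known limitations

* Stoichiometries beyond 2:1, kinetics, activity/ionic-strength corrections
  and ITC analysis are out of scope.
* The full 2:1 model's two bound shifts can be nearly collinear on weakly
  curved isotherms; its standard errors are then large, which the AICc
  ranking correctly penalizes.
* Tm is only reported when the half-denaturation point lies inside the
  measured temperature window; strongly truncated transitions are rejected
  rather than extrapolated.
* Van 't Hoff ΔH/ΔS extraction from melt curves is deliberately not
  implemented.
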