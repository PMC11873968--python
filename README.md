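# afhdx

Analysis pipeline for **anion-facilitated hydrogen–deuterium exchange
(AF-HDX)** studies of β-hairpin peptides: quantifying how weakly-binding
Hofmeister anions (Cl⁻, ClO₄⁻, ReO₄⁻, …) denature a small hairpin, and
mapping *where* on the peptide they act, from peak-level NMR observables.

## Who this is for

Groups studying ion-specific (Hofmeister) effects on peptide stability with
solution NMR. The experimental design the package supports:

* a 12-mer β-hairpin recipient (e.g. Ac-RWVTVNGOKILQ-NH₂; O = ornithine)
  with a Type-1′ turn and a Trp/Lys cation–π folding core;
* a cystine-bridged macrocycle of the same sequence as the **fully folded**
  reference, and capped 6-mer half peptides as the **fully unfolded**
  references;
* salt titrations (0–650 mM) at pH 2.3, where amide exchange is
  hydronium-catalysed, monitored by ¹H chemical shifts and by per-residue
  HDX decays.

## What it computes

**Fraction folded.** Treating folding as two-state, the diastereotopic
CαH₂ splitting of the turn glycine (G7) is a global reporter:

    F = (δ_obs − δ_0) / (δ_100 − δ_0)

with δ₀ the half-peptide splitting and δ₁₀₀ the macrocycle splitting.
Salt-induced unfolding is reported in percentage points, `(F_0 − F_salt)·100`,
with first-order error propagation throughout.

**Δδ maps.** Per-residue amide N–H chemical-shift perturbation maps
(downfield = positive, rendered blue; upfield red), after internal
referencing against the N-terminal acetyl methyl to remove bulk
ionic-strength drifts.

**HDX rate fits.** Per-residue pseudo-first-order exchange rates from
weighted least-squares fits of `I(t) = b + (I₀ − b)·e^(−kt)` with a
non-negative floor; residues exchanging too fast or too slow to measure are
censored and reported as bounds. EX2 protection factors `PF = k_int/k_obs`
close the loop with the forward model.

**AF-HDX maps.** The headline statistic: per-residue percentage rate change

    %Δk = (k_salt − k_0) / k_0 × 100

with propagated errors, z-style significance calls (default 2σ, labelled,
no multiple-testing correction by default), and region summaries over the
terminal half {1,2,3,10,11,12} vs the turn half {4–9} of the hairpin —
the contrast that distinguishes terminal anion chelation from
intercalation into the cation–π-hydrophobic core.

**Weak binding constants.** Per-residue 1:1 fast-exchange isotherm fits
(exact binding quadratic, never the ligand-excess shortcut) give a
residue × anion Kₐ matrix with per-anion averages. Because the affinities
are weak (Kₐ ≈ 0.3–3.5 M⁻¹), fits whose Kₐ–Δδ_max confidence region is
unbounded along the product ridge are flagged `weak_binding_degenerate`
and excluded from averages.

**Synthetic data.** `afhdx.synthetic` is a first-class forward model —
thermodynamic linkage (anion binds the open state, so salt unfolds the
hairpin: `f_F = K_fold/(K_fold + 1 + Kₐ[A])`) plus EX2 exchange with
per-residue protection and bound-state deprotection — that generates every
input table with known ground truth. All statistical guarantees of the
analysis are validated against it.

## Worked example

```python
import numpy as np
from afhdx import synthetic as syn
from afhdx.constructs import Condition, ATOM_REPORTER_SPLIT
from afhdx.folding import fraction_folded
from afhdx.kinetics import fit_rate_table
from afhdx.ratemap import build_map, region_summary

params = syn.default_params()               # 79%-folded hairpin, weak anion binding
base = Condition()                          # 50 mM phosphate, pH 2.3, no salt
salt = Condition(anion="ReO4", concentration_mM=230)

# fraction folded from the Gly7 CaH2 splitting
table = syn.simulate_shift_table(params, base, seed=1)
split, _ = table.get(7, ATOM_REPORTER_SPLIT)
ff = fraction_folded(split, params.reporter_split_U, params.reporter_split_F)
print(f"fraction folded (baseline): {ff.value:.3f} +/- {ff.sigma:.3f}")

# AF-HDX map for a charge-diffuse anion intercalating into the core
p_salt = syn.scenario_params("core_intercalation", Ka_anion=3.36)
tcs0, _ = syn.simulate_hdx_timecourse(p_salt, base, syn.DEFAULT_HDX_TIMES, seed=2)
tcs1, _ = syn.simulate_hdx_timecourse(p_salt, salt, syn.DEFAULT_HDX_TIMES, seed=3)
afmap = build_map(fit_rate_table(tcs0), fit_rate_table(tcs1))
print(region_summary(afmap).round(1).to_string(index=False))
```

prints

```
fraction folded (baseline): 0.783 +/- 0.012
  region  n_residues  n_censored  mean_abs_pct  mean_pct  n_significant dominant_direction
terminal           6           0         239.5     239.5              6           increase
    turn           6           0          95.2      95.2              6           increase
```

The baseline fraction folded recovers the 79 % ground truth within its
±1.2-point propagated error. In the rate-change map, the deprotected core
residues (W2, K9, I10, L11 at +360 % to +500 %) dominate the terminal-half
aggregate, the signature of an anion prying open the cation–π-hydrophobic
core rather than chelating at the termini.

## Command line

`afhdx simulate | foldfrac | ddmap | hdxfit | afhdx | bindfit | run | report`
— thin wrappers over the library. `afhdx run --config cfg.yaml` executes
the whole chain and writes fold-fraction and percent-unfolding tables, Δδ
and AF-HDX maps (CSV + SVG bubble graphics), rate tables, the Kₐ matrix,
and a provenance log; reruns with the same config are byte-identical, and
every output embeds the config hash.

## Layout

```
src/afhdx/constructs.py   peptide constructs, conditions, shift tables
src/afhdx/synthetic.py    linkage + EX2 forward model (ground-truth generator)
src/afhdx/folding.py      fraction folded, percent unfolding, Δδ maps
src/afhdx/kinetics.py     exponential HDX rate fits with censoring
src/afhdx/ratemap.py      AF-HDX %Δk maps, significance, region summaries
src/afhdx/binding.py      1:1 isotherm fits, Kₐ matrix, degeneracy detection
src/afhdx/io.py           delimited text formats (documented headers/units)
src/afhdx/pipeline.py     end-to-end orchestration, config, provenance
src/afhdx/plotting.py     bubble-map SVG rendering
src/afhdx/cli.py          command-line interface
docs/methods.md           model assumptions, parameters, limitations
```
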