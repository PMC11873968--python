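# Methods

## The physical model

### Two-state folding and the global reporter

The hairpin is treated as a two-state system, folded (F) ⇌ unfolded (U),
with equilibrium constant `K_fold = [F]/[U]` at zero added salt. Any
fast-exchange observable is then a population-weighted average of its
folded- and unfolded-state values. The splitting of the diastereotopic
CαH₂ protons of the turn glycine is used as the global reporter because
its two endpoint values are directly measurable: the macrocyclic construct
pins the folded endpoint (`δ_100`) and the 6-mer half peptide pins the
unfolded endpoint (`δ_0`, near zero but *measured*, never hard-coded).
`fraction_folded` is the linear interpolation between those endpoints with
first-order propagation of all three shift errors. Estimates outside
[0, 1] by more than 0.05 are flagged rather than clamped. The fit refuses
to proceed when the two references are closer than three combined sigmas —
a collapsed denominator means the references carry no information.

Percent unfolding is defined as the **percentage-point decrease in
fraction folded**, `(F_baseline − F_salt)·100`, not a relative change;
this keeps a 79 %-folded peptide that loses 11 points at a physically
sensible 68 %.

### Linkage: why salt unfolds the hairpin

The generator couples folding to anion binding with the simplest topology
that reproduces salt-induced unfolding: the anion binds the open (unfolded)
state at a single site with association constant `Ka` (M⁻¹), giving

    f_F([A]) = K_fold / (K_fold + (1 + Ka·[A])^n)

with `n = 1` by default (`n_sites` exposes the multi-site extension).
Binding to the folded state is represented only by an optional
`bound_shift` term on observed shifts, defaulted to zero: whether
folded-state binding contributes shifts independently of unfolding cannot
be separated with these observables, so the default attributes all shift
response to the folding equilibrium.

A consequence worth knowing: under this linkage, a salt titration of any
residue's shift follows a 1:1 isotherm in the ligand-excess limit with
apparent constant `Ka/(1 + K_fold)`. The titration series the study
bundle emits for binding analysis are therefore generated directly from
the exact 1:1 quadratic with a stated per-residue truth `Ka`, keeping the
binding-fit validation loop closed and exact.

### EX2 exchange

Amide exchange is modelled in the EX2 limit (opening/closing fast relative
to intrinsic exchange — appropriate at pH 2.3 where base catalysis is
suppressed and observed rates sit on the min⁻¹ scale):

    k_obs = k_int · [ (1 − f_F)·((1 − f_b) + f_b·d) + f_F / PF ]

where `PF ≥ 1` is the per-residue protection factor of the folded state,
`f_b = Ka[A]/(1 + Ka[A])` the anion-bound fraction of the open population,
and `d ≥ 1` a per-residue deprotection multiplier for bound open states —
the knob that encodes *where* a bound anion facilitates hydronium access.
Two mechanistic presets exercise the mapping problem: `terminal_chelation`
deprotects residues {1, 12} (a charge-dense anion chelated by the terminal
amide pincer) and `core_intercalation` deprotects {2, 9, 10, 11} (a
charge-diffuse anion prying open the cation–π-hydrophobic core).

### Intrinsic rates

The intrinsic-rate law is deliberately simple: a reference rate
(0.5 min⁻¹ for an alanine-context amide at pH 2.3), acid-catalysis slope
of exactly +1 in log₁₀(k) toward lower pH, a packaged per-residue
side-chain context table (β-branched and bulky residues slow exchange,
glycine accelerates; geometric mean of the left-neighbour and own-residue
factors; an N-terminal factor of 2 replaces the absent left neighbour),
and a weak Arrhenius factor (17 kJ/mol) that is unity at 298.15 K. This
produces plausible per-residue *spreads*, which is all the generator
needs; it is not a reference-grade intrinsic-rate compilation and should
not be used as one.

## Estimators and numerical choices

### Exponential rate fits

`I(t) = b + (I₀ − b)e^(−kt)` with `b ≥ 0` absorbing residual protonated
solvent signal. Weighted least squares with fractional errors
(σᵢ = σ·max(Iᵢ, 0.05·max I); the relative floor keeps near-zero points
usable and makes the fit exactly scale-equivariant). Time is normalised
internally to the sampling window, so rates are exactly covariant under a
change of time units. Initialisation is a deterministic log-linear
regression on points above the floor, with five multiplicative restarts;
σ_k comes from the curvature of the weighted objective at the optimum,
scaled by reduced χ² but never *below* the stated-noise covariance (the
one-sided scaling keeps ±2σ intervals honest when a draw happens to fit
well: measured coverage is ~97 % rather than the ~88 % obtained with
symmetric rescaling).

Censoring rules, applied before anything else is reported:

* **too fast** — first post-mixing intensity already below 0.2: report the
  lower bound `−ln(0.2)/t₁`, no point estimate;
* **too slow** — fitted decay amplitude over the sampled window smaller
  than 3× the intensity noise: report the upper bound
  `−ln(1 − 3σ)/t_span`.

Censored fits carry NaN σ, never produce significance calls downstream,
and are logged in the pipeline provenance.

### AF-HDX maps

`%Δk = (k_salt − k_0)/k_0 × 100` with first-order propagation treating the
two fits as independent (the conditions are measured on separate samples).
Significance is a plain z-style criterion, |%Δk| > m·σ with m = 2 by
default and a **strict** inequality (the boundary case is not
significant); the output labels it as a propagated-error criterion, not a
formal test. No multiple-testing correction is applied by default — with
12 residues this is descriptive mapping — but a Benjamini–Hochberg layer
is available and records itself in the map notes when used. First-order
propagation of a ratio is accurate to within ~3 % of a 10⁵-draw
Monte-Carlo for the relative errors these fits produce (≲10 %); it
degrades if σ₀/k₀ grows far beyond that regime.

### Binding fits

The 1:1 fast-exchange isotherm uses the exact physical root of the binding
quadratic in total concentrations (residual < 1e-12; the ligand-excess
approximation is kept only as a cross-check in tests). Fitting is
(Ka, Δδ_max, δ_free) weighted least squares, seeded deterministically by a
coarse 61-point log-grid scan in Ka with the two amplitude parameters
solved exactly (they are linear given Ka). Degeneracy is flagged when

* the fitted saturation product `Ka·G_max < 0.1`, or
* the Ka profile (amplitudes re-solved at each grid point) rises by less
  than 1 χ²-unit across a decade centred on the optimum, or
* the curvature matrix yields no finite σ(Ka).

Degenerate cells stay visible in the Kₐ matrix but are excluded from
per-anion averages, with the exclusion count reported. Calibration under
the default study conditions (12 titration points to 650 mM, σ_δ =
0.005 ppm, residue-typical amplitude ≈ 0.2 ppm): the flag fires in ~98 %
of `Ka·G_max = 0.01` replicates and ~0 % at `Ka·G_max = 1`. The Wald ±2σ
interval on Ka is mildly anticonservative for this skewed estimator
(measured coverage ~91–94 % at the preset affinity), which is why the
degeneracy flag, not the σ, is the identifiability statement.

### Referencing and Δδ maps

Internal referencing subtracts the acetyl-methyl drift so the reference
lands exactly on its baseline position; the operation is idempotent, the
reference row is preserved for audit, and corrections larger than 0.1 ppm
warn (likely mis-assignment). Δδ maps use the convention downfield =
larger δ = positive Δδ (blue; upfield red), residues are matched through
explicit construct alignments (N-half → 1–6, C-half → 7–12, stated in
metadata, never inferred from 6-mer sequence overlap), and a residue
present on one side only is emitted as `missing`, never dropped. Bubble
areas are proportional to |Δδ| with the area scale exposed as a parameter
(per-figure maximum by default, settable for cross-figure comparison).

## The synthetic study and what passing means

The default preset mirrors the regime of interest: baseline fraction
folded 0.79, per-anion Ka of 0.37 / 1.5 / 3.36 M⁻¹ (charge-dense to
charge-diffuse), salt grid 0–650 mM with the HDX contrast at 230 mM,
shift noise 0.005 ppm (additive, peak positions), intensity noise 2 %
(multiplicative, peak heights), protection factors 2–100 placing observed
rates in ~0.07–0.4 min⁻¹, and a 12-point HDX sampling schedule from 1 to
960 min. Problem sizes in the validation runs — 500 replicates for
coverage statistics, 200 for scenario discrimination and flag calibration,
10⁴-point grids and 10⁵ Monte-Carlo draws for the oracles — were chosen
as the smallest sets that make the binomial uncertainty on each pass/fail
proportion comfortably smaller than its margin.

What the generator does **not** emulate: spectral reality (no lineshapes,
overlap, phasing or baseline artefacts — peak picking is assumed solved),
EX1 or bimodal exchange, activity effects at high ionic strength (internal
referencing is the only ionic-strength correction, matching the
experimental treatment), buffer-anion competition, and any direct
structural readout of binding poses. Passing tests therefore demonstrate
that the estimators recover the stated model's truth under realistic
peak-level noise — not that the model captures every feature of real
spectra.

## Known limitations

* Fraction-folded errors are first-order; near the reference-collapse
  guard the linearisation degrades (the guard exists for this reason).
* The EX2 closure `PF = k_int/k_obs` inherits the simplified intrinsic-rate
  law; absolute PF values are model-relative.
* Per-residue binding fits ignore that all residues report the same
  binding event; the global shared-Ka fit is provided for that purpose and
  both outputs are labelled.
* Censored-rate bounds propagate as flags, not as interval arithmetic,
  through the AF-HDX map.
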