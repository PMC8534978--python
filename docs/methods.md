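# Methods

## Thermochemistry

Homolytic bond-dissociation enthalpies are computed directly from
tabulated species enthalpies, `BDE = H(radical) + H(H·) − H(parent)`,
after converting every term to kJ/mol. The energies are treated as
enthalpies at the source's implicit standard state; no zero-point or
thermal corrections are applied, because none are available for the
packaged tables. The hartree → kJ/mol factor is fixed at **2625.4996**
(`oxikin.constants.HARTREE_TO_KJ_PER_MOL`); the packaged hartree-valued
energies only reproduce their published kJ/mol BDEs (353.92, 353.72) with
a factor of ≈2625.5, which pins the convention.

A negative or zero BDE is physically meaningless for homolysis of a
stable parent but useful for exercising validation, so it warns instead
of failing. Site ranking is ascending by BDE with lexicographic
tie-breaking on the bond label, making the order deterministic.

The frontier-orbital gap is the bare subtraction E(LUMO) − E(HOMO) in
kJ/mol. Its interpretation (smaller gap ⇒ less stable, more reactive
radical) is documented but not enforced; the published gap value for the
carnosic-acid radical (525.21 kJ/mol) cannot be recomputed here because
the underlying orbital energies were never tabulated, so only the
arithmetic contract is tested.

## Rancimat kinetics

The induction period is inverted to an effective first-order rate
constant, k = 1/IP (h⁻¹), and two linearizations are fitted by unweighted
ordinary least squares (no weighting scheme is defensible for 4-point
tables):

* Arrhenius: ln k on x = 1000/T (K). Eₐ = −slope × R (kJ/mol directly,
  because the abscissa carries the factor 10³), ln A = intercept.
* Eyring/ACT: ln(k/T) on x = 1000/T. ΔH = −slope × R,
  ΔS = (intercept − ln(k_B/h)) × R.

**Abscissa convention.** x = 1000/T is the default and is recorded in
every fit object. Published slopes of magnitude ~6–8 for activation
energies of ~50–66 kJ/mol are only consistent with this scaling; fitting
against 1/T would change slopes by 10³ and silently corrupt any
downstream comparison.

**ln(k_B/h).** The default is the tabulated reproduction value **21.46**.
This matches neither the SI s⁻¹ value, ln(1.380658×10⁻²³/6.6260755×10⁻³⁴)
= 23.76, nor an h⁻¹-converted value (≈31.95). Published ΔS values in this
field are frequently only reproducible with 21.46, so it is kept as the
compatibility default, exposed alongside `LN_KB_OVER_H_SI`, and every use
of the default is logged as a warning. The choice shifts ΔS by a constant
(R × Δln(k_B/h) ≈ 19 J mol⁻¹ K⁻¹) and nothing else.

Temperature input is °C or K via an explicit unit column — never
autodetected, since Rancimat temperatures (100–130) are ambiguous.
Replicates at one temperature enter the OLS as individual points.
Fewer than 2 distinct temperatures is an error; 2 fits but warns.

Note on Eₐ vs ΔH: for these data the two differ by ≈ R·T̄ ≈ 3.2 kJ/mol, as
transition-state theory predicts, but the package fits them independently
and asserts no relation between them.

## Isoconversional DSC kinetics

Only peak-temperature (fixed-conversion) analysis is implemented: the
conversion at the exotherm peak is assumed constant across heating rates,
so the model-free linearizations apply without integrating a full α(T)
model (which would require thermogram data the instruments' peak tables
do not carry):

* FWO: log₁₀ β on 1000/Tp, Eₐ = −slope × R / 0.4567.
* KAS: log₁₀(β/Tp²) on 1000/Tp, Eₐ = −slope × R / 0.4343.

`lg` is log₁₀ throughout — the KAS constant 0.4343 = 1/ln 10 fixes this —
and no natural-log variant is offered, to make a silent constant mismatch
impossible. β stays in K/min; its unit only shifts the intercept, never
the slope, so Eₐ is unit-independent. The two methods use different
approximations to the temperature integral and systematically disagree by
several kJ/mol on the same data (here ~6 kJ/mol, ~12%); the sample
*ranking* is the robust output, and a property test asserts the two
methods agree within 15% and rank identically.

## Radical scavenging

SR% = (A₀ − A₁)/A₀ × 100. The assay label (DPPH at 517 nm, ABTS at
734 nm) is metadata; the arithmetic is identical. IC50 defaults to linear
interpolation between the first pair of consecutive ascending
concentrations bracketing 50% — the simplest defensible estimator when
the original estimation convention is unknown — with a four-parameter
logistic (4PL) fit available for smooth curves. The 4PL route reports the
concentration where the *fitted curve* crosses 50%, which coincides with
the fitted midpoint parameter only for symmetric curves (bottom + top =
100). Curves whose measured SR never crosses 50% are rejected rather than
extrapolated; non-monotonic curves warn.

## Synthetic data

Each generator is the exact right-inverse of its fitter, which is what
makes zero-noise round-trip tests meaningful:

* **Rancimat**: IP(T) = exp(Eₐ/(RT) − ln A) · ε with ln ε ~ N(0, σ²).
  Noise is multiplicative lognormal because induction periods are
  positive and their errors plausibly proportional; no error model was
  ever published for such data. Default grid: 100, 110, 120, 130 °C (the
  standard accelerated-oxidation range). Default σ = 0.05 in the
  Monte-Carlo studies — a realistic relative scatter for replicate
  Rancimat determinations.
* **DSC peaks**: Tp(β) is obtained by solving the chosen FWO/KAS
  linearized relation itself with Brent root-bracketing on
  Tp ∈ [200, 2000] K (|residual| < 10⁻¹⁰). The fits only ever see (β, Tp)
  pairs, so generating from the linearized relation is sufficient and
  exactly invertible; no reaction model is simulated. Default β grid:
  5, 10, 15, 20 K/min.
* **Dose-response**: a Hill curve SR(c) = SRmax·c^h/(IC50^h + c^h) plus
  Gaussian noise, rendered as absorbance pairs with the control fixed at
  A₀ = 0.700 (the standard ABTS working absorbance).

What the generators do *not* emulate: radical chain chemistry,
conductivity traces, DSC thermogram shapes, inter-laboratory systematic
error, or correlated replicate structure. Passing round-trip tests
therefore demonstrates that the estimators invert their assumed models
correctly and without bias — not that real Rancimat or DSC data satisfy
those models.

All randomness flows through `numpy.random.default_rng(seed)`; a fixed
seed reproduces tables exactly.

## Numerical and design choices

* OLS via `scipy.stats.linregress`; R² is the ordinary coefficient of
  determination. Degenerate abscissa (zero variance) is an error.
* Problem sizes: 4 temperatures × 1–3 replicates, 4 heating rates, 5–7
  concentrations, 200 Monte-Carlo seeds — matching the scale of the real
  experiments these stages model; the entire suite runs in seconds.
* All constants live in `oxikin.constants` and are echoed into every
  pipeline report together with SHA-256 digests of the input files, so
  any reported number is traceable to its inputs and conventions.
* CSV validation is strict: missing columns, unparseable numbers, unit
  typos and decimal commas are errors naming the row and column; nothing
  is guessed.
* The published Eyring equations appear in a source ordering that
  conflicts with the tabulated R²/ΔH pairing; the packaged
  `regression_lines` table follows the tabulated pairing (the middle line
  belongs to TBHQ+OA).

## Limitations

* No electronic-structure computation: species enthalpies are inputs.
  Consequently the package can rank sites and reproduce BDEs from tables
  but cannot generate them.
* No induction-period detection from conductivity curves, no DSC peak
  picking, and no conversion-resolved isoconversional analysis.
* The published half-scavenging concentrations (10.50/15.50 µg/mL DPPH,
  17.11/13.14 µg/mL ABTS for CA/TBHQ) cannot be recomputed because the
  underlying absorbance tables were never released; the IC50 estimators
  are validated on synthetic curves only.
* k = 1/IP treats oxidation onset as a single effective first-order
  process; the derived Eₐ, ΔH, ΔS are apparent parameters of that
  simplification, not elementary-step quantities.
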