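# oxikin

Desk-side kinetics of lipid autoxidation and its inhibition by phenolic
antioxidants. The package covers the complete computational chain used to
compare a natural antioxidant (carnosic acid, CA — a diphenol diterpenoid
from rosemary) against a synthetic one (tert-butylhydroquinone, TBHQ) in
protecting oleic acid (OA) from thermal oxidation:

1. **Thermochemistry** — homolytic bond-dissociation enthalpies from
   tabulated quantum-chemical species enthalpies,
   `BDE = H(radical) + H(H·) − H(parent)`, with strict hartree ↔ kJ/mol
   unit handling, plus frontier-orbital (HOMO–LUMO) gaps. A lower phenolic
   O–H BDE than the lipid's allylic C–H BDE is the thermodynamic signature
   of a one-step hydrogen-atom-transfer (HAT) antioxidant.
2. **Rancimat kinetics** — induction periods IP(T) from accelerated
   oxidation become effective rate constants k = 1/IP (h⁻¹); ordinary
   least squares on `ln k = ln A − Eₐ/(RT)` (Arrhenius) and
   `ln(k/T) = ln(k_B/h) + ΔS/R − ΔH/(RT)` (Eyring / activated-complex
   theory) gives Eₐ, ln A, ΔH, ΔS.
3. **Isoconversional DSC kinetics** — apparent activation energies from
   peak temperatures Tp at several heating rates β via the model-free
   Flynn–Wall–Ozawa (`lg β = −0.4567 E/(R Tp) + C₁`) and
   Kissinger–Akahira–Sunose (`lg(β/Tp²) = −0.4343 E/(R Tp) + C₂`)
   linearizations.
4. **Radical scavenging** — DPPH/ABTS scavenging rates
   `SR% = (A₀ − A₁)/A₀ × 100` and IC50 by linear interpolation or a
   four-parameter logistic fit.
5. **Synthetic data** — seeded generators that are exact right-inverses of
   the fitters, so every stage is testable end-to-end without laboratory
   data.

All linear fits use the abscissa x = 1000/T (K) and R = 8.314 J mol⁻¹ K⁻¹,
so a slope times R is an activation energy in kJ/mol; every fit object and
report records these conventions.

It is intended for food chemists and thermal-analysis practitioners who
have induction-period, DSC-peak, or absorbance tables (the instruments'
summary outputs) and want activation parameters and IC50s with traceable
constants, not spreadsheet arithmetic.

## Worked example

Reference species enthalpies for CA, OA, their radicals and the hydrogen
atom ship with the package:

```bash
oxikin bde --species "$(python -c 'from oxikin.datasets import path_for; print(path_for("species_energies"))')" \
       --parent CA --hydrogen H-atom
```

```json
[
  {"bond_label": "CA-O18-radical", "parent_label": "CA",
   "radical_label": "CA-O18-radical", "bde_kj_mol": 295.63},
  {"bond_label": "CA-O15-radical", "parent_label": "CA",
   "radical_label": "CA-O15-radical", "bde_kj_mol": 303.27}
]
```

The O(18)–H hydroxyl (295.63 kJ/mol) is CA's most active hydrogen-donation
site; both phenolic O–H bonds sit ~50–60 kJ/mol below OA's allylic C–H
bonds (353.72 and 353.92 kJ/mol), so CA intercepts the radical chain
before the lipid's own hydrogens are abstracted.

The same chain from the Python API, on synthetic Rancimat data:

```python
from oxikin import generate_rancimat, rate_constants, arrhenius_fit

ip = generate_rancimat(ea_kj_mol=66.29, ln_a=20.55)   # 100-130 °C grid
fit = arrhenius_fit(rate_constants(ip), "synthetic")
print(f"Ea = {fit.ea_kj_mol:.2f} kJ/mol, R² = {fit.r_squared:.4f}")
# Ea = 66.29 kJ/mol, R² = 1.0000
```

The numbered scripts under `analysis/` run each stage on its in-repo
inputs and write tables to `results/`: site ranking (`01`), Arrhenius and
Eyring parameters for OA, CA+OA and TBHQ+OA (`02`: Eₐ 50.59 → 57.32 →
66.29 kJ/mol — carnosic acid raises the oxidation barrier more than
TBHQ), FWO/KAS activation energies with the method-invariant stability
order CA+OA > TBHQ+OA > OA (`03`), IC50 estimation on synthetic
dose-response curves (`04`), and Monte-Carlo parameter-recovery
diagnostics (`05`).

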