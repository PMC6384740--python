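# albind

Analysis of small-molecule binding to human serum albumin (HSA) from
fluorescence, circular dichroism and FT-IR spectroscopy — built for
binding-interaction studies where two drugs may compete for, or
cooperatively share, Sudlow's Site 1 of the protein.

HSA carries a single tryptophan (Trp214) inside Site 1 whose fluorescence
reports on site occupancy. The package implements the desk-side half of a
typical titration study:

- **Signal corrections** — buffer-background subtraction and the
  inner-filter correction F_cor = F_obs·10^((A_ex+A_em)/2), followed by
  window integration of the emission band (10 nm around the maximum).
- **Stern–Volmer analysis** — F₀/F = 1 + K_SV·[Q] fitted over the first
  seven titration points; the bimolecular constant k_q = K_SV/τ₀
  (τ₀ = 10⁻⁸ s for Trp); quenching-mechanism classification (static /
  dynamic / combination) from the temperature dependence of K_SV, with a
  diffusion-limit flag at k_q > 2×10¹⁰ M⁻¹s⁻¹.
- **Binding constants with ligand depletion** — the exact 1:1 mass-balance
  free-ligand solution
  L_free = ½[(L_t−P_t−K_D) + √((L_t−P_t−K_D)² + 4·K_D·L_t)],
  a two-state signal model F/F₀ = 1 + (r_sat−1)·L_free/(L_free+K_D)
  fitted by trust-region least squares, ΔG = −RT ln(c⁰/K_D), and
  binary-vs-ternary affinity comparison (competitive displacement vs
  cooperative enhancement).
- **Circular dichroism** — mean residue ellipticity
  MRE = θ/(10·n·c·l) and the α-helix estimate
  α% = −(MRE₂₀₈ − 4000)/(33000 − 4000)×100; near-UV difference spectra
  summarized over the Tyr (275–287 nm) and Trp (285–305 nm) windows.
- **FT-IR amide I decomposition** — second-derivative-seeded sum-of-Gaussians
  fitting of the 1600–1700 cm⁻¹ region with configurable secondary-structure
  assignment rules (random coil / α-helix / β-turn).
- **Synthetic data** — forward models of every experiment above with known
  ground truth (the `albind.synth` module), standing in for instrument data.

## Worked example

Simulate a noise-free quercetin-into-HSA titration (5 μM protein,
0–83.3 μM ligand, generative K_D = 6.48 μM) and refit it:

```python
from albind import (TitrationScenario, simulate_titration,
                    build_quenching_curve, system_from_curve, fit_binding)

scenario = TitrationScenario(k_d=6.48e-6, noise_sd=0.0,
                             absorbance_per_molar=(12000.0, 3000.0))
series = simulate_titration(scenario)
curve = build_quenching_curve(series)          # F0/F, inner-filter corrected
fit = fit_binding(system_from_curve(curve, scenario.p_total))
print(f"K_D = {fit.K_D * 1e6:.2f} uM, dG = {fit.delta_g:.3f} kJ/mol")
```

prints

```
K_D = 6.48 uM, dG = -30.806 kJ/mol
```

i.e. the fit recovers the generative dissociation constant exactly and the
standard Gibbs free energy of binding at 310.15 K is −30.8 kJ/mol
(spontaneous association). The same path from the shell:

```bash
albind simulate --ligand quercetin --noise-sd 0 --out sim
albind bind sim/quercetin.yaml
```

## Analysis scripts

`analysis/` holds the numbered end-to-end study over simulated data; each
script prints what it finds and writes tables under `results/`:

1. `01_simulate_experiments.py` — generate all datasets (titrations at
   three temperatures, ternary pairs, CD triplicates, IR spectra)
2. `02_stern_volmer.py` — quenching constants and mechanism calls
3. `03_binding_thermodynamics.py` — K_D and ΔG table
4. `04_ternary_comparison.py` — binary vs ternary affinity calls
5. `05_cd_helix.py` — α-helix content across molar ratios
6. `06_ftir_bands.py` — amide I decomposition and assignment

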