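# Methods

## Model formulation

A proteome-constrained model extends a stoichiometric network with the life
cycle of every protein.  For a growth rate μ (a parameter, not a variable)
the constraint system is linear in the metabolic fluxes *v*, the per-protein
synthesis and degradation fluxes, and the enzyme levels *e* (mmol/gDW):

* **Mass balances.**  Every internal metabolite is balanced, including the
  amino-acid precursor and the energy carrier.  Protein synthesis consumes
  `L` residues and `2(L−1) + c_init + c_scan·UTR` ATP-equivalents per chain
  (`c_init = 1`, `c_scan = 0.05`/nt); degradation returns all residues and
  costs 1 ATP per residue.  These constants collapse aminoacylation,
  translocation, initiation-factor scanning and proteasomal unfolding into
  documented per-residue lump sums; each is a module-level constant in
  `pc_builder`.
* **Lifecycle.**  `v_syn,i − v_deg,i − μ·e_i = 0` with
  `v_deg,i = k_deg,i·e_i`.  Dilution by growth is the `μ·e_i` term —
  implicit rather than a separate pseudo-flux, which saves variables without
  changing semantics.
* **Catalysis.**  One rule per catalysed reaction, `v = s·kcat·e`, as an
  equality: enzymes work at maximal rate, so the model computes *minimal*
  required expression.  The saturation factor `s ∈ (0,1]` on the glucose
  transporter is the control parameter that emulates external substrate
  availability without kinetics; the residual substrate concentration is
  recovered as the inverse Michaelis relation `c = s·Km/(1−s)` (default
  Km = 1 mM).
* **Ribosomes.**  Total elongation flux is capped by
  `σ(1−f_inactive)·k_el·e_R`, separately for the cytosolic and the
  mitochondrial ribosome pool.  A protein located in a mitochondrial
  compartment that was not imported is, by inference, mitochondrially
  translated.
* **Compartment pools.**  Volumetric pools constrain protein mass
  (capacities in g per g total protein, converted with the reference protein
  content `protein_per_gdw = 0.46 g/gDW`); membrane pools constrain area
  (capacities in μm²/cell, converted with `cells_per_gdw = 6.7×10¹⁰`,
  i.e. 15 pg dry mass per cell).  Membrane specific areas default to
  1.32×10¹³ μm²/mmol per residue (≈0.022 nm² per residue per molecule).
  Complex subunits are lumped stoichiometrically (`e_sub = n·e_complex`) and
  count toward the complex's compartment.  The inner mitochondrial membrane
  is treated as area-based; a mass-based variant is available by switching
  the compartment kind.
* **Cytosolic density.**  The cytosol row is an *equality*: vacant space is
  filled by the unspecified protein (UP), which has average composition and
  a minimum expression level `m_UP ≥ f_min · Σ m_i e_i` relative to the
  (variable) total protein mass.  This coupling is what lets protein
  expressed anywhere in the cell claim cytosolic space, and is the mechanism
  behind condition-dependent overflow below.
* **Mitochondrial import.**  `Σ v_syn,imported ≤ k_import·e_importer`, the
  importer being an inner-membrane complex competing for membrane area.

## Solving

Feasibility is monotone in μ on the models generated here, so the maximal
growth rate is located by bisection (default bracket [0, 1] h⁻¹, tolerance
10⁻⁴ h⁻¹, ≤ 40 iterations; if the upper bracket is feasible it is widened
once to 4×).  LPs are solved with HiGHS via `scipy.optimize.linprog`
(primal/dual tolerances 10⁻⁹), deterministically.  At the accepted μ a
lexicographic refinement resolves degeneracy: minimise substrate uptake
(the chemostat convention of minimal glucose consumption at fixed dilution
rate), then minimise total protein synthesis mass.  This yields the unique
minimal-proteome solution whose pathway mass fractions are compared with
proteomics.  Pool occupancies are Σw·e/capacity, clamped to [0,1] within
10⁻⁶; the density pool reports occupancy *excluding* UP above its minimum,
so 1 means "no free UP slack".  A pool is called active when its occupancy
is ≥ 1−ε (default ε = 10⁻³) or its capacity row has |dual| > 10⁻⁸.

## The reduced yeast cell and its calibration

The packaged fixture lumps central carbon metabolism into eight reactions
(hexose transport, glycolysis, fermentation, pyruvate oxidation + TCA,
oxidative phosphorylation at P/O = 1, amino-acid synthesis, non-protein
biomass synthesis, free O₂ diffusion) catalysed by 12 proteins over four
pools.  Carbon is balanced exactly (glucose C6, residue C5 with one CO₂
released per residue synthesised, carbohydrate lump C6), so every reported
solution closes its carbon balance to rounding error.  Lump lengths
(glycolysis 5000 aa, respiratory complex 5000 aa across two subunits,
ribosome 12000 aa, …) and kcats were chosen so minimal pathway mass
fractions fall in the physiological range (ribosome ≈ 16% of protein at
batch growth, respiratory proteome ≈ 10–20% when respiring).

Four parameters were then calibrated by a scripted round-robin log-secant
search (`scripts/calibrate_toy.py`) against four growth-rate anchors of
glucose-limited and sugar-batch physiology:

| knob | anchor | achieved |
|---|---|---|
| GAM (44.9 mmol ATP/g) | glucose batch μ_max 0.37–0.39 h⁻¹ | 0.377 |
| inner-membrane area (258 μm²/cell) | ethanol onset μ ≈ 0.28 h⁻¹ | 0.281 |
| cytosol capacity (0.314 g/g protein) | UP-at-minimum μ ≈ 0.35 h⁻¹ | 0.350 |
| transporter kcat (1.048×10⁵ h⁻¹) | galactose batch μ ≈ 0.16 h⁻¹ | 0.160 |

The search converged to < 1% relative error on all anchors; the values are
frozen in `Calibration` and the packaged JSON.  The respiratory kcat
(5×10⁴ h⁻¹) is fixed, not searched: it keeps respiration markedly less
proteome-efficient than fermentation (protein per unit ATP flux) while
metabolically more efficient (ATP per glucose), which drives the regime
structure: below the onset the transporter is the only full pool and pure
respiration is optimal; between 0.28 and 0.35 the inner mitochondrial
membrane is also full and the ATP shortfall overflows into ethanol; above
0.35 the cytosol is full and respiration is progressively traded for
fermentation (the predicted O₂ uptake falls).  Condition overlays change
only the three published parameters (transporter area, carbon-linked NGAM,
minimal UP fraction); on galactose the enlarged UP floor (0.49 g/g) and the
smaller transporter area make growth overflow-positive already at
0.16 h⁻¹, with the transporter and the cytosol as the active constraints.

## Synthetic data generators

* `make_self_replicator` — one self-synthesising ribosome with free
  precursors; its maximal growth rate is exactly
  `σ(1−f_inactive)·k_el/L_R`, the analytic oracle for the bisection engine.
* `make_random_model` — seeded random linear pathways (random lengths,
  kcats, degradation constants, pool capacity, UP floor).  The elongation
  rate is drawn so the ribosome-limited growth ceiling stays below 1 h⁻¹,
  keeping exhaustive grid scans over [0, 1] cheap.
* `make_synthetic_proteomics` — emulates label-free proteome fractions as
  predicted minimal fraction / assumed saturation, with multiplicative
  lognormal noise and UP absorbing the remainder.  It reproduces the shape
  of real proteomics data (undersaturated enzymes expressed above the
  minimal level) but none of its technical structure: no missing proteins,
  no shared-peptide ambiguity, no compositional correlation beyond the
  sum-to-one closure.  Passing recovery tests therefore demonstrate the
  *estimator* logic (saturation proxy, capped-biogenesis fit), not
  robustness to real measurement error.
* `make_synthetic_mito_series` — dilution-by-growth decay
  `fraction = v_syn,max/(μ+k_deg)` of a sector whose synthesis rate has
  saturated, for the capped-biogenesis least-squares fit (closed-form
  weighted solution).

## Numerical choices and degenerate inputs

Bisection tolerance 10⁻⁴ h⁻¹ (tests quote growth rates to ±few×10⁻⁴);
regime boundaries are located by bisection in the saturation control with
step tolerance 5×10⁻⁴ (ethanol threshold 10⁻⁶ mmol/gDW/h, UP-slack
threshold 10⁻⁶ g/gDW).  At μ = 0 with zero maintenance the null steady
state (all fluxes zero, cytosol filled with UP) is feasible by
construction.  An infeasible saturation point inside a sweep is flagged and
the sweep continues.  Problem sizes are small throughout (the reduced model
expands to 47 variables and 48 rows; random oracle models to ~25
variables), so the full test suite, including a 30-point sweep and a
100-model exhaustive grid-search comparison at step 10⁻³, completes in a
few minutes on one CPU.

## Known limitations

* The reduced model's batch optimum keeps the glucose transporter weakly
  co-limiting together with the full cytosol.  Consequently, under
  simulated translation inhibition the model holds glucose uptake at the
  transporter cap and substitutes fermentation for respiration as ribosomes
  crowd the cytosol: ethanol *rises* as growth falls, instead of the
  near-proportional decline of glucose, ethanol and CO₂ fluxes expected
  when a single dominant constraint is scaled.  With purely linear enzyme
  capacities the fully fermentative, cytosol-only growth ceiling lies far
  above the batch anchor, so a batch state with a slack transporter cannot
  be calibrated without losing the galactose anchor — the uptake demands of
  the two conditions then pin the same transporter pool through the fixed
  2.5× area ratio.  The corresponding acceptance test is retained and
  fails; the inhibition↔gratuitous-expression equivalence (a stalled
  ribosome fraction is exactly dead proteome of the same mass) holds to
  bisection tolerance.
* Tie-breaking among alternate optima (minimal uptake, then minimal
  synthesis mass) is a design choice; other refinements would report
  different — equally optimal — proteomes.
* The amino-acid pool is lumped into one average species (per-species mode
  is a schema option, not used by the fixture); tRNA turnover, chaperone
  cycles and misfolding are absorbed into the per-residue energy constants.
* Capacities quoted per cell (membrane areas) depend on the cells-per-gDW
  constant; it is a single calibration knob and the fixture's value
  corresponds to 15 pg dry mass per cell.  The fixed reference protein
  content ignores the growth-rate dependence of cellular protein mass.
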