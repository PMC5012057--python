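# Methods

## The model

The package centres on a core stoichiometric reconstruction of
*Clostridium thermocellum* central metabolism (64 metabolites, 76
reactions after biomass assembly). Content:

- **Sugar assimilation.** ABC transport of glucose (G1) through
  cellohexaose (G6) at one ATP per oligomer, followed by phosphorolytic
  chain shortening G(N) + Pi → G(N−1) + G1P down to glucose, whose
  phosphorylation consumes the second ATP. Total assimilation cost is two
  ATP per oligomer regardless of length, so the ATP yield per glucose
  equivalent rises with chain length — the mechanistic basis of the
  cellodextrin yield analysis.
- **Atypical glycolysis.** PPi-dependent phosphofructokinase; lumped
  GAPDH+PGK and PGM+enolase steps; no pyruvate kinase. PEP is converted by
  pyruvate:phosphate dikinase (PPDK, with adenylate kinase regenerating
  AMP) or by the malate shunt (GTP-yielding PEP carboxykinase, malate
  dehydrogenase, NADP-malic enzyme), which transhydrogenates NADH to NADPH.
- **Pyruvate node and fermentation.** PFOR (ferredoxin-reducing) and PFL
  (formate-producing) acetyl-CoA routes; PTA-ACK acetate (substrate-level
  ATP); AdhE ethanol (2 NADH); LDH lactate; a lumped valine overflow.
- **Redox and membrane energetics.** Electron-bifurcating hydrogenase
  (BIF: NADH + Fd_rd → 2 H2), energy-conserving hydrogenase (ECH),
  ferredoxin:NAD+ oxidoreductase (RNF), and NADH-dependent
  ferredoxin:NADP+ oxidoreductase (NFN, bifurcation direction only). An
  explicit translocated-proton pool couples ECH and RNF to the ATP
  synthase and the membrane pyrophosphatase.
- **Anabolism.** Lumped syntheses of an average amino acid (two reductant
  variants, NADPH-linked and NADH-linked, reflecting parallel glutamate
  dehydrogenases), protein, RNA, DNA, lipid, cell wall, solute pool, and
  lipoteichoic acid, in the measured mass fractions (0.5285 g protein,
  0.026 DNA, 0.0655 RNA, 0.076 lipid, 0.2242 cell wall, 0.00494 solutes,
  0.0304 LTA per g DCW; the printed values sum to 0.9555 and are kept as
  reported). Polymerisation releases one PPi per monomer, as aa-tRNA
  charging and NTP condensation do in vivo.
- **Biomass.** The route from precursors to 1 g DCW consumes 42.66 mmol
  ATP (the detailed bookkeeping lives in `ATPRequirementTable`) plus the
  growth-associated maintenance (GAM) coefficient; the protein share
  (43.28 mmol ATP/g protein) is charged on the protein-synthesis reaction
  itself so protein-maximising analyses carry their cost. The whole-cell
  reaction is written literally as 1 g DCW + f g cellulosome per unit
  flux, f = 0.02 (cellobiose) or 0.2 (cellulose). Non-growth-associated
  maintenance is a lower bound of 3.27 mmol ATP/g DCW/h on the
  maintenance ATPase.
- **Cellulosome.** Its amino-acid demand is the median over culture
  conditions of the abundance-weighted count matrix **A**·**c**, converted
  to mmol per gram with average residue masses (one water per peptide
  bond). The bundled protein sequences and abundance vectors are
  *synthetic* stand-ins (real cellulosomal proteomics are not
  redistributable here); every analysis that depends on them uses only
  properties invariant to the specific values — scale invariance, median
  behaviour, and the per-gram normalisation, which pins the total demand
  near 9.1 mmol residues/g regardless of composition.

Internal reactions carry a 60 mmol/g DCW/h capacity cap (all observed
central fluxes are below 20); without it, a thermoneutral ATP/PPi
interconversion direction dominates sampled turnover sums.

## Reconstruction calibration

Several stoichiometric parameters of the membrane energetics are not fixed
by available measurements: the translocation numbers of ECH, RNF, the
membrane pyrophosphatase, and the ATP synthase, and the lumped amino-acid
precursor coefficients. These were fixed once, at build time, by requiring
the reconstruction to reproduce its training data — the measured
cellobiose/cellulose fermentation balances and the relative cell yields on
different cellodextrins — mirroring how the original genome-scale study
trained its own free energetic parameters. The frozen values are: ATP
synthase 4 H+/ATP; membrane PPase 4 H+/PPi, i.e. PPi at energetic parity
with ATP (a deliberate guard: in an LP without thermodynamic constraints a
cheaper PPi would let the PPi-linked glycolysis inflate every yield);
ECH 2.4 H+/H2 as the effective energy conservation of the membrane
hydrogenase; RNF 2 H+ per ferredoxin. The network content and these values
are hashed, and tests pin the hash.

Experimental fluxes are applied either as equalities at their means or as
mean ± SD ranges; the scans default to the range mode, which matches the
"observed range" framing of the calibration and is the only mode under
which a network this small can reach the measured growth rate — at strict
mean equality the measured fluxes pin the carbon and electron balances so
tightly that no maintenance coefficient reproduces growth.

## Calibration procedure

1. **GAM.** With cellobiose fluxes constrained, NGAM at 3.27, and the
   cellulosome ATP coefficient at protein parity (43.28), growth is
   maximised for GAM on a 1–50 grid (step 0.5, refined to 0.1); the best
   fit minimises |μ_pred − μ_obs| with ties broken toward the larger
   coefficient. On the bundled network the scan lands at 13.8 mmol ATP/g
   DCW/h with μ_pred = 0.330 1/h.
2. **Cellulosome ATP.** With the fitted GAM fixed and cellulose fluxes
   constrained (cellulosome fraction 0.2), the cellulosome coefficient is
   scanned over 40–100 (step 1). On this reduced network the
   cellulose-constrained state produces ~6 % less ATP than needed to reach
   the measured 0.31 1/h anywhere on the grid, so the scan bottoms out at
   the 40 floor instead of the ~57 a full reconstruction recovers. The
   shortfall is structural: every energetic parameter shifts the
   cellobiose and cellulose states almost equally, and the cellobiose
   state (which fixes GAM) leaves no freedom to close the difference. The
   scan is still run and reported faithfully.
3. **Cellodextrin yields.** For each sugar as sole carbon source with
   glucose-equivalent uptake fixed at 6.5 mmol/g DCW/h, the summed flux to
   cell protein plus cellulosome is maximised; yields divide that mass
   flux by the glucose-equivalent mass uptake. Ratios to G6: G5 98.5 %,
   G4 96.2 %, G3 92.4 %, G2 84.7 %, G1 61.8 % — monotone in chain length,
   within a few points of the observed 95/92/83/58.

## Sampling protocol

100 growth rates are drawn from a normal distribution truncated to
[0, 0.3] 1/h (mean 0.15, sd 0.075 — the distribution's parameters are not
otherwise specified and are configurable), and uptakes uniformly on
5.0–7.5 mmol glucose equivalents/g DCW/h (a 5.5–7.5 preset also exists);
draws are shared between the cellobiose and cellulose member of each grid
pair. Per point, growth, uptake (through the chain-length balance), the
sum-of-yields line, and a noise-perturbed E:A ratio are fixed, all other
products left free, and the polytope is sampled by hit-and-run in the null
space of the equality constraints: warm-up equal to the chain length
(default 1000 steps), then thinning to 1000 retained states. Empty
polytopes are skipped and logged. Summaries are per grid point, never
binned. The E:A lines (cellobiose slope 5.0, intercept 0.5; cellulose 1.0,
0.25) are reconstructed so cellobiose reaches E:A ≈ 2 near μ = 0.3 while
cellulose stays below 1; Eq.-style noise multiplies slope and intercept
independently by uniform factors on [0.8, 1.2].

Sampled GTP, PPi and NADPH turnover rise cleanly with growth rate (purely
anabolic cofactors). Mean ATP turnover *falls* with growth rate on this
network: the sum-of-yields line forces ~95 % of substrate carbon into
ethanol+acetate as μ → 0, the attendant substrate-level ATP has no
biosynthetic sink at low growth, and its dissipation through the free
maintenance bound dominates the turnover sum. Fixing the maintenance flux
restores a rising trend but empties roughly half the sampling grid. This
is a known, documented divergence of the reduced network from the
full-scale behaviour, and the corresponding check is left failing rather
than redefined.

## Numerical choices

- LP: scipy's HiGHS, primal/dual feasibility 1e−9; steady state checked
  post hoc at 1e−6 max-norm, irreversibility at 1e−9. cobrapy/GLPK serves
  as an independent cross-check in tests, never as the solver.
- Loopless post-processing: LP re-solve minimising total absolute internal
  flux with exchanges and the objective fixed (deterministic, no MILP).
- Tie-breaks: scan ties go to the larger ATP coefficient (conservative
  energetics); alternate optima are reported as the solver vertex, and
  tests assert only solver-invariant quantities.
- Elementary modes: double-description tableau on the reversible-split
  network with support-minimality pruning; enumeration refuses networks
  beyond 30 split reactions rather than truncating. Cut sets are found as
  minimal hitting sets of target-mode supports and certified by FBA
  (growth floor 1e−4, yield floor 60 % of the wild-type theoretical
  maximum, enforced against *all* surviving steady states by minimising
  product flux at the growth floor).
- JSON is the canonical model format (coefficients as decimal strings;
  byte-stable round trips); SBML L3/FBC import/export goes through
  cobrapy.

## What the synthetic data do and do not show

Toy networks are random but seeded, with a planted feasible pathway; they
exercise solver and enumeration correctness, not biology. Synthetic
fermentations are exact inversions of the batch/chemostat rate relations
plus optional log-normal noise; recovering their parameters validates the
estimators, not the culture model. The bundled cellulosome fixture is
synthetic; conclusions that would depend on real cellulosomal composition
(absolute amino-acid demands per residue class) are out of scope. Passing
tests therefore certify the machinery and the reconstruction's trained
behaviour on its training data — not predictive accuracy on new
conditions, which only the full genome-scale reconstruction can attempt.

## Known limitations

- The cellulose-side ATP calibration undershoots (see above); the
  reduced network should not be used to quantify cellulosome synthesis
  cost, only to demonstrate the procedure.
- No thermodynamic (ΔG) constraints; PPi parity is a surrogate for them.
- Elementary-mode and cut-set analyses are exhaustive only at toy scale.
- Proton translocation numbers are effective, calibrated values, not
  measurements.
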