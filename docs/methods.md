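# Methods

## Scope and data model

The package analyses two kinds of titration data for silver binding to short
SilE-derived peptides: assigned 2D NMR peak lists (TOCSY or ¹H–¹³C HSQC)
across a series of Ag⁺:peptide ratios, and centroided positive-mode ESI–MS
spectra with known total concentrations. Peak lists are plain 6-column
TSV/CSV (`residue_index, residue_type, atom_f1, atom_f2, f1_ppm, f2_ppm`);
a blank shift cell means the cross-peak is not visible at that point and is
carried as `present=False`, never dropped — downstream stages must handle
missing peaks explicitly. Residue numbering is peptide-local 1-based in
files; protein-numbering labels (e.g. `87His`) are derived from the
sequence's `numbering_offset` for reports. A series is validated to have
strictly increasing, unique ratios and one spectrum type, and its assignment
sets are reconciled to the union with `present=False` placeholders, so
ordering is total and stable under input permutation.

## Chemical-shift perturbations

For TOCSY the perturbation between the reference spectrum (default ratio
0.0) and the endpoint (default 10.0) is the Euclidean displacement of the
cross-peak; for HSQC the squared carbon displacement is scaled by α
(default 0.3, the conventional value for ¹³C/¹H shift ranges) before the
root. HSQC records are grouped by the carbon atom name — Cα/Hα, Cβ/Hβ,
Cγ/Hγ, and a fourth bin collecting the methyl-region / side-chain-end
carbons (Cδ, Cε, CH₃). TOCSY records are grouped amide-NH/Hα versus other
side-chain cross-peaks. Group statistics use the population σ by default
(n denominator; configurable to sample σ — the choice is a convention, both
are defensible for n ≲ 20 peaks per group).

Mover classification is deliberately simple and configurable: weak below
the group mean, medium in [μ, μ+σ), strong at or above μ+σ. The closed
lower bounds give deterministic tie-breaks; when σ = 0 a CSP exactly at the
mean classifies as medium (there is no dispersion to stand above), and
comparisons carry a 1e-12 relative epsilon so ties survive floating-point
rounding of μ. These thresholds are this package's documented convention —
published CSP practice varies and no universal cut-off exists.

## Secondary ¹³Cα shifts and helix face

Secondary shifts are δ_obs(¹³Cα) − δ_rc per residue at one titration point,
positive values indicating helical tendency. The packaged random-coil table
carries standard literature ¹³Cα values for unstructured peptides
(Wishart-style tabulation, pH ≈ 5, 25 °C); published tables differ by a few
tenths of a ppm, so the table is user-replaceable (`RandomCoilTable.from_tsv`).
No neighbour-sequence corrections are applied.

The helix-face test uses the ideal α-helical wheel of 100° per residue: two
residues are same-face when their wheel separation (mod 360°, folded into
[0°, 180°]) is within a tolerance of 0°. The default tolerance is 100°,
inclusive. This choice makes i+3 (60°), i+4 (40°) and directly adjacent
residues i+1 (100°) same-face while i+2 (160°) is opposite-face; it is the
widest reading under which the full His/Met binding face of the 16-residue
fragment (protein residues 80, 83, 87, 90, 91) is pairwise same-face, as the
structural interpretation requires — a stricter 80° tolerance would split
the adjacent methionine pair (90, 91) on a technicality of the idealised
wheel.

## Titration trajectories and direction changes

Under fast exchange a cross-peak sits at the population-weighted average of
free and bound positions, so one binding mode traces a straight line and a
second mode with a different bound-shift vector bends the path. Trajectory
geometry lives in the same weighted plane as the CSP metric — the ¹³C
coordinate is multiplied by √α so squared distances carry α — keeping one
distance metric across modules.

The detector computes turning angles between successive displacement
vectors. Steps shorter than `min_step_ppm` (default 0.005 ppm,
¹H-equivalent after weighting) are merged into the following step as a
noise guard; a trajectory whose total motion stays below the guard returns
a zero-motion flag instead of a breakpoint. A break is declared when any
angle reaches `turn_threshold_deg` (default 30°), and the reported
`break_ratio` is the titration ratio at the vertex of the first qualifying
turn — the last point before the new direction. Both thresholds are
explicit formalisations of what is otherwise a visual judgement; the
defaults are far below the ~70–95° turns of the two-mode synthetic preset
and far above the ≈0° angles of noiseless one-site data, so the decision is
not threshold-sensitive in the regimes tested. Turning angles are invariant
under rigid rotation and uniform scaling of the peak coordinates, and
reversing the titration order preserves the angle multiset.

## Equilibrium model and masses

The binding model is the sequential two-site scheme with stepwise
dissociation constants, K_D1 = [P][Ag]/[P·Ag] and K_D2 = [P·Ag][Ag]/[P·Ag₂]
(μM). Stepwise rather than cumulative constants match the two-step
narrative of a high-affinity primary site filled first. Species at given
totals are the unique non-negative root of the mass balances; the solver
eliminates the peptide species analytically and Brent-solves the silver
balance on free Ag⁺ in [0, Ag_tot], where the residual is strictly
increasing — deterministic, no random starts, both conservation laws closed
to 1e-9 relative (the residual rounding is absorbed into the free pools).
Degenerate inputs (zero peptide or zero silver) short-circuit analytically.

Peptide masses are computed with pyteomics' amino-acid composition tables,
average-mass mode by default: the average convention reproduces printed
synthesis-report MWs of the two study peptides within ±0.02 Da (tolerance
±0.05 Da absorbs atomic-mass-table vintages). Adduct m/z uses
(k·M + n·m(Ag⁺) + (z−n)·m(H⁺))/z — each bound Ag⁺ contributes its charge,
the remainder is protonation, the standard positive-mode convention for
metalated peptides.

## MS annotation, quantification, fitting

Each centroid is matched to the nearest theoretical species m/z within a
ppm tolerance (default 10 ppm); exact ties are flagged ambiguous and
excluded from quantification. Dimer candidates default to the apo dimer
only: a metalated dimer (k=2, 2n, 2z) is m/z-identical to the monomer
(n, z) and cannot be resolved without isotope-pattern modelling, which is
out of scope; observed dimers are treated as nonspecific gas-phase
association. Species areas are summed over all matched charge states.

Quantification converts areas to peptide mole fractions with equal response
factors across species (configurable for sensitivity analysis): dimers
contribute two peptide equivalents to the apo pool, monomer species with
n ≥ 2 are pooled into the doubly-bound fraction (so a small n=3 gas-phase
adduct is quantified without forcing a third binding step). Fractions are
scale-invariant in the areas and sum to 1.

The fit minimises Σ‖f_obs − f_model(K_D1, K_D2)‖² over titration points,
with the constants log₁₀-parameterised, bounded in [10⁻⁶, 10⁹] μM, and
started from the fixed point (1, 10) μM — fully deterministic. When the
first site is much tighter than the working peptide concentration, binding
is near-stoichiometric and the data constrain K_D1 only from above; the fit
reports a sensitivity diagnostic (Jacobian column norm, floor 10⁻³) and
flags the estimate as an upper bound when the data cannot resolve it. The
`AgBindingTitration`/`AgBindingResults` pair wraps this with prediction,
asymptotic standard errors (Gauss–Newton curvature on the log scale, delta
method back to μM) and a text summary.

## Synthetic data

The NMR generator has two modes. *Equilibrium* mode is the physical one:
occupancies f₁, f₂ from the mass-balance solver at each ratio (default
peptide concentration 1 mM, NMR-scale) place each peak at
base + f₁·Δδ_site1 + f₂·Δδ_site2; noiseless one-site trajectories are
exactly collinear and two-site trajectories are convex combinations in the
triangle of the free and two bound positions. *Piecewise* mode is
phenomenological: a linear path to a pre-break displacement, then a
different direction to the final ratio, with the vertex at a chosen
equivalence point. The packaged `sp2-paper` preset uses piecewise mode with
the break at 0.5 equivalents and ratios {0, 0.1, 0.5, 3, 10}: a sequential
equilibrium with a sub-micromolar first site at millimolar peptide would
saturate site 1 essentially stoichiometrically and place the visible turn
wherever concentration, not affinity, dictates — the phenomenological mode
separates testing the detector from arguing the chemistry. Baseline peak
positions are deterministic spreads over realistic ppm windows (amides
7.9–8.3, Hα 4.05–4.3, ¹³Cα near random coil).

The MS generator drives the isotherm solver (preset `sp3-paper`: 100 μM
peptide, ratios {0, 0.5, 1, 2}, K_D1 = 0.2 μM, K_D2 = 24.5 μM), converts
species concentrations to stick areas (area ∝ concentration × response),
distributes them over charges 2–3 (weights 0.6/0.4), draws a dimer fraction
(0.35) from the free-peptide pool and splits a small n=3 fraction (0.05)
off the doubly-bound pool as a gas-phase artifact. Because the dimer is
drawn from the apo pool and n ≥ 2 species are pooled on analysis, the
noiseless round trip through assign → quantify reproduces the model
fractions exactly, which is what makes exact K_D recovery a meaningful
end-to-end test. All randomness flows through one `numpy` generator seeded
from the config (default 1722); seeded runs are bit-reproducible. The
presets themselves are noiseless — they define study conditions, not noise
benchmarks; the general-purpose defaults (noise_sd = 0.002 ppm,
noise_cv = 0.05) are conventions for test design.

What the synthetic data does *not* emulate: lineshapes, relaxation and
intermediate-exchange broadening; peak overlap and picking errors; silver's
two-isotope pattern and isotope envelopes; ionisation-efficiency differences
between species; solvent/adduct chemical noise. Passing recovery tests
therefore shows the analysis chain is correct and self-consistent under its
own assumptions, not that those assumptions hold for any particular
instrument dataset.

## Problem sizes and numerical choices

Tests run the full 16/19-residue peptides, 4–5-point titrations, 100-point
random oracle grids and a 3×3 K_D recovery grid; the whole suite completes
in a few seconds. The equilibrium solver uses Brent with xtol 1e-15; the
oracle used to cross-check it is an independent 200-iteration bisection.
Tolerances asserted in tests: 1e-12 for CSP arithmetic against direct
formulas, 1e-6 relative for solver-vs-oracle, 1e-9 relative for
conservation, 10% relative for K_D2 recovery (5% in the symmetric
identifiable regime).

## Known limitations

- Mover thresholds and the direction-change angle are conventions, not
  community standards; report them alongside results.
- K_D1 below ~1% of the peptide concentration is an upper bound, not an
  estimate; the sensitivity flag makes this explicit but cannot conjure
  identifiability.
- The MS quantification inherits the equal-response assumption; real
  electrospray response varies with metalation and conformation.
- The helical-wheel test uses the ideal 100° geometry with no structural
  input; it supports register reasoning, not structure determination.
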