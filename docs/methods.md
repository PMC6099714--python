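# Methods

## Decomposition ledger

The ledger treats the HVPT partition purely as bookkeeping: levels are
cumulative sums of components over residue groups, and every operation
is linear in the components. Components are never computed ab initio
here; they enter as data (per residue group where available, or as a
single "total" record reconstructed by successive subtraction of
adjacent level totals). The packaged level table stores the published
values at their printed precision (one decimal), and the component
fixture is derived from it by subtraction, so the two representations
are mutually consistent by construction.

Two tolerances govern validation. Data read from one-decimal tables use
0.15 kcal/mol: up to three rounded terms enter a level sum and each
carries at most 0.05 of rounding error. Synthetic (unrounded) data use a
strict zero tolerance — the generator satisfies the sign constraints
exactly, so any violation is a bug, not noise. Violations are reported
with their residuals, never repaired silently.

The residue grouping (Arg103, Phe108, Cys70–Cys188, Val72–Met73) is
configuration data: the disulfide-bonded cysteines and the sequential
Val/Met pair interact with the ligands as units, while the charged
arginine and the aromatic phenylalanine stand alone.

## Long-range terms

Multipole electrostatics uses traceless (Buckingham) moments and the
interaction-tensor formulation: with D_n = ∇ⁿ(1/R) and prefactors
(1, 1, 1/3, 1/15) for charge, dipole, quadrupole, octopole, the
(l_A, l_B) pair term is k(−1)^{l_A} C_{l_A} C_{l_B} M^A⊗M^B : D_{l_A+l_B}
and decays as R^−(l_A+l_B+1). "Truncated at R⁻⁴" is implemented as: keep
every pair term of overall order n ≤ 4 — charge–charge (R⁻¹) through
dipole–quadrupole and charge–octopole (R⁻⁴). Whether octopoles
participate at all is a switch, since the maximum site rank of a
cumulative-multipole expansion is a modelling choice; both R⁻⁴ channels
are on by default. Helpers convert primitive Cartesian moments to the
traceless convention, and site constructors reject moments whose traces
exceed 1e−9.

The Coulomb constant is fixed at 332.06 kcal·mol⁻¹·Å·e⁻² (the common
molecular-mechanics value) so numeric expectations in tests are
bit-stable. Interfaces use Å and elementary charge throughout; no
internal unit system leaks out.

Dispersion is the damped atom–atom form −f₆(βR)C₆/R⁶ (optionally
−f₈(βR)C₈/R⁸) with Tang–Toennies damping f_n(x) = 1 − e⁻ˣ Σ_{k≤n} xᵏ/k!.
The fitted functional form and parameters of the original atom–atom
potential are not published alongside the study data, so the form and
all parameters here are configuration inputs (YAML/JSON tables keyed by
unordered element pair, with an optional geometric-mean combining rule);
numeric agreement with the published per-ligand dispersion column is
therefore not asserted anywhere — only the ledger arithmetic on it is.

Correctness of the physics rests on oracles rather than reference
values: reduction to brute-force Coulomb sums for point charges,
finite-difference convergence (a dipole as ±q/d charges converges with
error O(d²)), exact agreement of a compact charge cloud with its own
traceless expansion at long range, rotational invariance, and an
independently written double-loop Tang–Toennies reference.

## Ranking statistics

Pearson R is computed on raw score vs pIC50; columns whose convention is
"higher score = stronger binder" are negated first, so more negative R
uniformly means better ranking. Npred enumerates all unordered ligand
pairs; pairs with exactly equal recorded pIC50 are excluded from the
denominator (the reference series contains exactly one such pair, giving
104 of 105 pairs counted), and a pair counts as concordant when the
lower (more negative, after orientation normalisation) score belongs to
the more potent ligand. A predicted-score tie counts as a failure, not
an exclusion: a model that cannot order a pair has not predicted it. The
experimental-tie test uses exact equality at the recorded precision — no
epsilon — because activities are data printed at two decimals, not
measurements with error bars in this pipeline.

SE regresses the energy on pIC50 (not the reverse) so the residual SD
carries energy units, matching how the reference footers report it:
se = √(SS_res/(n−2)).

Recomputing all eighteen footer statistics from the one-decimal tables
reproduces seventeen at printed precision. The remaining one — SE of the
Heitler–London level, 5.67 here vs 5.6 printed — differs by one unit in
the last printed digit because the published value was computed from
unrounded energies; the same input-rounding effect shifts the
11-ligand ΔGsolv SD from the printed 1.8 to 1.75. Both are left as
observed; no tolerance is widened to absorb them.

## Solvation screen

The sample SD (n−1 denominator; the n−1 choice is what reproduces the
published 3.0 → 1.0 sequence) of ΔGsolv acts as the applicability
predictor. The verdict is `elevated` only when the SD exceeds every
packaged reference value — a deliberately conservative rule, since the
references are single numbers, not distributions. Outlier removal
supports two modes: the explicit list (the reproduction default) and a
rule dropping the k ligands farthest from the median ΔGsolv. The rule
variant exists because any explicit list is ultimately a judgment call;
it approximates but does not claim to reproduce the published choice,
and iterating it to chase ever-lower SDs is exactly the over-fitting the
screen is meant to avoid — hence no automated iteration is provided.

## Synthetic series

The generator emulates the structure the analysis assumes, not real
chemistry: per-group electrostatic terms are Gaussian (dominant charged
group mean −80 kcal/mol, SD 6; neutral groups −4 ± 1.5; non-dominant
charged groups −15), short-range magnitudes are exponential with scales
2–4 kcal/mol and exact physical signs, so the dominant group carries
≥ 70% of the first-order electrostatic total in expectation. Activities
are an affine map of the MP2 total (±2σ of energy spans the requested
pIC50 range) plus Gaussian noise whose SD is solved in closed form from
the requested population correlation; the analytic population SD of the
energy uses the known component variances, so no calibration loop is
needed. Solvation values are Gaussian with the requested SD and split
exactly into el + non-el parts. Everything derives from one NumPy PCG64
seed, recorded in emitted metadata.

What the generator does not emulate: real substituent chemistry, docked
pose errors, correlated components, heteroscedastic activity noise.
Passing parameter-recovery tests therefore shows the statistics and the
generator are mutually consistent, not that the score works on any
particular real series.

Problem sizes in the test suite were chosen to make sampling error
negligible relative to the asserted bands: single-series correlation
recovery at n = 200 (±0.05 band), mean recovery over 100 seeds (±0.02),
toy-complex dominance over 200 seeds. The whole suite runs in a few
seconds.

## Pipeline and CLI

`run_pipeline` wires the stages together: load (packaged tables by
default, user CSVs otherwise), validate at the configured tolerance with
every finding logged, evaluate all requested columns, screen, re-evaluate,
and write CSV plus a plain-text report. External score columns (e.g.
docking scores) are ingested as opaque columns with a per-column
orientation map and are never given an SE, which is only meaningful in
energy units. The `reproduce` subcommand diffs the recomputed footers
against the expected values and tolerates exactly the one known
rounding-unit difference described above.
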