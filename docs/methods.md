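# Methods

## Competition equilibria (`hydromap.equilibria`)

The binding model is mutually exclusive 1:1 competition: a protein binds a
labeled probe (dissociation constant `K_probe`) or an unlabeled competitor
(`K_comp`), never both, and no higher-order complexes form. Because the
assays run at protein concentrations near the dissociation constants, ligand
depletion is material and no trace-ligand approximation is made: the coupled
mass-action system is solved exactly at every titration point.

Eliminating the complexes gives one equation in the free protein p,
g(p) = p(1 + D_t/(K_probe+p) + C_t/(K_comp+p)) − P_t, strictly increasing on
[0, P_t] with g(0) < 0 ≤ g(P_t), so the physical root is unique and always
bracketed. It is located with Brent's method (xtol 1e-15 M) and then
polished with up to eight Newton steps until |g(p)| ≤ 1e-12·P_t. The polish
matters: where g is steep (total ligand far above its K), a 1e-15 bracket on
p still leaves a mass-balance residual above the 1e-9 relative closure the
rest of the package assumes. g′ ≥ 1 everywhere, so the Newton steps are
stable.

The anisotropy signal is two-state: ⟨r⟩ = r0 + (r1 − r0)·F_b. Solvent
effects on probe photophysics and plate-reader variation are absorbed into
the per-curve limiting anisotropies r0/r1 rather than modeled mechanistically,
which is why both are fitted per curve by default.

Fitting minimizes unweighted squared residuals (a per-point σ column
switches on weighting) over {K_comp, r0, r1} with K_probe fixed from assay
metadata; dissociation constants are searched as log₁₀K (bounds 10⁻¹⁵–1 M)
so the optimizer is well-scaled across the picomolar–micromolar span.
Starting values come from the data: r0/r1 from the last/first measured
anisotropies, K_comp from the geometric midpoint of the dose range.
Standard errors come from the Jacobian at the optimum
(cov = (JᵀJ)⁻¹·RSS/dof), with log-scale errors mapped to K·ln10·se.
A curve whose anisotropy span does not exceed four times the
first-difference noise estimate is flagged unidentifiable and never
optimized; non-convergence is flagged on the result, not raised. A global
variant shares K_probe across curves for experiments where the probe
affinity is common.

Whether the protein total should ever float is left to the caller (it is a
`fixed` entry like any other); the default keeps it at its pipetted value,
which is the usual practice when protein concentrations are known
spectrophotometrically.

## Osmotic linkage (`hydromap.osmometry`)

The osmolyte is assumed colligative (effects scale with osmolality,
independent of identity) and the dependence linear: log₁₀K_B = a + Γ·osm.
The fit is closed-form weighted least squares with weights 1/se² when every
point carries a finite standard error on log K, uniform otherwise; the slope
standard error comes from the weighted residual variance. With exactly two
osmolalities the line is determined and the slope error is NaN (undefined),
not zero. The regression was cross-checked against statsmodels WLS in the
test suite.

Water counting uses Δn_w = −128·Γ with the conversion constant fixed at
exactly 128 rather than the unrounded 55.5·ln10 = 127.79: published water
counts in this field reproduce only with the printed 128, and consistency
with those tables outweighs the 0.16% difference. Reported counts round
half-up to the nearest integer; the unrounded value is kept on the fit
object and used for downstream arithmetic (one published table row, a slope
of −0.30 printing 39 waters instead of the 38 that −0.30·128 = 38.4 gives,
is reproducible only from the unrounded slope; this package reports from
unrounded slopes whenever full data are supplied).

"Normo-osmotic" is 0.3 osmolal by default (physiologic baseline; the
experimental series start at 0.29 osm) and configurable everywhere it
appears. The hydration budget assigns each counted water a nominal 9 Å²
cross-section and divides by the buried interface area; fractions above 1
are reported as computed and flagged, since clipping would hide an
inconsistency between the thermodynamic count and the structural area.

## Surface areas (`hydromap.structure`)

SASA is Shrake–Rupley: each atom's sphere is inflated by the 1.4 Å probe,
960 points are placed on it, and the accessible fraction is the share of
points not inside any neighbor's inflated sphere. The point set is a
deterministic Fibonacci (golden-spiral) lattice, so areas are exactly
reproducible and rigid-motion invariance holds to the lattice discretization
(~1–2% at 960 points; tests use 2% bands). 960 points keeps a 20-atom
cluster within 2% of a 10⁴-point reference while staying fast enough to run
complexes at test time. Neighbor candidates come from a k-d tree.

Van-der-Waals radii use a single documented table (C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80 Å) with a warned 1.70 Å fallback for anything else;
hydrogens and waters are excluded on reading since crystal structures of
these complexes deposit neither. Residue numbering follows the input file
verbatim.

Contact area is a property of the protein: buried(residue) =
SASA(protein alone) − SASA(protein in complex), summed per residue, grouped
into user-supplied secondary-structure element ranges (the element
boundaries are a YAML config because they are structure-specific), and
averaged across declared asymmetric copies. Identical lattices in both
evaluations make the difference non-negative by construction.

## Motif information content (`hydromap.motif_ic`)

Per-column IC is 2 + Σ p·log₂p bits against a uniform background, the
convention for curated motif models; an explicit background vector switches
to relative entropy. The Schneider-style small-sample correction
(3/(2·ln2·n) bits per column) is available but off by default for the same
reason — the intended inputs are motif models, not raw site counts.
Count matrices normalize as (count + pseudocount)/(total + 4·pseudocount).
Motif comparison returns the total-IC difference, ratio, and per-position
deltas; unequal widths require an explicit offset so that alignment is
always a caller decision, never a guess.

## Synthetic data (`hydromap.synth`)

The generators emulate the experimental designs the analysis targets:

- **Titrations** — 12-point 3-fold serial dilutions geometrically centered
  on the expected competitor K, probe 1 nM, protein 5 nM (inside the
  10⁻⁹–10⁻⁸ M window used experimentally), additive Gaussian noise on
  anisotropy with σ = 0.002 by default, forward-modeled through the exact
  solver and the two-state signal. Default limiting anisotropies r0 = 0.18,
  r1 = 0.28 are plausible Cy3 values chosen as simulation constants — they
  are not measured quantities.
- **Osmotic series** — log₁₀K_B linear in osmolality over 0.29–2.0 osm
  (5 osmolalities), 3 replicates, Gaussian noise σ = 0.05 on log₁₀K_B.
  Additive Gaussian noise on the log scale is the simplest model consistent
  with replicate ± SD reporting.
- **Binding sites** — column-independent draws from a PFM, written as FASTA.
- **Toy complexes** — sphere-atom structures with declared protein/DNA
  chains and asymmetric copies, writable as PDB, sized so closed-form
  spherical-cap overlap is an exact oracle for contact areas.

All generators are pure functions of (design, seed); equal seeds give
byte-identical files. What they do *not* emulate: instrument drift,
osmolyte-specific (non-colligative) effects, probe photobleaching,
cooperative 2:1 binding, or correlated noise between titration points — so
passing recovery tests demonstrate estimator correctness under the stated
noise model, not robustness to every failure mode of real plates.

## Pipeline (`hydromap.cli`)

Replicate titrations are fitted independently; per osmolality the fitted
log₁₀K_D values are averaged with the SEM from replicate scatter (a global
shared-K_probe fit exists but is not the default, matching the
fit-then-average convention for reporting averages ± SE of independent
replicates). The aggregated series feeds the osmotic regression; water
counts, normo-osmotic K_D and (optionally) structural contact areas and the
hydration budget complete the report. Reports carry a config digest, seed
and package version; identical config + seed reproduce an identical numeric
payload. Stage failures are recorded per construct and surfaced as a
non-zero exit from the CLI rather than aborting the remaining constructs.

## Problem sizes and numerical choices

Recovery properties are established at the study's own designs: 50 titration
fits spanning K_comp 0.1–100 nM for the median-log-error bound, and 200
osmotic series for the slope-calibration bound; both complete in seconds.
Equilibrium solutions are validated against a 1e-15 M bisection oracle via
interval enclosure (the oracle's final bracket bounds the true root because
g is monotone, so species computed at the bracket endpoints bound the true
species). Ties and degenerate inputs: zero protein short-circuits to the
all-free state; zero-signal curves are flagged, not fitted; two-point
osmotic series return an undefined slope error rather than a fabricated one.

## Known limitations

- The osmotic model is strictly linear and colligative; preferential-
  interaction (osmolyte-specific) corrections are out of scope.
- Contact areas depend on user-supplied element boundaries; published
  per-residue tables additionally depend on the exact deposited structure,
  so they are external validation, not a desk-scale check.
- The anisotropy model is two-state; cooperative 2:1 complexes and probe
  photophysics beyond per-curve limiting anisotropies are not modeled.
- No mmCIF support; standard PDB only.
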