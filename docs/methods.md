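# Methods

This note records the models, numerical choices and design decisions
behind each module, what the synthetic fixtures do and do not emulate, and
the known limitations.

## Electrostatics

The potential solves ∇·(ε∇φ) = −4πρ at zero ionic strength on a uniform
cubic lattice. Units are Gaussian-style with lengths in Å and charges in
e; the solution is scaled by 332.063 kcal·Å/(mol·e²) to kcal/(mol·e).
Discretization is the standard 7-point stencil with harmonic-mean face
dielectrics, which preserves flux continuity across the dielectric
boundary; point charges are spread to the eight surrounding nodes by
trilinear (cloud-in-cell) weights. The resulting symmetric
positive-definite system is solved by conjugate gradients to a relative
residual of 1e-8 by default; non-convergence raises with the residual
attached rather than returning a silently bad field.

Boundary conditions are Dirichlet: the Coulomb potential of all charges
screened by the aqueous dielectric. The aqueous constant is 78 (the
conventional value; only the low constant, 2, is prescribed by the
recipe), and no salt term is included. The discrete Gauss law — flux
through any node box around an isolated charge equals −4πq — holds to
solver precision by construction and is asserted in tests at 3%.

Accuracy: against the Coulomb closed form in a uniform dielectric the
solution is within 5% for distances between 3 grid spacings and half the
box; closer than that, the cloud-in-cell charge makes the potential finite
where the analytic form diverges. Tests and the acceptance experiment use
0.5–1.0 Å spacings; 0.4 Å is the default for production-style runs.

## Dielectric and desolvation geometry

The solvent/interior boundary is the union of inflated atomic spheres
(atom radius + 1.9 Å surface extension), not a solvent-excluded molecular
surface. This realizes the stated extension rule literally and makes the
classification checkable against an exhaustive per-node distance oracle.
Lipid atoms within 17 Å of any receptor atom are kept and occupy dielectric
volume at their own radius (default 1.9 Å, no extension); farther lipid
atoms are discarded. Lipid atoms carry no charge, contribute no van der
Waals attraction (they are excluded from the vdW grids), but do occlude
solvent in the desolvation grid.

Desolvation occlusion at a node is the fraction of a probe ball (default
radius 4–6 Å) around it that falls inside the receptor-or-lipid volume,
with the receptor inflated by 0.5 Å. The ball is sampled with a fixed
quasi-uniform 256-point cloud (one deterministic stream, identical for
every call), and the builder is cross-checked against an independent
100,000-sample Monte-Carlo oracle at mid-surface points to 0.02.

## Van der Waals grids

The grids store Σ√A_j/r¹² and Σ√B_j/r⁶ separately so a probe atom's
energy is √A_i·G_A − √B_i·G_B, the geometric-mean combination rule of the
AMBER-style 6-12 potential. Distances are clamped at a 0.8 Å floor and the
per-atom repulsive term is capped at +100 kcal/mol at score time: clashed
poses stay finite and rankable rather than overflowing. Element parameters
are a small built-in united-atom table; absent elements raise rather than
defaulting silently.

## Matching spheres and orientation sampling

Matching spheres are the reference ligand's heavy-atom positions,
deduplicated greedily in input order at 0.25 Å, then truncated to 45
keeping the points closest to the reference centroid — the pocket-core
hot-spots, which are the most transferable; how a production matcher
selects its 45 is not specified anywhere, so centroid proximity is this
package's documented choice.

Orientations come from triplet matching: each ligand heavy-atom triplet is
tested against every ordered sphere triplet, and when all three pairwise
distances agree within the tolerance (default 0.5 Å) the least-squares
(Kabsch) proper rotation aligning atoms to spheres becomes a pose.
Near-collinear triplets (area < 0.1 Å²) are skipped as rotationally
degenerate. Enumeration order is lexicographic, making results
deterministic and ties reproducible; the enumeration equals a brute-force
O(n³m³) oracle on small fixtures. This is deliberately simpler than a
production docking matcher's hierarchical search — absolute pose counts
and energies are not comparable to production engines; orderings and
invariances are what this implementation guarantees and tests.

Ligand conformers are inputs (from the fixture generator or SDF);
conformer generation and per-atom solvation energies are upstream
commercial steps outside this package's scope, so per-atom desolvation
costs arrive as data.

## Screening cascade

Clustering is greedy leader in rank order at Tc ≥ 0.5 (inclusive) on
radius-2/2048-bit circular fingerprints; heads are automatically each
cluster's best-scoring member. Novelty removal is inclusive at Tc ≥ 0.35
against the known-ligand set. Strain filtering evaluates each rotatable
dihedral against the first matching rule of a small built-in
piecewise-linear TEU table (amide cis/trans, ester, biaryl,
α-to-carbonyl; overridable from TSV) and passes a record iff its worst
dihedral is ≤ 1.5 TEU, inclusive. The full torsion-library method the
screening literature uses is far larger; only the thresholding behaviour
is reproduced here, with the table as a documented stand-in. Dihedrals no
rule covers score 0 and are reported as uncovered rather than silently
passing judgement.

Interaction checks codify the criteria a human inspector applies: ionic =
opposite formal charges within 4.0 Å (receptor atoms with |partial
charge| ≥ 0.5 e count as charged); H-bond = N/O donor-acceptor pair within
3.5 Å with a ≥ 120° angle at the donor hydrogen; both thresholds
inclusive and configurable, since no authoritative geometric definition
accompanies the screening recipe.

All filters are monotone in their cutoffs, stage counts telescope, and
re-running the cascade on its own survivors is a fixed point — all three
are asserted as properties.

## Enrichment metrics

ROC curves advance tied scores as one block (equivalent to averaging over
tie orderings), so the trapezoidal AUC equals the Mann-Whitney U
statistic exactly; both routes are computed and compared in tests. The
adjusted logAUC integrates the piecewise-linear ROC against log10 FPR
over [λ, 1] analytically per segment (no quadrature grid), normalizes by
|log10 λ|, and subtracts the identical integral of the diagonal; λ = 1e-3
is the convention of the enrichment literature and is configurable. The
random baseline is therefore exactly 0 and perfect separation gives
1 − (1 − λ)/(ln 10·|log10 λ|) ≈ 0.8554 at the default floor.

Decoy windows (±25 amu, ±1.0 clogP, equal net charge, ±2 rotatable
bonds/HBD/HBA, Tc < 0.35 to the own ligand) follow the DUDE-Z-style
property-matching idea; the most dissimilar candidates are taken first,
with pool order as the deterministic tie-break. Decoys are drawn from the
synthetic pool, so published decoy counts are used only as fixture shapes,
never as reproduction targets.

## Library chemistry

Protonation at pH 7 is a fixed rule table: carboxylic, sulfonic, sulfinic
acids, tetrazoles and acylsulfonamides lose one proton; phosphonic acids
lose exactly one (their second pKa is above neutrality — a guard keeps the
rule idempotent on the monoanion); aliphatic amines and
amidines/guanidines gain one; anilines, amides and heteroaromatic N are
untouched. The rules are idempotent by construction and that property is
tested. Tautomer enumeration is deliberately omitted (one canonical
tautomer per molecule); clogP is the Crippen atomic-contribution method.
Both are dialect choices where the original tooling is commercial and
unstated.

Analog enumeration uses RDKit reaction SMARTS per scheme (amide coupling
and aryl amination ship built-in). The retro transform must match exactly
one site or the decomposition refuses — an ambiguous cut would silently
enumerate the wrong library. Forward enumeration canonicalizes and
deduplicates, so with structurally distinct pools the product count is
exactly the product of pool sizes, and re-coupling a hit's own fragments
always regenerates the hit.

## Pharmacology

The 4PL model is y = bottom + (top − bottom)/(1 + 10^((log x − log XC50)·h))
with the sign of the exponent set by the model direction; the fit runs
Levenberg-Marquardt from five log-spaced XC50 starts and keeps the lowest
SSE. Flat responses raise a no-fit error rather than returning a
meaningless XC50. The convergence flag is honest: it is set only when at
least one start converged.

The dose-response generator emulates the standard plate design — by
default 13 half-log-spaced concentrations spanning ±3 decades around the
midpoint, each in triplicate, with additive Gaussian noise per well.
Under that design the fitter recovers log10 IC50 within 0.1 in 97 of 100
seeded 5%-noise runs; sparser single-well designs cannot support that
precision regardless of fitter (verified by global refits), which is why
the emulated design matters and is stated here.

NCA uses the linear trapezoid over the observed span with no terminal
extrapolation (AUC_0–t): the motivating datasets tabulate exposure over a
fixed 1,440-minute window and whether published AUCs extrapolate is
unstated, so the bounded quantity is the documented choice. The two LLOQ
rules are applied exactly as stated: censored samples count as zero in the
AUC and are discarded from the half-life regression. The terminal phase is
the longest suffix of quantifiable, strictly declining points with at
least three members — a deterministic stand-in for a pharmacokineticist's
manual point selection; with fewer than three points T1/2 is reported
absent, never guessed. Ligand efficiency uses R = 1.987×10⁻³
kcal/(mol·K) at 298 K (no temperature is stated anywhere; this is the
standard convention). Schild regression excludes DR ≤ 1 points with a
warning and reports K_B = 10^(−pA2) only when the slope lies in
[0.8, 1.2], flagging non-competitive behaviour otherwise.

## Synthetic fixtures: what they do and do not show

The toy complex is a rigid concave cup of ~40–50 pseudo-atoms (radii
{1.5, 1.9} Å, charges {−0.4, 0, +0.4, +1} e) opening toward +z, with an
Arg-like +1 atom at the pocket floor, three Thr-like hydroxyl-H/carbonyl-O
residue pairs on the wall (the perturbation targets), and two 8 Å-pitch
planes of apolar lipid points at ±slab_z/2 whose +z face has a hole over
the pocket mouth. It spans the geometry the grid recipe needs — a concave
anion-recognizing pocket in an anisotropic dielectric environment — but it
is not a protein: no force field, no real lipid chemistry, no
conformational flexibility, no ordered water. Passing tests therefore
demonstrate the correctness and directional physics of the pipeline
(e.g. that the dipole perturbation improves monoanion scores by ~0.4–0.5
kcal/mol on this fixture), not affinity prediction on real receptors.

Compound libraries are template-enumerated per class (carboxylates,
tetrazole/acylsulfonamide/sulfonate bioisosteres, neutral heteroaromatic
amides, aliphatic amines) with inert aryl decorations, so
substructure-match and charge-class ground truth is exact by construction;
candidates falling outside the requested MWT window are skipped, and class
counts follow deterministic largest-remainder rounding. The chemical
diversity is far below a real make-on-demand library — these fixtures test
bookkeeping and filters, not chemical coverage.

PK profiles are exact one-compartment solutions (iv bolus and Bateman oral
form with ka ≠ ke enforced) with optional log-normal multiplicative noise
and LLOQ censoring. Real profiles have absorption variability,
distribution phases and analytical error structure these do not.

## Problem sizes

Default test and acceptance workloads are sized for a laptop-class single
CPU: lattices of 33³–45³ nodes at 0.5–1.0 Å spacing, libraries of 30–200
molecules, 100-seed recovery studies, and benchmark sets of 21 ligands
against 658 decoys (the shape of the published control calculation). The
whole test suite runs in well under a minute; the acceptance script in
about fifteen seconds.

## Known limitations

- No receptor flexibility, ordered waters, or ligand internal energy in
  the docking score (strain is a post-filter, as in the original
  workflow's triage).
- The Poisson solver supports only two-valued dielectrics on uniform
  lattices and zero ionic strength.
- The bioisostere SMARTS table and torsion-rule table are curated
  stand-ins, overridable from files; they do not claim equivalence to the
  proprietary sets used in production screens.
- Absolute docking energies are not comparable to production docking-engine scores;
  only orderings, decompositions and invariances are meaningful.
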