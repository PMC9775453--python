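# Methods

This note documents the models, conventions and numerical choices behind
each module, what the synthetic generators do and do not emulate, and the
known limitations.

## Coordinates, symmetry and annotation (`structure_io`)

Internal coordinates are Cartesian ångströms. Fractional coordinates are
kept as read until conversion; orthogonalization follows the *a*-along-*x*,
*b*-in-*xy* convention (delegated to gemmi, which implements exactly this).
Symmetry operators store their translations as exact rationals
(`fractions.Fraction`, denominators ≤ 12) so repeated application of screw
components cannot accumulate floating-point drift.

Macrocycle annotation assigns each atom a chemical role (C1…C6, O2…O6,
substituent slots). Two schemes are supported because crystallographic CIFs
are label-heterogeneous: a label scheme (role read from the label, residues
grouped by residue id) and a connectivity scheme (pyranose six-rings
detected in the covalent-bond graph — heavy-atom pairs closer than 1.8 Å —
with the anomeric carbon identified by its exocyclic glycosidic oxygen).
Ring order always comes from the glycosidic O4(*n*)→C1(*n*+1) linkage; for
ring *ordering* the nearest C1 within 2.5 Å is accepted, a deliberately
tolerant cap (non-bonded candidates sit beyond ~3.5 Å) so that strained,
strongly tilted macrocycles still order correctly. Substitution is inferred
from the carbon chains attached to O2/O3/O6: one carbon → methyl (O2+O6 on
all residues → 2,6-di-O-methyl; all three → permethyl), three or more →
hydroxypropyl. Disordered sites carry an `alt_site` tag and descriptors are
computed per site, never occupancy-averaged.

## Conformational descriptors (`cd_geometry`)

* **Plane fits** minimize the sum of squared orthogonal distances (SVD).
  Normal-sign policy: oriented along a caller-supplied direction when given
  (the host axis), otherwise the largest-magnitude component is made
  positive — an arbitrary but deterministic tie-break. Signed deviations
  always sum to zero by construction.
* **Heptagon centroid** is the arithmetic mean of the seven O4 positions
  (not the plane-projected mean; the difference is < 10⁻³ Å for near-planar
  rings).
* **Tilt angle sign**: the unsigned angle between the O4-plane normal and
  the residue-plane normal is computed with atan2 (well-conditioned near
  0°, unlike acos); the sign is the sign of the dot product between the
  residue-plane normal oriented toward the residue's primary side and the
  inward radial direction at O4(*n*). The primary-side reference is the
  mean of C5/C6/O6 rather than O6 alone: an outward-pointing O6 can lie
  almost in the residue plane, making it a numerically fragile reference.
* **Rotamer states** use the IUPAC torsion sign convention (validated
  against gemmi and MDAnalysis) and a ±30° window per torsion around the
  ideal pairs gg (−60°, +60°), gt (+60°, 180°), tg (180°, −60°); anything
  else is `unclassified`. The window value is a convention of this package;
  the literature names the states without numeric bins.
* **Ring puckering** implements the Cremer–Pople construction for
  six-membered rings in the order O5–C1–C2–C3–C4–C5, under which the ⁴C₁
  chair of a D-glucopyranose lies near the θ = 0 pole. `is_4C1` requires
  θ ≤ 30° *and* Q > 0.1 Å (a flat ring is planar, not a chair).
* **Cavity axis**: O4-plane normal anchored at the O4 centroid, oriented
  from the secondary-rim centroid toward the primary-rim centroid.

## Packing and contacts (`packing_interactions`)

Host-pair orientation uses the signed (secondary→primary) host axes and
the centroid-offset direction: tail-to-tail when the axes point toward each
other, head-to-head when away, head-to-tail when parallel; dot products
within ±0.5 of zero keep the nearest label but raise an "oblique" warning.
Axial/lateral shift decomposition is against the bisector of the two
sign-aligned axes, which keeps the Pythagorean identity exact for parallel
axes. Channel (CH) packing is declared when successive stacked units are
laterally shifted ≤ 3.2 Å — covering the 2.7–3.1 Å range reported for
dimeric cyclodextrin channel structures, with margin; the threshold is
overridable.

Contact criteria are conventional small-molecule crystallographic values,
config-overridable, with inclusive boundaries: hydrogen bonds at
d(D···A) ≤ 3.4 Å (plus d(H···A) ≤ 2.7 Å and ∠DHA ≥ 120° when the donor H is
modelled — without modelled H, as for deposited water, the distance alone
decides); C–H···O at d(H···O) ≤ 2.9 Å and ∠ ≥ 110°; H···H at ≤ 2.4 Å
(twice the H van der Waals radius), excluding geminal and vicinal pairs.
Contact lists are deduplicated per unordered atom pair. Symmetry-expanded
neighbours are included on request by tiling the cell ±1 in each direction
and keeping mates within reach of the asymmetric unit.

## Trajectory analysis (`traj_analysis`)

RMSD follows fit-then-measure with independent selections: frames are
superposed on the reference (frame 0 by default) over the fit selection via
Kabsch (SVD with determinant correction; proper rotations only), then RMSD
is evaluated over the measure selection. This supports both per-entity
RMSD (fit = measure = the entity) and guest-drift monitoring (fit on the
host, measure the guest). Mass weighting is off by default. MD-style
hydrogen-bond criteria (3.5 Å / 135°) are intentionally distinct from the
crystal-mode defaults; the running mean uses a 100-frame window by default
with a growing window at the series head, so the mean always lies within
the count range.

## Phase solubility (`solubility`)

Profile classification: any level dropping more than 5% below the running
maximum marks a B-type isotherm (B_s with a ≥2-point near-maximum plateau,
else B_i); otherwise the quadratic term of a parabola fit decides A_P/A_N
at α = 0.05 (statsmodels OLS t-test), defaulting to A_L. The linear portion
is the longest initial run of ≥3 points with OLS R² ≥ 0.99. With noisy
A_L data the curvature test fires spuriously in roughly the α fraction of
datasets; the fitted slope is then still taken from the linear portion, so
Kc/CE remain accurate even when the label flips to A_P/A_N (visible
occasionally in `analysis/01_phase_solubility.py`).

S₀ is an explicit argument and is never taken from the isotherm intercept:
poorly soluble guests routinely give negative A_L intercepts, which would
be meaningless in the Kc formula — the measured aqueous solubility
(0.0378 mM for piperine) is used instead. Kc = m/(S₀(1−m)) with S₀
converted from mM to M; CE = 100·m/(1−m). Uncertainties are first-order
delta-method propagation of the regression slope's standard error:
sd(Kc) = SE(m)/(S₀(1−m)²), sd(CE) = 100·SE(m)/(1−m)². Published ± values
may derive from replicate scatter instead; the delta-method choice is
documented rather than claimed to match.

## MM/GBSA bookkeeping (`energetics`)

Derived quantities are computed per frame and then averaged; their SDs are
sample SDs (ddof = 1) of the per-frame sums, the convention of MM/GBSA
post-processing tools — not quadrature combinations of component SDs,
which would be correct only for uncorrelated components. A property test
demonstrates the distinction: at zero correlation SD(ΔE_MM) converges to
√(σ₁²+σ₂²), at strong correlation it does not, which is why published
tables' derived SDs differ from quadrature. TΔS is consumed as printed
(normal-mode output; often negative) and ΔG_binding = ΔH − TΔS; entropy is
never computed here. `consistency_check` verifies the four additive
identities of a published summary at a 0.015 kcal/mol tolerance — the
worst residual attainable from two-decimal rounding of the addends.

Running the checker over the published piperine table flags one genuine
inconsistency: in the PN_i.m.2/HP-β-CD column the printed ΔE_vdW + ΔE_ele
misses the printed ΔE_MM by 0.04 kcal/mol and ΔG_GB + ΔG_nonpolar misses
ΔG_solvation by 0.02 kcal/mol — beyond rounding, most plausibly a typo in
one printed component. The other five columns close within 0.01 kcal/mol.

## Synthetic generators (`synthetic_data`)

The builder places seven idealized ⁴C₁ glucose templates (C–C 1.52 Å,
C–O 1.43 Å, tetrahedral-like angles, chair pucker ±0.25 Å on a 1.36 Å
hexagon radius) on an ellipse whose semi-axes are solved so that, over the
seven discrete placement angles, max(d_K)/min(d_K) equals the requested
ellipticity exactly. Template constraints are chosen to make descriptor
recovery exact rather than approximate: each residue's O4, C1 and C4 lie
exactly in the O4 plane at zero tilt, with C1 exactly on the chord toward
the previous O4, so a rigid rotation of the residue about that chord
changes its tilt angle by exactly the applied amount and leaves every O4
in place. The ring spin puts residues upright (C5/C6 toward the primary
rim) and the C6 branch is chosen with D-sugar chirality (ω′ ≈ ω + 120°);
ω is set exactly via torsion placement, ω′ then lands ~19° from the ideal
value — well inside the ±30° classification window. Default O4 radius is
5.05 Å (the β-CD regime, which also makes the glycosidic C1–O4 link come
out near 1.44 Å).

The guest is a generic three-fragment template (aromatic six-ring with two
flanking oxygens — linker — six-ring with one nitrogen) mimicking
piperine's benzodioxole–pentadienoyl–piperidine topology with no
force-field realism. Complexes stack hosts along +z with the requested
orientation, shifts and interplanar angle; trajectories add seeded
Gaussian jitter and deterministic cumulative drift on a selection; phase
solubility curves are piecewise isotherms with relative Gaussian replicate
noise (defaults: S₀ = 0.0378 mM, triplicates, 2% noise, 1–60 mM for A_L and
a 3 mM plateau for B_s — the regimes of the piperine study); energy-frame
tables are correlated Gaussian draws constructively recentred/rescaled so
the sample moments equal the specification exactly. All randomness flows
through explicit integer seeds; equal spec + seed gives bit-identical
output.

What the generators do *not* emulate — and hence what passing closure
tests do not show about real data: thermal conformational ensembles,
anisotropic displacement and disorder statistics of real crystals,
water networks, force-field energetics, or non-Gaussian experimental error
structure.

## Problem sizes

The defaults used by the test suite and analysis drivers are desk-scale by
design: ~100-atom hosts, 10–15-frame closure trajectories (600 frames in
the narrative driver), 200 seeded replicates for the noise-recovery study,
10 000-frame tables for the SD-convention demonstration. The whole suite
runs in a few seconds.

## Known limitations

* Only heptameric (β) cyclodextrins are built and annotated; α/γ would need
  the ring size parameterized through `annotate_cd` and the builder.
* The connectivity annotation scheme requires near-chemical bond lengths;
  heavily strained synthetic builds are ordered via the label scheme.
* Signed O4-plane deviations are reported against the package's normal
  orientation policy; published tables may use the opposite global sign.
* The full-structure geometry checks (deposit-derived τ/d_K ranges,
  interplanar angles, centroid shifts) require the CCDC deposits, which
  cannot be redistributed here; which deposit holds which complex is
  decided by unit-cell matching (`match_deposit`), not by identifier.
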