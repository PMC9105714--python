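# Methods

## Coarse geometric model

All analyses in this package depend only on labelled points: the MB ring
atoms (which define a stacking plane), the two terminal dimethylamino
nitrogens (which define the long axis and anchor electrostatic contacts),
and the GAG anionic-site anchors (sulfate sulfur or carboxyl carbon).
Atomistic sugar geometry, glycosidic torsions and force-field detail are
deliberately out of scope; the chain is a scaffold that holds its sites at
plausible relative positions.

**GAG scaffold.** Backbone beads every 5.0 Å along the chain axis, one per
monosaccharide (dp counts monosaccharides; dp10 = 5 disaccharides).
Anionic sites sit 4.0 Å radially off their residue's bead. The azimuth
alternates by 180° between consecutive residues, and sites sharing a
residue are spread 120° apart. The sub-offset is a deliberate refinement
of a plain alternating phase: it guarantees that a dye nitrogen placed
4.0 Å outside one anchor stays > 8 Å (analytically ≥ 8.5 Å) from anchors
of every other site type, so scripted scenarios can schedule
single-site-type contacts exactly (this separability is asserted by a
test). Hexosamine residues (odd positions) carry N-, 4-O- and
6-O-sulfates; uronic residues (even positions) carry 2-O-sulfates and one
carboxylate each. An optional uniform-turn bend (total tangent turn in
radians, distributed over segments) models bent conformations; the
bending observable is the end-to-end over contour-length ratio of the
backbone beads (1 = extended, 2/π for a semicircle in the fine limit).

**MB template.** A 14-atom planar lattice of three edge-fused benzene-like
hexagons (C–C 1.39 Å) approximates the tricycle; terminal nitrogens sit
1.35 Å outside the terminal rings on the long axis, symmetric about the
centre; formal charge +1. Only planarity, the long axis and the two N
positions matter downstream. Molecules move as rigid bodies (poses =
rotation + translation), so intra-molecular distances are conserved
exactly.

## Stack detection

The ring plane is the least-squares (SVD) plane of the ring atoms; the
normal's sign is fixed by making its largest-magnitude component
positive, preferring z on near-ties, so detection is deterministic.
Collinear inputs are rejected. The inter-plane distance of two molecules
is the mean of the two unsigned centroid-to-plane distances, which makes
it symmetric and equal to the slab separation for parallel planes.
Orientation is the sign of the dot product of the long-axis unit vectors
(terminal-N 1 → terminal-N 2); an exactly perpendicular pair is flagged
indeterminate rather than forced into a class.

Two molecules are stacked when inter-plane distance ≤ 4.5 Å, normal angle
(mod 180°) ≤ 30°, and in-plane centroid offset (the larger of the two
projections) ≤ 3.0 Å. The observed equilibrium spacing is ~3.7 Å but no
detection thresholds accompany it in the source data, so these defaults
were chosen to accept 3.7 Å stacks with thermal wobble while rejecting
T-shaped contacts, and all three are exposed in the configuration and
CLI. Stacks are connected components (size ≥ 2) of the resulting graph;
members are ordered by projection onto the sign-aligned mean stack
normal, ties broken by molecule id, which resolves "adjacent" for spacing
and pairwise orientation. Because whether the reported average spacing
covers dimers only or all adjacent pairs is ambiguous, the summary emits
both readings (`mean_spacing`, `mean_spacing_dimers`).

## Contacts and the sulfation statistic

The dye–site distance is the minimum over the two terminal nitrogens of
the distance to the site anchor — the most permissive reading of "one of
the nitrogen atoms". A pair is in contact when that distance is strictly
below the cutoff (default 8 Å). Per site type the primary report is the
fraction of frames with at least one sub-cutoff pair of that type; the
per-pair mean occupancy is emitted as a secondary column because the
published aggregation convention ("distances … were summed") is not fully
specified. A molecule is bound when it contacts any site; the per-frame
bound count defines the simultaneous-binder summary. For the summary the
convention chosen is n_MB = maximum simultaneous count and t = fraction
of frames at that count; since alternatives (≥ count, episode lengths)
cannot be excluded, the full count distribution is always attached.

D = n_MB · t / n_SO3, undefined (rendered "-") when the chain carries no
sulfates. Reported values are rounded half away from zero to two
decimals; raw values are retained for chaining.

## Energetics bookkeeping

The Generalized Born engine is not reimplemented: the module operates on
component records (ΔG, ΔG_vdW, ΔG_eel, ΔG_esurf, ΔG_eel + ΔG_egb in
kcal/mol). Frames enter energetic analysis when at least three dyes are
bound (configurable). Per-drug columns divide by the number of
interacting drugs and round half away from zero to one decimal. The
additivity identity ΔG = ΔG_vdW + ΔG_esurf + (ΔG_eel + ΔG_egb) is checked
at a tolerance of 0.15 kcal/mol — the worst-case residual from three
independently 1-decimal-rounded addends. Reproduction of a published
per-drug cell is accepted when |total/n − printed| ≤ 0.05 + 0.05/n, since
the printed totals themselves carry ±0.05; the published tables contain
half-way cells rounded in both directions, so exact re-rounding is not a
well-defined target.

The published desulfated-heparin row is internally inconsistent: its ΔG,
eel and (eel+egb) per-drug cells equal the totals divided by 10, not by
the stated 7 interacting drugs, and its components sum to −2.1 against a
printed ΔG of −2.8 (residual −0.7, far beyond rounding). The package
flags all of this (`reproduce_reference_table`) rather than matching it
silently, and the acceptance suite keeps one deliberately failing test on
that row's additivity.

The surrogate scorer used for end-to-end synthetic runs is a transparent
toy: screened Coulomb (prefactor 332 kcal·Å/mol, charges +0.5 e per
terminal nitrogen, −1 e per site, screening length 10 Å) for eel;
Lennard-Jones (ε 0.1 kcal/mol, σ 3.4 Å, 10 Å cutoff, inner clamp at
0.8 σ) over inter-molecular ring/backbone atom pairs for vdW; −0.005
kcal/mol per buried contact (< 4.5 Å pair) for esurf; and eel+egb =
eel × (1 − s) with uniform screening factor s = 0.8. It is deterministic
in coordinates, vanishes at infinite separation, and satisfies the
additivity identity by construction. It is not a free-energy method and
its absolute numbers are meaningless; it exists so the pipeline's
energetic stage runs and its bookkeeping can be exercised.

## Synthetic trajectories

**Scripted mode** is the testing backbone: a per-frame script (stack
membership and position, orientation relative to the stack's first
member, bound flag, optional designated site) is realized exactly.
Stacked neighbours are placed along a shared normal at the target spacing
(default 3.7 Å); antiparallel members are rotated 180° about the stack
normal; bound groups put the first member's terminal nitrogen 4.0 Å
(configurable) from the designated anchor, along the anchor's outward
radial direction; unbound groups are parked on a 45 Å ring, ≥ 20 Å from
the chain and from each other. Identical frame scripts are placed once
and cached, so thousand-frame trajectories cost two placements. Overlaps
(inter-group atom distance < 2 Å) raise an error naming the frame. When
more binders are scheduled than the chain has anchors (the
7-binders-on-5-carboxylates case of the desulfated preset), binders pair
into bound dimer stacks: the partner 3.7 Å above a bound dye is still
within the 8 Å cutoff, so up to two binders per site can be scheduled
exactly.

Ground truth (bound flags, stack membership and orientations, scheduled
time fractions) is emitted alongside and is recovered exactly by the
analysis stages — sizes and orientations exactly, spacings to 1e-6 Å,
fractions to machine precision. What passing these tests shows is that
the analysis operations are correct on geometry they were pointed at;
it does not validate force fields, sampling or any thermodynamics of
real MB/GAG systems, whose disorder (thermal wobble, partial stacking,
solvent effects) the scripted scenes idealize away.

**Monte-Carlo mode** provides mechanistic plausibility, not thermodynamic
rigor. Rigid-body Metropolis: one attempt per molecule per sweep,
translations up to 1 Å, rotations up to 15°, acceptance exp(−ΔE/T) with
T the temperature factor (default 1). The energy has three terms:
hard-core repulsion (any inter-molecular atom pair < 2.5 Å is rejected);
a flat-bottom stacking well, −depth when the centroid separation is
within ±0.8 Å of the 3.7 Å target — the depth is orientation-independent,
and the hard core makes near-parallel plane alignment the only way to
occupy the well, so well occupancy implies detectable stacking; and a
screened-Coulomb attraction −A · (4/r) · exp(−r/λ) summed over (terminal
N, site) pairs. The simulation lives in a reflecting sphere (default
radius 60 Å) centred on the GAG; initial placements are uniform over the
cell with hard-core rejection, which is exactly the stationary
distribution of the force-free dynamics — the null-model test exploits
this by comparing the bound fraction of a force-free run against fresh
draws from that sampler.

Two qualitative contrasts are asserted with paired seeds: deep stacking
wells enrich stacking relative to the null model, and switching the
dye–site attraction on raises the fraction of frames containing a stack.
In this model the GAG promotes the *amount and persistence* of stacking
(stacks held near the chain survive), not the first-passage time to the
first dimer, which showed no stable direction across disjoint seed banks;
the promotion test therefore asserts the occupancy contrast. Test-scale
MC runs use 4–5 molecules, 400–500 sweeps and 15–20 Å cells so that 20
paired seeds complete in seconds while the contrasts stay decisive.

## Determinism and numbers

All randomness flows from a single seed through a documented splitting
rule (SHA-256 of `"<seed>:<stage>"`, reduced mod 2³¹). Same configuration
and seed give byte-identical outputs, including the run manifest. The
trajectory formats write 3-decimal Å coordinates, and reading then
rewriting reproduces the file exactly. Scripted analysis checks use exact
or 1e-6–1e-9 tolerances; plane-fit noise recovery is a seeded 100-run
check (≥ 95 hits within 2°). Problem sizes throughout (1000-frame
scripted runs, 10-frame enumeration oracles, ≤ 6-molecule brute-force
component checks) were chosen so the full suite runs in about a minute on
one CPU.

## Known limitations

- The GAG is rigid within a run; binding-induced conformational change is
  modelled only through the scripted bend parameter, not emergent.
- The MC ensemble has no explicit water, counterions, or long-range
  electrostatics beyond the screened pair term; acceptance rates and time
  scales have no physical mapping.
- The simultaneous-binder convention (max count + fraction at that count)
  is one of several defensible readings; consumers needing another can
  derive it from the attached count distribution.
- The surrogate energy model shares no parameters with MM-GBSA; only its
  bookkeeping shape is comparable.
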