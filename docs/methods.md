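# Methods

`xldisc` models a two-domain exchangeable apolipoprotein (the packaged
sequence is mature apoE4, 299 residues) bound to a discoidal
phospholipid particle, using chemical cross-linking (XL-MS) distance
restraints as the primary experimental input. This note records the model,
its assumptions, the tunable parameters, and the design choices made where
the problem was genuinely open.

## Restraint processing

An XL-MS search engine emits one row per identified cross-linked peptide
pair. The pipeline keeps rows with FDR < 5% and deltaS < 95% (strict
inequalities, both configurable), collapses them onto unique unordered
residue pairs (`res_a < res_b`, `support` = number of collapsed rows), and
attaches a Calpha-Calpha ceiling of 30 Å — the conventional upper bound for
a DSS/BS3-bridged lysine pair. Pairs are classified against the domain
bounds NT = 1–191 and CT = 210–299; the 192–209 linker belongs to neither
domain, so a pair touching it is classified `other` rather than forcing a
domain assignment. All identifications are treated as intramolecular,
mirroring an experiment in which only the monomeric gel band is digested.

A restraint is *satisfied* when the Euclidean Calpha–Calpha distance is
strictly below its ceiling; an exact tie fails. Trajectory validation
judges the trailing window of frames (default the final 10%), either on the
window-averaged distance (`mean`, default) or requiring every window frame
below the ceiling (`all`).

## Chain representation

Chains are Calpha traces. Helices are ideal alpha-helical wheels (rise
1.5 Å/residue, twist 100°, wheel radius 2.3 Å), giving consecutive-Calpha
distances of ~3.83 Å and i/i+3, i/i+4 distances of 5.05 and 6.20 Å.
Optimized conformations keep virtual bonds in 2.8–4.2 Å and no two beads
closer than the excluded-volume floor.

Secondary structure is assigned from geometry alone: a five-residue window
starting at residue *i* is helical when d(i,i+3) ∈ [4.5, 5.7] Å and
d(i,i+4) ∈ [5.6, 6.9] Å, and every residue covered by at least one passing
window is labeled helix. Covering by windows (rather than labeling only
window start positions) treats the two ends of a helical run symmetrically:
an ideal helix of n ≥ 5 residues is labeled helical over its full length,
which is what a run-length measurement such as `longest_helical_span`
needs. The bands sit ±10–12% around the ideal values: tolerant to annealing
noise, but a fully extended chain (d(i,i+3) = 11.4 Å) scores zero helix.
This is a bead-level criterion; it is not DSSP and has no notion of
hydrogen bonds.

The default segmentation places the four N-terminal bundle helices at
24–42, 54–81, 87–122, 131–164, one long C-terminal helix at 210–290 with a
flexible 291–299 tail, and coil elsewhere; the `elongated_h4` variant
extends helix 4 to 131–180 (the 164–168 stretch converted to helix and
merged with the short downstream helix). Helix boundaries beyond H4 follow
the canonical apoE bundle literature and are overridable; the CT helix
bounds are a documented assumption, since only domain bounds are certain.
A hinge window that clips the end of a helix trims that helix back
(`SegmentTopology.with_hinge`); a hinge buried inside a helix is rejected.

## Constraint recipes

Models are generated on an implicit lipid disc (belt radius 46.5 Å,
half-thickness 20 Å, axis z). All soft constraints are flat-bottom
quadratic penalties — zero inside the band, weight × violation² outside —
so the pseudo-energy of a fully satisfied conformation is exactly zero.

Shared elements of both recipes:

* CT helix on the belt annulus (radial band belt+1 … belt+7 Å) and inside
  the bilayer (z ∈ [−10, 0] Å); the hairpin arm runs above it
  (z ∈ [0, 10] Å), so zipped arm/CT partners sit ~10 Å apart vertically.
* CT tail (291–299) pushed radially off the disc (≥ belt+5 Å).
* a loose containment band (radius ≤ belt+11 Å, |z| ≤ 28 Å) keeping the
  chain at the particle — this encodes the measured particle extent.
* excluded volume: no non-bonded Calpha pair below 4.0 Å (hard).

Zippers pair two helix intervals residue-by-residue at 10 ± 3 Å. Bundle
zippers (H1–H2, H2–H3, and H3–H4 in the compact recipe) use a centered
register: helix midpoints align and the longer helix overhangs both ends
equally, as in a packed antiparallel bundle.

The hairpin fold-back pairs arm helices with CT-helix residues by arc
length measured from the hinge: helix residues advance 1.5 Å of arc, coil
residues `coil_arc_advance` (default 0.65 Å — flexible linkers bunch rather
than extend along the belt). This single register parameter was calibrated
so that the fold-back reproduces the opened model's published NT–CT contact
pattern (Lys95 falling opposite CT ~272, which places both Lys262 and
Lys282 within reach); with this value the hinge-186 register is also
nearly balanced, the arm end falling close to the CT helix end.

The opened recipe additionally unfurls the H3–H4 turn, zips H4 and H3
along the CT helix with H3 on the belt, keeps H1–H2 and H2–H3 zipped,
constrains H2 radially outside the lipid core (belt+4 … belt+10 Å), and
adds an *end-closure* band (≤ 22 Å, weight 4) between the hinge-distal arm
end and the CT helix end: the particle carries two chains, each spanning
half the rim, so the two arms of one hairpin meet opposite the apex. The
closure band is the monomer-level stand-in for the second chain's steric
claim on the other half of the belt, hence its high weight. For the
hinge at 186–193 the closure is automatically consistent with the fold-back
register; for the 164–168 hinge, whose arms are strongly unbalanced
(~112 Å vs ~162 Å of arc), closure and fold-back cannot be satisfied
simultaneously — the recipe is internally frustrated, which is the
geometric reason that hinge placement fails validation.

The compact recipe keeps the four-helix bundle closed (three zippers),
lays it along the CT helix with only H4 on the belt, and places H3 radially
outside H4 (belt+7 … belt+13 Å). No closure is applied: the rigid bundle
covers only part of the CT helix, anchored at the hinge.

## Annealing

The CNS-style engine is replaced by an in-house rigid-segment Metropolis
annealer: helices move as rigid bodies, coils are flexible. Moves are
pivot rotations at coil residues (35%), crankshaft rotations between two
coil residues (25%), small rigid-body perturbations of one helix (20%) and
single-bead coil displacements (20%); amplitudes shrink along a geometric
temperature ladder (10 rungs, 15 000 steps by default). Pivot and
crankshaft moves preserve bond lengths exactly; all proposals violating the
connectivity band or excluded volume are rejected outright, so every
visited conformation is sterically valid and the returned model satisfies
both hard conditions by construction.

Annealing starts from an idealized layout implied by the recipe (arcs at
band-center radii, zipper-registered off-belt helices, flexible linkers
wound as compact solenoids and locally repaired to clear excluded volume).
The automatic start temperature is proportional to the layout's initial
strain (E/50, clipped to [1, 200]): a recipe the layout can satisfy is
only locally refined, while a frustrated recipe (e.g. opened with hinge
164–168) is melted and forced to restructure. The best-so-far conformation
is returned; identical (seed, inputs) give bitwise-identical output. A
result whose final pseudo-energy exceeds the schedule tolerance (default
25) is flagged `converged=False`, never silently accepted.

Hinge enumeration builds one model per (hinge, seed) from the recipe alone
and scores it against the cross-link restraints afterwards — restraints
never drive the optimization. Hinges are ranked by mean satisfied count,
ties broken by lower mean pseudo-energy, then input order.

## Explicit nanodisc

Lipids are three-bead pseudo-particles (head + two stacked tails) on
hexagonal leaflet lattices at 68.3 Å² per lipid, head planes at ±19.5 Å
(phosphate positions of a fluid POPC bilayer), within a lipid core of
radius = outer radius (57.5 Å) − belt width (10 Å). At these defaults
round(2πr²/APL) = 208 lipids, consistent with the measured ~200
stoichiometry, and the head-to-head extent plus bead radii gives a 46 Å
thickness, inside the measured 50 ± 10 Å. The head-plane default was
chosen so the lipid extent matches the cited POPC bilayer thickness.
Dimers are generated by exact symmetry (head-to-tail: 180° about the disc
axis; head-to-head: 180° about an in-plane axis), preserving intra-chain
distances bit-for-bit. Diameter is the maximal in-plane bead-center
distance plus twice the largest bead radius; on the TEM-derived outer
diameter of 115 Å the two candidate experimental sizes (Stokes ~105 Å,
TEM 115 ± 10 Å) disagree slightly — the package standardizes on the TEM
value for geometry.

## Accessibility

SASA is computed on the bead representation by Shrake–Rupley with a
deterministic golden-spiral point set (960 points by default; single-sphere
closed-form agreement within 2%, and 960 vs 4000 points agree within 2% on
random clusters). Normalized accessibility divides each bead's area by its
isolated-sphere value — Gly-X-Gly references make no sense without side
chains — so this is a model-level accessibility, not an atomic SASA. The
receptor-binding site defaults to all Arg/Lys/His in 136–150 plus Arg172,
computed from the packaged sequence, because the exact six binding
residues are not enumerated in the source literature; the site is
configurable.

## Synthetic data

The fixtures module generates every input the tests need:

* toy belt conformations — an extended superhelical belt (the double-belt
  style decoy, wound with enough z-pitch that its overlapping wraps stay
  30 Å apart) and hairpins folded at each candidate hinge;
* two conformations whose 22 lysine-pair distances reproduce a packaged
  yes/no compatibility pattern exactly (anchors solved by least squares
  with yes pairs ≤ 24 Å and no pairs ≥ 36 Å, chain threaded through them
  with correct contour lengths); the pattern itself ships as data so tests
  never depend on regenerating annealed models;
* simulated identification tables: each lysine pair under the cutoff is
  reported with probability p, far pairs at rate q, peptide-level
  duplicates injected per a duplication factor (default 27/22, the
  redundancy level of the packaged table), tryptic peptide strings derived
  from the packaged sequence, and score columns that pass the default
  confidence filter;
* docked pose sets with an exactly constructed minimum anchor span.

What the generator does **not** emulate: spectral noise and search-engine
misassignment (scores are cosmetic), heavy/light isotope pairs,
inter-molecular cross-links within the dimer, lipid disorder, and any
side-chain chemistry. Passing tests therefore demonstrate the geometry and
bookkeeping of the pipeline, not robustness to real MS artifacts.

## Problem sizes

Test and acceptance runs use desk-scale settings: 15 000 annealing steps
per model, five seeds per recipe where seed robustness is asserted, three
seeds for the averaged nanodisc diameter, 100 randomized trials per
brute-force oracle comparison, and 960-point SASA. These sizes are the
package defaults; all of them scale up through configuration.

## Known limitations

* The per-hinge satisfied counts depend on engine details; only the
  ordering among hinges is meaningful, and the margin between hinge
  186–193 and 164–168 is small (the frustrated 164 recipe still grazes
  several pairs just under the 30 Å ceiling).
* The published compact-model count (19/22) includes contacts of the free
  N-terminal tail (Lys1) that a recipe without tail constraints cannot
  guarantee; annealed compact models here typically satisfy 11–14 of 22,
  with the bundle contacts stable.
* Cα-bead SASA and secondary structure are coarse proxies; no all-atom
  reconstruction is attempted.
* Lipid count, diameter, thickness and density profiles depend only on
  packing geometry; there is no lipid energetics, solvation or membrane
  elasticity.
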