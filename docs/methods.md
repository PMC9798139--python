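# Methods

## Model

The comparison operates on restrained-solvent MD output: the protein is
fixed, waters move, frames are snapshots of the solvent. Water is the
rigid 3-site TIP3P model; the pair interaction between waters a and b is

    v(a,b) = k_e Σ_{i∈a} Σ_{j∈b} q_i q_j / r_ij + A/r_OO^12 − C/r_OO^6,

a nine-term Coulomb sum over the (O, H, H) sites of each molecule plus a
single Lennard-Jones term on the oxygen–oxygen distance. A pair is
hydrogen bonded when v ≤ −2.25 kcal·mol⁻¹ (the threshold itself counts as
bonded; the comparison is `≤` and configurable). A topological water
network (TWN) is a 3-membered ring: three waters whose three pair energies
all meet the criterion; its centroid is the mean of the three oxygens.
Larger rings and geometric (angle/distance) hydrogen-bond definitions are
out of scope.

Each frame is encoded against a binding site given as an ordered residue
list with the four backbone atoms N, Cα, C, O per residue (64 atoms at the
16-residue default; side chains are excluded so dissimilar residues remain
comparable across proteins). Rings whose centroid lies within
`site_radius` of at least one site atom are retained; the frame vector
holds, per atom, the minimum distance to any retained centroid. Distances
are binned into hydration shells A [0, 5), B [5, 7.5), C [7.5, 10),
D [10, ∞) Å. Frames with no retained ring carry a sentinel (`NO_TWN`,
stored as infinity) that classifies as D and is valued at a 12 Å cap in
frame-difference computations.

To compare proteins P1 (reference) and P2 (query), the query frames are
greedily reordered: reference frames are visited in order, and each step
assigns the not-yet-used query frame with the smallest L1 difference
between distance vectors (ties go to the lowest query frame index).
Similarity is the matched fraction of class labels over all
(frame, atom) cells of the reordered matrices. The procedure is anchored
on the reference, so the score is directional; the CLI can report both
directions and their mean (`--both-directions`).

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| q_O, q_H | −0.834, +0.417 | e | TIP3P site charges (neutrality enforced) |
| A, C | 582 000, 595 | kcal·Å¹²·mol⁻¹, kcal·Å⁶·mol⁻¹ | O–O Lennard-Jones coefficients |
| k_e (`coulomb_constant`) | 332.0636 | kcal·Å·e⁻²·mol⁻¹ | electrostatic conversion |
| `hbond_criterion` | −2.25 | kcal·mol⁻¹ | hydrogen-bond energy threshold |
| `oo_prescreen_cutoff` | 4.5 | Å | O–O distance above which pairs are skipped |
| `site_radius` | 10 | Å | TWN inclusion radius around the site |
| sentinel cap | 12 | Å | value of `NO_TWN` in frame differences |

The electrostatic constant deserves a flag: the energy expression is
usually written with a bare e²/r, leaving the unit conversion implicit.
This package adopts the standard CHARMM/TIP3P value 332.0636
kcal·Å·e⁻²·mol⁻¹, which reproduces conventional TIP3P dimer energetics
(the ideal near-linear dimer at r_OO = 2.8 Å evaluates to −6.07
kcal·mol⁻¹ here). The constant is exposed in `Tip3pParams` for anyone
needing a different convention.

The O–O prescreen is a speed device only: sampling orientations at 4.5 Å
never brings a TIP3P pair below −1.7 kcal·mol⁻¹, well above the −2.25
criterion, and the test suite asserts exact equivalence of detection with
the prescreen on, off, and against a brute-force all-triples scan. It can
be disabled (`oo_prescreen_cutoff <= 0`).

The `site_radius` of 10 Å is a design choice: the operative notion of a
ring being "within the binding site" is not fixed by the method's
definition, and 10 Å matches the outermost informative shell boundary —
a ring farther than that from every site atom could only ever contribute
class D. Class-boundary closure (left-closed upper bins) is likewise a
documented choice; only the outer bins (< 5, ≥ 10) are forced.

Minimum-image wrapping of site–site distances is applied only when box
lengths accompany a frame (from a CRYST1 record); synthetic fixtures are
non-periodic by default.

## Per-frame aggregation

The method's distance matrix is defined per TWN occurrence, but frames can
contain any number of rings while reordering and similarity operate on
fixed-width per-frame rows. This package defines the frame descriptor as
the per-atom **minimum** over that frame's retained ring centroids: it is
fixed-length, permutation-invariant over rings, and reduces to the single
ring's distances when exactly one ring is present. This aggregation is the
principal reconstruction in the package and is isolated in
`frame_distance_vector` should a variable-width encoding be preferred
later.

Similarity cells are counted per atom (not per residue), matching the
per-atom construction of the matrices; columns are comparable across
proteins because binding-site residues correspond position-by-position.

## Greedy, not optimal, assignment

Frame reordering is deliberately the greedy sequential procedure (first
reference frame takes its best match, then the second among the remaining,
and so on), not a globally optimal assignment: the greedy order is part of
the method's definition. The tie-break (lowest query frame index) makes
runs deterministic.

## Synthetic trajectories

The generator emulates what matters to the pipeline: frames containing
hydrogen-bonded water triangles at known positions plus a hydrogen-bond-
free background. A planted triangle places oxygens on an equilateral
triangle of side 2.8 Å (a typical water–water H-bond distance) with each
water donating an O–H to the next oxygen in the cycle, hydrogens built
from the rigid TIP3P internal geometry (r_OH = 0.9572 Å, ∠HOH = 104.52°);
all three pair energies evaluate to −3.52 kcal·mol⁻¹, clearing the
criterion with margin. Background waters are rejection-sampled at ≥ 6 Å
mutual separation, beyond any orientation's reach of the −2.25 criterion,
so they can never form rings. Each frame draws from its own RNG substream
(seeded by trajectory seed and frame index), making any frame reproducible
in isolation; identical spec and seed give byte-identical PDB output.

Coordinate jitter displaces each planted water **rigidly** — one Gaussian
offset per molecule, not per atom. Per-atom jitter would distort the rigid
TIP3P internal geometry and at the larger jitter scales used in the
degradation experiments (up to 4 Å) would produce waters no reader should
accept (O–H sanity window 0.5–1.5 Å). Rigid displacement keeps every frame
valid at any jitter while still destroying the inter-molecular hydrogen-
bond geometry: ring survival falls from 100 % at σ = 0.02 Å to roughly
60 % at σ = 0.1 Å and to zero by σ = 2 Å, which is what drives the
monotone similarity degradation the tests assert.

What the generator does *not* emulate: bulk-water density and structure,
exchange dynamics, long-range order, or a protein. Passing tests
demonstrate the correctness of detection, encoding, reordering and scoring
on controlled ground truth — not that the similarity score discriminates
real binding sites; that judgement requires real trajectories.

## Numerical choices and degenerate inputs

- Energies are evaluated in double precision with no cutoffs other than
  the (provably inert) prescreen; coincident oxygens (r_OO < 1e-6 Å) are
  an error rather than an infinity.
- Binding-site coordinates are static per protein (restrained protein), so
  they are read once from a config or reference structure, never per
  frame.
- Frames with zero waters or zero rings are legal everywhere downstream
  (all-sentinel rows, class D).
- Empty trajectories, mismatched frame or atom counts, non-bijective
  permutations, constant correlation inputs and censored Kd values are
  rejected or warned about explicitly rather than silently coerced.
- Problem sizes in the test and acceptance runs (20-frame trajectories,
  ≤ 40-water frames for oracle equivalence, 10 replicate seeds) were
  chosen to make the brute-force oracles exact companions of every code
  path while keeping the whole suite quick to run.

## Known limitations

- Only 3-membered rings are detected; larger cyclic networks are invisible
  to the encoding.
- The similarity is directional by construction; no canonical
  symmetrisation is imposed.
- The greedy assignment can be arbitrarily far from the optimal transport
  between frame sets on adversarial inputs; this is faithful to the
  method, not a bug.
- GRO input requires MDAnalysis and reads one frame per file; compressed
  trajectory formats are not supported.
- The method presumes comparable proteins (position-aligned pockets of
  equal residue count); it is not a general pocket-matching tool.
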