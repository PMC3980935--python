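# Methods

## Implicit surface model

A frame of n atoms with centers **c**<sub>i</sub> and van der Waals radii
r<sub>i</sub> defines a scalar field f with the convention f > 0 inside the
molecule, f < 0 outside, surface at f = 0:

- **vdw**: f(**p**) = max<sub>i</sub> (r<sub>i</sub> − d<sub>i</sub>),
  d<sub>i</sub> = |**p** − **c**<sub>i</sub>|.
- **sas** (default): f(**p**) = max<sub>i</sub> ((r<sub>i</sub> + R) −
  d<sub>i</sub>), the van der Waals spheres inflated by the solvent probe
  radius R. The solvent-excluded surface (SES) would be the more faithful
  production surface for cavity work; it requires a dedicated functional
  representation that is out of scope here, and the field is pluggable, so
  SAS is the default: it is solvent-aware, exact under the max union, and
  gives sphere tracing a true distance lower bound.
- **kernel**: f(**p**) = Σ<sub>i</sub> b<sub>i</sub>
  e<sup>−a<sub>i</sub>d<sub>i</sub>²</sup> − T, a Gaussian density
  ("blobby") surface, oriented so inside is positive.

The union operator for vdw/sas is max (the standard R-function union).
Consequences used throughout: the gradient of f is the gradient of the
*maximizing* sphere term (a unit vector toward that atom's center), and the
Newton distance estimate |f|/|∇f| equals the exact Euclidean distance to a
single inflated sphere and never exceeds the distance to a union — so
sphere tracing cannot overshoot the first surface crossing.

Neighbor queries use a uniform voxel grid with edge
2·radius<sub>max</sub> + 2·R<sub>max</sub>; the 3×3×3 voxel block around a
point contains every atom whose inflated sphere can reach it. Whenever the
block cannot certify the global maximum (empty block, or best block value
below −(radius<sub>max</sub> + R<sub>max</sub>), the bound on any
out-of-block contribution), evaluation falls back to a full atom scan, so
grid-accelerated and brute-force evaluation agree *exactly* for the union
fields. The kernel field sums the 3×3×3 block only; the grid is sized at
three Gaussian sigmas, bounding the truncation error far below 1e-9.

## Cavity detection

Per atom, k samples (default 16) are drawn at uniform random radius in
[r<sub>i</sub>, r<sub>i</sub> + 2R] with uniform random direction. The RNG
is keyed by (seed, atom index), so the sample set is bit-identical for a
fixed seed and, over a trajectory, samples ride along with their atoms.
This deviates deliberately from holding sample positions fixed in space
over time (with a bounding-box adjustment): atom-keyed sampling is
reproducible frame by frame and never lets a moving molecule drift out of
its sample cloud; `sampling.reposition_fixed` restores the fixed-space
variant for users who want samples decoupled from atom motion. The 2R shell
width is not arbitrary — beyond it an atom cannot influence the SAS, so the
retained exterior samples are guaranteed to lie within 2R of the surface.

A sample with f < 0 is a *cavity* sample iff the ray from it along the
outward normal −∇f/|∇f| re-hits the surface: it then lies between two
opposite-facing surface patches (the working definition of a cavity as a
connected concave patch with at most a narrow mouth). A single ray keeps
the test cheap at ~50 K samples; the cost is that *shallow, open*
depressions are missed by design (a multi-directional ray variant would
recover them at the price of many false positives — a known limitation, not
implemented). The sample is repositioned to the midpoint of the two hits of
the full normal line (near hit toward the surface, far hit across the
cavity), putting nodes on the cavity midline; its radius is the distance
estimate there. Degenerate cases are dropped and counted in the log: zero
gradients (atom centers, kernel saddles) and midpoints that land inside the
molecule (possible in strongly non-convex throats).

## Cavity graphs

Nodes are cavity samples; an edge joins two nodes whose straight segment
stays outside the molecule, probed at spacing δ = R/2 (endpoints included).
Candidate pairs are limited to distance d<sub>vis</sub> = 2·(2R) = 5.6 Å.
Testing literally all pairs is quadratic in the sample count and lets
components fuse through open solvent around the molecule; the locality
cutoff keeps components spatially coherent and the edge set tractable.
Setting d<sub>vis</sub> = ∞ restores the all-pairs behavior. Connected
components are found with union-find (result independent of edge order);
components with fewer than n<sub>min</sub> = 3 nodes are discarded as
sampling noise. Each component's skeleton is its Euclidean minimum spanning
tree (Kruskal), with the deterministic tie-break (length, min node id, max
node id).

Attributes per component: *avgP*, the mean weighted shortest-path length
over unordered node pairs (an overall cavity-size proxy); the *diameter*,
the longest shortest path between any two nodes; and the average node
degree. "Longest path between any two nodes" is implemented as the
shortest-path diameter: the longest *simple* path is NP-hard and useless as
a skeleton metric, while the diameter is canonical and deterministic.
Attributes are computed on the weighted visibility subgraph by default;
`attributes_on="mst"` computes them on the skeleton instead (both are
defensible readings, so both are exposed). Singletons score (0, 0, 0).

## Residue assignment and profiles

The MST skeleton, densified at spacing R/2 (nodes plus edge interiors),
becomes a distance object of width D<sub>g</sub> = 3R. For a skeleton
point **s**, an atom i is a candidate when | |**s** − **c**<sub>i</sub>| −
(r<sub>i</sub> + R) | ≤ D<sub>g</sub> — i.e. the nearest point **q** of its
inflated sphere is within D<sub>g</sub> — and it *contributes* when **q**
is actually on the molecular surface, tested as f(**q**) ≤ ε<sub>iso</sub>
(atom i is the maximizing contributor of the union at **q**; an atom
swallowed by its neighbors always fails). This max-contributor criterion is
deterministic and cheap compared with extracting the surface by ray
casting; it is one concrete reading of "atoms that form the surface near
the cavity". Assignment is monotone in D<sub>g</sub> and invariant under
rigid motion of frame + graph.

The profile marks every contributing atom with its parent residue's class
— hydrophobic {ALA, VAL, LEU, ILE, PRO, PHE, MET, TRP, GLY}, polar {SER,
THR, CYS, TYR, ASN, GLN}, positive {LYS, ARG, HIS}, negative {ASP, GLU} —
and reports the four atom-count ratios (atom-level counting, not
residue-level). The table is overridable (HIS is arguable); unknown residue
names classify as hydrophobic.

Residues are identified to the query layer by residue number alone (the
form queries are written in); `chain_qualified=True` switches to
(chain, number) pairs for multichain inputs.

## Query semantics

Grammar: OR-terms (`∨` or `|`) of AND-terms (`&`) of atoms; an atom is an
integer, a range `lo-hi`, a negation `!atom`, or a parenthesized
expression. Precedence NOT > AND > OR. A range matches when *any* residue
of the cavity falls inside it; conjuncts are evaluated independently, with
no requirement that overlapping ranges be witnessed by distinct residues
(for disjoint ranges — the typical case — the semantics coincide; this
simpler reading is the documented one). A reversed range is a syntax
error, as is the letter `v` (use `|` or `∨`).

Presence fraction of a query = (frames with ≥ 1 matching cavity) / (all
analyzed frames); frames with zero cavities count in the denominator, which
is why the stored corpus records the full frame list in its manifest.
Residue ranking counts (frame, cavity) pairs, descending, ties by id.

## Parameters

| name | default | unit | meaning / rationale |
|---|---|---|---|
| R (`probe_radius`) | 1.4 | Å | water-sized solvent probe |
| `samples_per_atom` k | 16 | — | protein-scale default; raise until the cavity count saturates |
| `d_vis` | 4R = 5.6 | Å | visibility candidate cutoff (∞ = all pairs) |
| `d_g` | 3R = 4.2 | Å | skeleton-to-surface assignment distance |
| `n_min` | 3 | nodes | minimum component size (noise floor) |
| δ (`delta`) | R/2 = 0.7 | Å | segment/skeleton densification step |
| `max_ray_len` | bbox diagonal | Å | far-ray budget; smaller values restrict detection to narrow-mouth cavities |
| ε<sub>min</sub> | 0.05 | Å | minimum sphere-tracing step (termination) |
| ε<sub>iso</sub> | 1e-3 | Å | iso-surface/bisection tolerance |
| N<sub>max</sub> | 1024 | steps | ray step budget |
| vdW radii | H 1.20, C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 | Å | Bondi-style; unknown element → 1.70 with a warning |

Kernel-field rays cap their step at 1/√a (the Gaussian length scale):
unlike the union fields, the kernel's Newton step is not a distance lower
bound and diverges where the gradient vanishes, and no region of density
above the threshold can be thinner than that scale.

## Synthetic fixtures: what they do and do not show

The generators build molecules whose ground truth is known by
construction, all from carbon atoms (inflated radius 3.1 Å) on ~1.8 Å
lattices so every bound is analytic: a lone atom and compact convex
clusters (zero cavities), a slab with a spherical depression of carve
radius 4.8 Å and mouth radius 4.5 Å (exactly one pocket; lining atoms
labeled residue 7 within the analytic reach D<sub>g</sub> + r + R of the
void, so a correct assignment is a subset of the lining), a closed
Fibonacci-lattice shell (one internal void), and a 10-frame "breathing"
trajectory whose pocket is overfilled by a 5-atom lid column in closed
frames and vacated (lid translated +25 Å) in open frames, giving a known
presence schedule. In open frames the hovering lid column and the slab face
each other across empty space, so a small residue-free component between
them is a correct detection, not noise.

These fixtures exercise every pipeline stage at desk scale (hundreds of
atoms, seconds per frame) but are *not* proteins: they have uniform radii,
flat lattices instead of packed side chains, single-digit cavity counts,
and rigid geometry apart from the lid. Passing tests therefore demonstrate
algorithmic correctness (classification, graph topology, assignment,
statistics, determinism), not biological recall on real MD data, where
surface noise, probe-size sensitivity and marginal mouths matter far more.

## Determinism and degenerate inputs

For a fixed (frame, config, seed) every stage is a pure function; two runs
write byte-identical CSV. Ties are broken deterministically everywhere:
gradient maximizer → lowest atom index, Kruskal → (length, min id, max
id), components ordered by lowest member sample. Degenerate gradients make
`distance_estimate` fall back to the ε<sub>min</sub> step and are dropped
(with counts logged) in classification. Empty residue assignments are
allowed and flagged; profiles of empty assignments are all-zero with an
`empty` marker rather than NaN.

## Known limitations

- Shallow open depressions are invisible to the single-ray test (by
  design; see above).
- No cavity tracking across frames — graphs are independent per time step;
  residue queries are the cross-frame link.
- The SES is approximated by SAS/vdw/kernel fields; pocket mouths computed
  on the SAS are systematically wider than SES mouths.
- Kernel-field ray marching is heuristic (step cap), not a guaranteed
  first-crossing method like the union fields.
- PDB reading takes altloc A only, skips waters/ions by default, and does
  not infer hydrogens (if present, they are kept); mmCIF and periodic-box
  unwrapping are unsupported.
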