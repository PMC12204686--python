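# Methods

`spiroscan` quantifies the structural features that distinguish extended
from compact AdhE spirosomes: how much surface the oligomerisation
interfaces bury, how many salt bridges and hydrogen bonds cross them,
whether a probe-accessible channel connects the aldehyde-dehydrogenase
(ALDH) and alcohol-dehydrogenase (ADH) active sites and whether that
channel is sealed from the cytosol, how long a channeled aldehyde
intermediate survives inside the enzyme in simulation, and how spirosome
populations differ in length. This note records the models, the defaults
and the numerical choices, and what the synthetic fixtures do and do not
establish.

## Structure model

Structures are chains → residues → atoms with author numbering preserved
(catalytic residues are cited by author numbers, e.g. C252, H734, D844,
C846, so renumbering would be destructive). Alternate locations collapse to
the highest-occupancy conformer so every downstream count is deterministic.
All geometry is heavy-atom only: deposited cryo-EM coordinate sets carry no
hydrogens, and every criterion below is defined without them. Van der Waals
radii come from a single Bondi-style table applied uniformly (C 1.70, N
1.55, O 1.52, S 1.80 Å, …); an element outside the table is an error, not a
guess. Rigid superposition is the Kabsch algorithm (SVD with a
proper-rotation correction); chain-on-chain superposition pairs Cα atoms
through a global BLOSUM62 alignment (gap open 10, extend 0.5) with gapped
columns excluded. Collinear or coincident point sets are rejected rather
than silently resolved.

## SASA and buried surface area

Solvent-accessible surface area uses the Shrake–Rupley construction: each
atom is inflated by the probe radius (default 1.4 Å, water), a fixed
generalized-spiral (golden-angle) point set is placed on the inflated
sphere (default 960 points), and the accessible fraction is the fraction of
points outside every neighbouring inflated sphere. The spiral point set is
deterministic, so identical inputs give bit-identical areas; doubling the
point count changes totals by well under 0.5 % on the test fixtures.
Waters, ions and cofactors are excluded by default — interface areas are
protein–protein quantities.

Buried surface area between chain groups A and B is
`SASA(A) + SASA(B) − SASA(A ∪ B)`, reported as the **total** buried area
(both faces, not divided by two); the per-side value (total/2) is emitted
alongside. The total convention is the one on which the extended
domain-swapped dimer interface sits at the ~5000 Å² scale and the ADH–ADH
"tetramer" interface at ~2000 Å². The union SASA is evaluated over a
deterministically sorted chain list so BSA(A,B) equals BSA(B,A) exactly.

## Contact networks

The published criteria behind counts like "44 unique hydrogen-bond pairs"
are not stated anywhere we could adopt them from, so the detectors use
explicit defaults, all exposed on the CLI:

* **Salt bridge** — any side-chain nitrogen of Arg/Lys/His within 4.0 Å of
  any carboxylate oxygen of Asp/Glu on the opposite chain group, either
  direction; one contact per residue pair at the minimum distance. His is a
  donor by default (protonation unknown in the deposits) and switchable.
* **Hydrogen bond** — heavy-atom donor–acceptor pairs (N/O/S donors, N/O
  acceptors; main chain and side chain both eligible) within 3.5 Å. An
  optional geometric filter requires the antecedent–donor–acceptor angle to
  be ≥ 90°, which discards pairs whose implicit hydrogen could not point at
  the acceptor; donors whose antecedent atom is missing pass the filter.

Unique-pair counts are over unordered (chain, residue number, insertion
code) pairs, pooled across all interfaces of a deposited model — one count
per structure, matching how the published counts are quoted. Because the
authors' exact criteria are unknown, reproductions of 44/17 are expected at
the ±20 % level with the extended > compact ordering strict, not bit-exact.

## Grid-probe tunnel finding

The channel finder is deliberately **not** MOLE 2.0 (no Voronoi diagram);
outputs label the algorithm "grid-probe", and externally computed sphere
lists can be imported for the downstream operations. A cubic grid (default
0.6 Å) covers the padded structure; a node is open when a probe sphere
there clashes with no atom (centre distance < vdW + probe). Dijkstra runs
over the 26-connected open nodes with

    edge cost = step length × mean(1 / (clearance − probe + ε))

over the two endpoint nodes, ε = 0.1 Å. The endpoint mean makes the cost
symmetric under path reversal; clearance saturates at 10 Å so that empty
bulk, once comfortably wider than any lumen, stops getting cheaper —
without the cap, paths between two interior sites would happily detour
through open solvent. Anchors are caller-supplied coordinates (for AdhE:
the ALDH catalytic cysteine sulfur and the ADH metal-site histidine
centroid); an anchor inside an atom is an error, an unreachable end is a
"no tunnel" result, distinct from an error. Node ordering (x, then y, then
z) breaks ties deterministically. Per-point tunnel radii are exact
clearances to the nearest atom surface (verified against brute force in the
tests, never exceeding it).

Channel-lining residues are those with any heavy atom within local radius +
margin (default 3.0 Å) of the centerline. The enclosure profile labels a
centerline point *exposed* when bulk solvent — the open region connected to
the exterior of the padded box without ever passing within one local
tunnel-radius of the centerline — touches the channel at that point
(within √3 grid steps of its radius). The enclosure grid is padded beyond
the largest tunnel radius so that bulk exists even around an unenclosed
path. This is the operational form of the extended-vs-compact contrast: a
sealed channel yields all-enclosed flags, a channel with a wall window
yields exposed flags at window-adjacent points.

## Composition, enrichment and conservation

Channel-lining composition is counted over one-letter codes; non-standard
residues are excluded and reported. Enrichment of the lining against the
whole protein is

    log2fc[a] = log2( ((c_a + α)/(C + 20α)) / ((p_a + α)/(P + 20α)) )

with a Jeffreys pseudocount α = 0.5, so amino acids absent from the channel
(the hallmark single-lysine signal: aldehyde-reactive amines are all but
excluded from the conduit) stay finite and strongly negative rather than
−∞. Pairwise identity is a global Needleman–Wunsch alignment (BLOSUM62, gap
open 10 / extend 0.5); the identity denominator is aligned columns
excluding terminal-gap columns, the convention under which full-length
CtAdhE vs EcAdhE lands at the round published 62 %. MSA column conservation
is, per non-gap reference column, the percent of rows (reference included)
matching the reference residue, with gaps counted as mismatches. Motif
scanning (`GxGxxG` and friends) matches `x` as a wildcard with overlaps
allowed, 1-based positions. Residue-set homology across species maps set
positions through the pairwise alignment; unmapped positions count as
non-identical and are reported, and a similarity-class percentage is
emitted alongside strict identity because published "homology" figures do
not say which was counted.

## Trajectory post-processing

Residence time is operational: the escape frame is the first frame at which
the minimum ligand–protein heavy-atom distance exceeds 10 Å for 5
consecutive frames (both CLI-exposed and recorded in output metadata);
residence time is dt × that frame; brief excursions shorter than the
sustain window are ignored. A trajectory with no sustained escape is
right-censored at its full duration, and any ensemble mean containing
censored members is flagged as a lower bound — the treatment matching
"still inside at 200 ns" observations — rather than fed to a survival
estimator. Hydrogen-bond occupancy is the fraction of frames with at least
one donor–acceptor pair within 3.5 Å (distance-only; an angle term only
makes sense when hydrogens exist). Path adherence is the fraction of
pre-escape frames whose ligand centroid lies within 5 Å of the tunnel
centerline polyline.

## Length statistics

The two-sample comparison is a Mann-Whitney U test implemented in the
package: midranks for ties; an exact two-sided p by full enumeration of
label assignments when n1 + n2 ≤ 12 (or on request); otherwise a normal
approximation with tie correction and continuity correction. Two-sided p
doubles the smaller one-sided tail, capped at 1. Group summaries report
mean/SD/median and the fraction of spirosomes longer than 100 nm (the
feature that drives the native-vs-exogenous length difference); means are
reported even though the test is rank-based, because the finding is phrased
as a difference in mean length. Conformation proportions carry 95 % Wilson
score intervals.

## Synthetic fixtures: what they are and are not

The generators produce the statistical and geometric structure the analyses
assume — not the AdhE fold or sequence:

* **Toy multimer** — two parallel chains, designed Lys–Asp salt bridges at
  3.7 Å (inside the 4.0 Å salt-bridge cutoff, outside the 3.5 Å H-bond
  cutoff) and Ser–Asn hydrogen bonds at 2.9 Å, alanine filler; every
  fixture re-verifies its own truth with an internal brute-force scan
  before returning, so an accidental extra contact is impossible by
  construction.
* **Channel phantom** — a tube of uniform carbon pseudo-atoms (single
  radius keeps clearance arithmetic exact) whose wall sits at lumen radius
  + atom radius; ring and atom spacing are dense enough that a 1.4 Å probe
  cannot leak between atoms; capped ends make "sealed" mean sealed. Windows
  are carved to a stated free aperture (removal radius = aperture + atom
  radius + probe). Optional Gaussian bulges give a programmed widest point.
* **Trajectories** — a ligand random-walks inside a recorded tube and, from
  a geometrically sampled escape frame on, departs permanently beyond the
  escape distance; a designated donor–acceptor pair sits at bonding
  distance with programmed per-frame probability. Escapes that could not be
  sustained before the trajectory ends are generated as censored instead.
* **Toy MSAs** hit per-column conservation targets exactly at realized
  counts (k = max(1, round(p·n)) matching rows — the reference always
  matches itself); **length samples** are positive-truncated normals, by
  default 1250 measurements per group with an ~20 nm mean shift (80 ± 25 nm
  native vs 60 ± 25 nm exogenous), the scale of the negative-stain
  experiment they emulate.

Passing on these fixtures establishes that the detectors equal their
exhaustive/analytic oracles and recover programmed ground truth under the
stated criteria. It does **not** establish that the default cutoffs
reproduce any particular published count on deposited coordinates: real
interfaces have correlated geometry, partial occupancies and non-ideal
contacts that the fixtures deliberately avoid. The deposited-structure
checks in `tests/test_acceptance.py` cover that step and require the
inputs fetched by `scripts/fetch_inputs.py`.

## Problem sizes

Defaults were chosen so the whole suite runs comfortably on a laptop-class
single core: 960 SASA points (converged to ≪1 % on fixtures), 0.6 Å tunnel
grids on ~40 Å phantoms, trajectory ensembles of 12 replicates × 600
frames, 100-fixture contact sweeps, and 100-seed power checks at the full
n = 1250/group measurement scale. All are ordinary function arguments and
scale up unchanged.

## Known limitations

* The tunnel finder approximates MOLE-style channels; centerlines are grid
  polylines, radii are point clearances, and no physicochemical profiling
  beyond radius/enclosure is attempted.
* Contact criteria are distance-based with an optional coarse angle filter;
  no protonation assignment, π-stacking or cation-π detection.
* Censored residence means are lower bounds, not survival estimates, by
  design.
* Exact Mann-Whitney enumeration is limited to n1 + n2 ≤ 12 in auto mode;
  beyond that the corrected normal approximation is used (within 0.01 of
  exact at the boundary in the tests).
* Trajectory readers handle multi-model PDB and XYZ; binary formats (DCD,
  XTC) are out of scope.
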