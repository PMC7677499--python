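# Methods

## Cavity definition and the rain procedure

A cavity is defined operationally: the set of grid points a water probe
cannot reach from outside the structure by moving along a straight line. The
structure (protein atoms only, van der Waals spheres) is embedded in an
axis-aligned cuboid box with a cubic lattice of spacing `a`. The box is
padded by at least `max_vdw + 2 r_w + 3 a` beyond every atom sphere so that
rays start in free space and the covering dilations never touch the walls.

From each of the six box walls, a probe of radius `r_w` marches inward along
every perpendicular grid line in steps of `a`, marking each visited point.
The ray halts permanently at the first position where the probe sphere
overlaps any atom sphere, with overlap defined strictly
(`center distance < r_w + r_atom`; touching spheres do not block). Because
`a < r_w`, a probe cannot step across a blocking atom. After all six rains,
every point within `r_w` (Euclidean, ≤) of a visited point is marked
covered; visited ∪ covered is the outside of the structure.

Each remaining point is tested directly with the probe: overlap → structure
material; no overlap → cavity center. Material points within `r_w` of a
cavity center form the cavity's covering halo and are counted as cavity
volume, mirroring the covered band on the outside. Chambers are connected
components of cavity centers under 6-connectivity (face adjacency —
corner-touching voids stay separate), each augmented with the halo points
within `r_w` of its centers; a halo point claimed by several chambers goes
to the one with more center points (ties to the lower label). The largest
chamber is the cavity; `V_C = a³ × (centers + halo)` and
`V_T = a³ × material points` (a flag can fold cavity points into V_T for
thickness-style ratios), reported in nm³.

Entrance points are the chamber points face-adjacent to the rain-reached
exterior: the cavity-side mouth of any straight, atom-free corridor to the
outside. A sealed cavity has none. (A stricter reading — a cavity point
whose own axis ray to the wall is fully clear — is provably always empty
here: every point on a clear line is rain-visited, and a blocked endpoint
within `r_w` of visited points is classified as covered exterior before it
could become cavity.)

### Rotation averaging

The six rain directions are axis-aligned, so a single pass is orientation
biased. The whole procedure is repeated for `n_rotations` (default 5)
uniformly random rotations of the structure about its centroid (Gaussian
quaternion construction; each rotation reproducible from `(seed, index)`),
with the box rebuilt per rotation and no grid state carried across
rotations. `V_T` and `V_C` are summarized as mean ± sample standard
deviation. Surface and shell analyses need a single concrete grid; they use
the rotation with the median `V_C` (lower median for an even count). For a
sealed spherical test shell the rotation-to-rotation coefficient of
variation of `V_C` is below 2%.

## Cavity surface and the closure fraction

The cavity surface is the outer boundary of the cavity's probe-center point
set. To find which parts of that boundary face the outside, the rain is
re-run against a pseudo-structure of water spheres (radius `r_w`) centered
on the chamber's cavity-center points; boundary faces of sealed holes inside
the point cloud are excluded (they are not reachable by the pseudo-rain, and
only voxels within `2 r_w + a` of the pseudo-rain front are kept). Surface
area is grid-native: each face between a cavity-center voxel and a
non-center voxel contributes `a²`; their sum is `S_C` (nm²). Face counting
overestimates smooth areas by a bounded orientation factor (≈1.5 for a
sphere); only the dimensionless ratio below is compared across structures.

Each exposed face is classified by its neighbor voxel: faces against
structure material or the cavity halo are protein-contact surface, summing
to `S_CP`; faces against the rain-visited/covered exterior form the open lid
that closes the cavity. The closure fraction `s = S_CP / S_C` is 1 for a
fully buried cavity and falls as more of the boundary opens. A region with
`s < 0.21` is classified as a pocket; the threshold is the survey-derived
`s̄ − 3σ` with `s̄ = 0.36`, `σ = 0.05`, is stored as configuration, and is
recomputed from any batch by the survey summarizer. The inequality is
strict: `s = 0.21` is still a cavity.

An earlier per-point rule (a surface point is "contact" when its nearest
atom is within `r_w + r_atom + a`) was rejected: on thin shadow cavities
nearly every surface point has a nearby atom, which pushed `s` back up for
wide-open cups and broke the expected monotone decrease of `s` with aperture.
The per-face rule is monotone on the cup sweep and gives `s = 1` exactly for
sealed shells. Note a geometric consequence of the straight-line cavity
definition: smooth open cups bottom out near `s ≈ 0.5`, because a rain-shadow
region always keeps roughly half its boundary at the wall that casts the
shadow. Very low `s` arises from sprawling shadow regions whose boundary is
mostly lid, as in rugged real structures.

## Shell residues and descriptors

For every cavity-surface voxel, the residue owning the nearest atom —
minimizing `distance − vdw_radius` — joins the cavity shell. The shell,
of size `N_CP`, carries all chemical and shape descriptors:

- `H = Σ q_i`, the Kyte–Doolittle hydropathy sum, one term per shell residue
  (shipped scale: ILE 4.5 … ARG −4.5). Residues without a defined index
  (non-standard names, if retained) are skipped and counted.
- `h = Σ q_i δ_i`, the hydropathy vector, with `δ_i` the residue position
  relative to the shell center of mass; `|h|` measures the hydropathy
  gradient across the cavity and cancels for chemically uniform symmetric
  shells.
- `R_g`, the root-mean-square distance of shell-residue positions from the
  shell center of mass, in Å.
- Inertia radii and shape: the mass-weighted inertia tensor
  `I = Σ m (|r|² E − r rᵀ)` over all atoms of shell residues about the shell
  center of mass; eigenvalues `D₁ ≤ D₂ ≤ D₃` give `R_α = sqrt(D_α / N_CP)`
  and `w = ΔR / R̄` with `R̄ = (R₁+R₃)/2`, `ΔR = R₂ − R̄`. Spheres give
  w ≈ 0; prolate (cigar) shells w > 0 (two large inertia eigenvalues);
  oblate (planar) shells w < 0. `|w| < 1` always. The residue-count
  normalization of `R_α` follows the published convention even though a
  mass normalization would be dimensionally cleaner; only ratios enter `w`.

Two conventions were genuinely open and are configurable: residue positions
are mass-weighted atom centroids by default (Cα by option), and the shell
center of mass is mass-weighted over all shell atoms. `R_g` and the `R_α`
are reported in Å (their natural scale for single chains, tens of Å);
volumes in nm³ and areas in nm², with survey tables printed at 2 decimals
(H at 1).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `a` | 0.6 Å | lattice constant; accuracy/cost trade-off, must stay < r_w |
| `r_w` | 1.42 Å | water-probe radius |
| `n_rotations` | 5 | random rotations averaged per structure |
| `seed` | 0 | base seed; batch entries derive per-entry seeds from a stable id hash |
| pocket threshold | 0.21 | `s̄ − 3σ` of the closure-fraction distribution |
| radii table | H 1.20, C 1.70, N 1.50, O 1.40, S 1.85, P 1.90, other 1.80 Å | per-element van der Waals radii, overridable; hashed into every record |

Hydrogens are used when present, never added; alternate locations collapse
to the blank/'A' conformer; the first model of multi-model files is used;
non-standard residues are excluded with a warning by default.

## Synthetic fixtures and what they do (and do not) show

All tests run on generated pseudo-structures — spherical shells of
single-atom "residues" on a Fibonacci lattice, with spacing kept below
`0.8 × 2 r_w` so probes cannot leak where closure is intended (construction
fails otherwise). Variants: sealed shells (analytic cavity volume
`(4/3)π(R − r_atom)³` — the probe-center ball of radius `R − r_atom − r_w`
dilated back by `r_w`), open cups (polar cap removed), axis bores, two-void
dumbbells (chamber selection), uniform/bipartite hydropathy labelings (exact
`H`, closed-form `h`), and rings of chains that only jointly enclose a void
(the quaternary contrast). These fixtures validate the geometry and the
descriptor algebra exactly, but they are smooth and single-layered: they do
not exercise rugged protein topography, side-chain packing, partial
occupancies, or the broad closure-fraction distribution of real survey data,
so quantitative agreement on fixtures does not by itself guarantee the
field-survey statistics.

Measured on the sealed 15 Å shell (one rotation), the volume error against
the analytic value shrinks monotonically with the lattice:
8.4% (a=1.2) → 4.6% (0.9) → 2.0% (0.6) → 0.13% (0.3).

## Numerical conventions and edge cases

- Overlap tests are strict (`<`); "within r" coverings are inclusive (`≤`).
  With `r_w/a` irrational in practice, grid distances never tie exactly.
- Euclidean coverings use exact distance transforms; chamber-halo claiming
  restricts each chamber's search to its bounding box plus `r_w`.
- Chamber claiming priority: center count descending, then label ascending.
- Empty chamber → zero surface, `s` undefined (null), no label.
- Shells with fewer than 3 residues or collinear geometry have no shape
  parameter (degenerate inertia tensor → explicit error).
- Survey batches derive one seed per entry from the base seed plus a CRC of
  the entry id, so results are independent of manifest order; failures are
  recorded as rows and never abort the batch.
- Problem sizes used in the shipped checks: shells of radius 8–15 Å
  (200–1000 atoms, grids up to ~155³ at the finest lattice), chosen so the
  whole suite and the acceptance script each run in minutes on one CPU.

## Known limitations

- The straight-line reachability definition is conservative: winding
  channels wider than the probe still count as enclosed, and results depend
  (by design, via averaging) on the rotation sample.
- `s` for thin rim cavities is resolution-sensitive: refining `a` from 0.6
  to 0.3 moves `s` by ≤ 0.03 for sealed shells and wide cups, but by up to
  ~0.1 for the narrow-fringe cavity of a 60° cup.
- Narrow slits only marginally wider than the probe drain a void only
  partially (the rain is straight-line); wide openings drain it completely.
- Surface areas are voxel-face counts: comparable between structures at
  fixed `a`, systematically larger than smooth-surface areas.
- Single static conformation only: no ensemble averaging over thermal
  fluctuations, no protonation or structure repair.
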