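# Methods

## Grid model and MRC2014 handling

A density volume is a 3D scalar field with per-axis voxel sizes and an
origin in Å; in memory the array is always indexed `(i, j, k) = (z, y, x)`.
On read, the MRC axis mapping (`mapc/mapr/maps`, any permutation of 1,2,3)
is resolved into this fixed convention; files are always written with the
identity mapping, mode 2 (32-bit real), spacegroup 1 and version 20140.
Integer label masks are also stored as mode 2: values 0–20 are exactly
representable in 32-bit floats, which keeps a single I/O code path.

Origin resolution follows the two dialects found in deposited maps: the
`origin` header fields are used when nonzero; otherwise the `nstart`
offsets scaled by the voxel size serve as fallback.

The validator checks the eleven documented header constraints
independently and never mutates the file; the overall verdict is the
conjunction of the individual checks. Header statistics are compared
against statistics recomputed from the data with tolerance
`1e-4 · max(dmax − dmin, 1)` to absorb storage rounding, and the
standard's "undetermined" markers (`dmax < dmin`, `dmean < min(dmin,
dmax)`, `rms < 0`) are accepted.

## Preprocessing

**Resampling** maps every volume onto a uniform target voxel size
(default 1 Å) by trilinear interpolation (`scipy.ndimage.map_coordinates`,
order 1); order 0 (nearest neighbor) is available for label masks, where
interpolation between class codes would be meaningless. The output covers
the full input bounding box — `ceil(extent / target)` voxels per axis —
with samples beyond the input support set to 0, so no part of the
original field is cropped. Trilinear interpolation is exact on affine
fields, which is what the exactness tests exercise; any reasonable
resampler agrees on that class.

**Normalization** divides by the 95th percentile (linear interpolation
between order statistics, the numpy default) of the *strictly positive*
densities, then clips into [0, 1]. Negative densities (solvent/noise
regions) become 0; the top ~5 % of positive values saturate at 1. The
percentile estimator is documented because different definitions shift
the divisor slightly; results are reproducible under this one.

## Labeling

Backbone residues are parsed with gemmi (first altloc kept, insertion
codes preserved). Amino-acid types map to integers alphabetically by
three-letter code (ALA=1 … VAL=20, 0 = unknown/non-standard); the mapping
is a module constant, not hard-wired into the mask logic. Secondary
structure comes from the HELIX/SHEET records (helix=2, strand=3,
otherwise coil=1); callers with an external per-residue assignment can
pass it as a table, since deposited HELIX/SHEET annotations are not
always complete.

Coordinate→index conversion has two modes. `nearest` (default) rounds
`(coord − origin) / voxel` to the nearest voxel, ties toward +∞; its
round-trip error is at most half a voxel per axis. `eq1` applies the
floor-then-ceil form `i = ceil(floor(z − origin_z) / voxel_z)` (and
analogously for j, k), kept for compatibility with pipelines that used
it; at 1 Å voxels it reduces to `floor(coord − origin)` and its
round-trip error approaches a full voxel. The verification report
(`verify_labels`) quantifies exactly this: labeled Cα voxels are
converted back to coordinates and matched one-to-one (globally nearest
pair first) against the true Cα positions.

Collisions during mask painting resolve by priority Cα > N > C, first
writer within equal priority, so Cα-derived labels (which feed three of
the four masks) are never overwritten. Atoms mapping outside the grid
are counted and skipped rather than raising: deposited models
occasionally extend past the map box.

## Tiling

Stride = `tile_size − 2·overlap` (20 with the 32/6 defaults). The first
core starts at parent index 0, so leading margins of boundary tiles are
zero padding, and trailing partial cores are clipped to the volume. This
makes the cores a partition: stitching takes each voxel from the unique
tile whose core contains it, and `stitch(divide(V)) = V` for every shape
(property-tested over random shapes 1–70). A missing tile is a coverage
error, not a silent zero region.

## The tracing HMM

States are candidate Cα voxels: voxels whose predicted Cα probability
reaches a threshold (default 0.5; lower it for weak predictions). Each
candidate carries the 20 amino-acid probabilities of its voxel,
renormalized after dropping the background/unknown class.

* **Emissions**: `e_s(a) ∝ sqrt(p_s(a) · bg(a))`, normalized to 1. The
  background table defaults to uniform 1/20 and is user-overridable;
  published per-proteome tables can be dropped in without code changes.
* **Transitions**: Gaussian density over Euclidean distance with mean
  μ = 3.8047 Å (the canonical trans-peptide Cα–Cα spacing) and effective
  SD σ·Λ = 0.36 Å (σ = 0.036 scaled by Λ = 10; Λ widens the Gaussian to
  tolerate voxelization error, which is up to ±0.87 Å in Euclidean
  distance on a 1 Å grid). Support is restricted to neighbors within
  [2.0, 6.0] Å — the Gaussian is negligible outside and full connectivity
  is quadratic in candidates — and each state's outgoing weights are
  renormalized over its neighbor list. If every neighbor weight
  underflows, relative log weights are used directly.
* **Initial distribution**: `π_s = e_s(a₁) / Σ_t e_t(a₁)` over the states
  still available.

**Decoding.** The injective constraint (each state at most once) makes
exact decoding combinatorial, so the decoder is a beam search over
partial injective paths (default beam 32). The path score is
`log π(s₁) + Σ log e + Σ log transition`, all in the log domain (no
underflow out to at least 10⁴ residues); the first residue's emission
appears both inside π and in the emission sum, and the enumeration oracle
in the test suite scores identically, so the two routes are comparable.
Ties break toward the lexicographically smallest state path. With a beam
at least as wide as the number of injective paths the search is
exhaustive; the tests verify equality with brute-force enumeration on
models of up to 6 states. A beam that dead-ends (no extension within the
neighbor window) raises an alignment error naming the failing position —
widening the beam or lowering the candidate threshold are the remedies.

Multiple chains are traced longest-first, each consuming its states
globally before the next starts; longer chains are more constrained, so
they get first pick.

## Synthetic data

The generator emulates the *geometry* and *classifier-output* side of the
problem, not experimental physics. Backbones combine ideal α-helix
Cα geometry (radius 2.3 Å, rise 1.5 Å, twist 100°, chord 3.83 Å),
near-extended strand zigzags (chord exactly 3.8 Å) and a self-avoiding
random walk for coil (step 3.8 Å, non-consecutive separation ≥ 3 Å),
with N and C placed on the Cα–Cα segments. Amino types are drawn from the
uniform background table — the same table the tracer defaults to, so
emission tests are self-consistent. Density maps are sums of isotropic
Gaussian blobs (σ = 1 Å at 1 Å voxels: resolvable but overlapping, like
~2–4 Å maps) plus Gaussian noise (σ = 0.05 of unit blob amplitude), on a
grid with a 5 Å margin.

Oracle predictions give the true class probability `fidelity` at every
voxel and spread the remainder randomly (seeded) over the other classes;
at fidelity 1 the argmax reproduces the masks exactly. Default conditions
for end-to-end tests: 30 residues, mixed motifs (40 % helix, 30 % strand,
30 % coil), fidelity 0.9, which keeps candidate extraction exact while
perturbing emissions.

What passing these tests shows: the pipeline's transforms, bookkeeping
and decoder are correct, and tracing recovers geometry and sequence when
the voxel classifier is good. What it does not show: performance on real
maps, whose noise, missing density and artifacts no blob model
reproduces — evaluating that requires real map/model pairs and a trained
classifier, both outside this package.

## Evaluation conventions

Chain comparison matches Cα atoms one-to-one, globally nearest pair
first, under a 3.0 Å cutoff (the convention of the commonly used
chain-comparison tool; configurable). Matching % is relative to the
*reference* residue count; sequence identity is over matched pairs; RMSD
is over matched pairs only. F1 uses the standard 0-when-undefined
conventions. Dataset resolution bins are [1,2), [2,3), [3,4] Å with
percentages rounded half-up to two decimals; splits shuffle with a seeded
generator and take `floor(fraction·n)` for training, optionally
stratified within resolution bins.

## Problem sizes in the test and acceptance runs

Synthetic end-to-end runs use 30-residue single chains (≈45³-voxel maps);
the tiling property tests use volumes up to 70³; the labeling round-trip
check uses 10,000 random points; Viterbi oracle-equivalence uses models
of ≤ 6 states, where exhaustive enumeration is cheap. These sizes fully
exercise every code path while keeping the whole suite fast.

## Known limitations

* Exact injective decoding is not attempted; the beam can in principle
  miss the optimum on adversarial candidate graphs (beam width trades
  time for optimality).
* Secondary structure relies on deposited HELIX/SHEET records; no
  geometric (DSSP-style) recomputation is provided.
* Nucleic acids, ligands and waters are ignored by the labeler.
* The MRC validator recognizes extended headers only by `exttyp`
  presence; dialect-specific extended-header contents are not parsed.
* `eq1` index mode is provided for compatibility but is not recommended:
  its round-trip error can approach one voxel, versus half a voxel for
  `nearest`.
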