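# mapforge

Tools for turning cryo-EM density maps into voxel-labeled training data
and for tracing protein backbones through predicted Cα voxels.

Single-particle cryo-EM yields 3D electron-density volumes (MRC2014
format) of proteins and complexes. Training voxel classifiers that build
atomic models from such maps requires (a) maps standardized to a common
voxel size and density scale, (b) per-voxel labels derived from the
deposited atomic structure, and (c) a way to turn per-voxel predictions
back into a connected, sequence-assigned backbone. `mapforge` implements
that full path for people building or evaluating map-to-model methods:

* **gridio** — MRC2014 read/write plus an 11-point format validator
  (ID string, machine stamp, mode, dimensions, axis mapping, volume-stack
  divisibility, labels, version, extended header, statistics, file size).
* **preprocess** — trilinear resampling to a uniform 1 Å voxel grid and
  percentile normalization: densities are divided by the 95th percentile
  of the strictly positive values, then clipped into [0, 1].
* **labeler** — paints four integer masks from a PDB model: backbone
  atoms (Cα=1, N=2, C=3), Cα-only, amino-acid type (1–20, alphabetical by
  three-letter code), and secondary structure (1 coil, 2 helix, 3 strand);
  includes the coordinate↔voxel-index transforms and a round-trip
  verification of the labeling.
* **tiler** — cuts volumes into 32³ sub-grids overlapping by 6 voxels and
  stitches per-voxel predictions back from the central 20³ cores.
* **hmmtrace** — the backbone tracer. Candidate Cα voxels become hidden
  states of an HMM; state *s* emits amino acid *a* with probability
  `e_s(a) = sqrt(p_s(a)·bg(a)) / Σ_a' sqrt(p_s(a')·bg(a'))` (geometric mean
  of the predicted amino-acid probability and its background frequency),
  transitions between states follow a Gaussian over their Euclidean
  distance `x` with mean μ = 3.8047 Å and standard deviation
  σ·Λ = 0.036·10 = 0.36 Å, and any state may start a chain with
  probability `π_s = e_s(a₁) / Σ_t e_t(a₁)`. Decoding is a *customized
  injective Viterbi* — no Cα state may occur twice in a path, because one
  position holds one residue — implemented as a beam search over partial
  injective paths and checked against exhaustive enumeration in the tests.
* **evalmetrics** — voxel precision/recall/F1, chain comparison (RMSD over
  matched Cα pairs, % of reference residues matched within 3 Å, sequence
  identity among matches), resolution-bin dataset statistics and seeded
  90/10 train/validation splits.
* **synthdata** — synthetic backbones (~3.8 Å Cα spacing), blob-plus-noise
  density maps and oracle probability volumes with a tunable fidelity, so
  every stage is testable end to end without downloads or trained models.

## Worked example

Generate a 30-residue synthetic protein with oracle predictions at
fidelity 0.9 (the true class gets probability 0.9 at every voxel), trace
its backbone, and compare against the reference:

```sh
$ forge synth --n 30 --motif mixed --fidelity 0.9 --seed 1 -o fixtures
synthetic fixture (30 residues, mixed) -> fixtures
$ forge trace --ca-prob fixtures/ca_prob.mrc \
              --amino-prob fixtures/amino_manifest.json \
              --fasta fixtures/seq.fasta --threshold 0.5 -o traced.pdb
traced 1 chains over 30 candidates -> traced.pdb
$ forge eval --model traced.pdb --reference fixtures/model.pdb
{
  "rmsd": 0.5073045107888025,
  "matching_pct": 100.0,
  "seq_id_pct": 100.0,
  "n_reference": 30,
  "n_matched": 30
}
```

All 30 reference residues are matched within the 3 Å cutoff
(`matching_pct` 100) with the correct amino-acid assignment everywhere
(`seq_id_pct` 100). The 0.51 Å RMSD is the voxelization error: traced
coordinates are voxel centers on the 1 Å grid, so each axis is off by up
to half a voxel. `forge validate-mrc fixtures/map.mrc` confirms the
generated map is MRC2014-compliant, and `forge run config.toml` chains
preprocess → label → verify → tile (→ trace → eval) with a JSON manifest.

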