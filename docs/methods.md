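# Methods

`voxbind` predicts DNA-binding sites on protein surfaces directly from 3D
structure. The unit of prediction is a 1-Å cubic voxel: the model emits a
per-voxel binding probability, and every downstream decision (binarization,
evaluation) is made voxel by voxel. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic test
bed does and does not demonstrate.

## Pipeline

1. **Parsing and screening** (`structure`). A PDB file is reduced to an
   ordered heavy-atom list. Waters and hydrogens are dropped, only the
   first MODEL is kept, and alternate locations resolve to altloc `' '`/`'A'`
   — the simplest deterministic rule; crystal structures rarely justify
   anything richer. Residues are classed PROTEIN (20 standard amino acids),
   DNA (`DA/DC/DG/DT/DI` plus legacy `A/C/G/T`), or OTHER. A complex is
   usable when it contains DNA and every protein atom has a typing-table
   entry; anything else is skipped with a logged reason rather than half
   featurized.

2. **Surface flag** (`surface`). Per-atom solvent-accessible surface area is
   computed with Shrake–Rupley on the protein *in isolation* — DNA is
   removed first, so interface atoms buried under the bound DNA still count
   as surface. That is deliberate: the interface is precisely what the
   model must learn to recognise. Sample points come from a deterministic
   golden-spiral lattice (default 960 points/atom), making results
   reproducible without a sampling RNG. Radii: C 1.7, N 1.55, O 1.52,
   S 1.8, P 1.8, metals 2.0 Å; probe 1.4 Å. An atom is "surface" when its
   SASA exceeds 0 Å² — the most inclusive threshold; both the threshold and
   radii are configurable. Cross-checked in tests against Biopython's
   independent Shrake–Rupley and against a Monte-Carlo surface integration.

3. **Atom typing** (`atom_typing`). Surface protein atoms get one of 16
   codes combining element, hybridisation context (sp2/sp3/aromatic/
   conjugated) and electrostatics (nonpolar/polar/variable/charged); the
   "variable" nitrogen code covers the histidine imidazole nitrogens (either
   protonatable state) and the tryptophan ring nitrogen. The shipped table
   (`data/typing_table.tsv`) covers every heavy atom of the 20 standard
   amino acids. Where the grammar leaves room, the table applies two
   conventions: a side-chain carbon is polar (`C3P`) iff bonded to N or O
   (so LYS CE, ARG CD, PRO CD, SER/THR CB are polar; carbons next to
   sulfur stay nonpolar), and an aromatic carbon is polar (`CRP`) iff
   adjacent to a ring nitrogen or hydroxyl (all five His ring atoms; TRP
   CD1/CE2; TYR CZ). The backbone is NCP/C3P/CCP/OCP with OXT as
   carboxylate `OCC`. `C2P` (isolated sp2 carbon) and `PHO` (phosphorus)
   are members of the closed code set but are not produced by the 20
   standard residues; metals type as `MET` only when hetero records are
   retained. The table is a plain TSV so disagreements can be amended
   without code changes.

4. **Featurization** (`featurize`). The grid covers the protein bounding
   box plus 3 Å padding per side at fixed 1-Å resolution; the origin is
   chosen so an atom at the bounding-box corner sits exactly at a voxel
   center. Each protein atom one-hot encodes its type into its nearest
   voxel over 17 channels (16 types + non-surface). DNA atoms are never
   written to the input — the network must not see the answer. Voxel
   collisions go to the atom nearest the voxel center, ties to the lower
   serial. Ground truth: a voxel is binding iff some protein atom P and
   DNA atom D satisfy dist(v,P) ≤ 6 Å, dist(v,D) ≤ 6 Å and
   dist(P,D) ≤ 6 Å, with voxel distances taken from the center. This
   triple rule is implemented pairwise over protein–DNA contact pairs and
   verified against an exhaustive per-voxel oracle in tests. Augmentation
   uses the 24 proper rotations of the cube, realised exactly as axis
   permutations and flips (no interpolation); grid/mask pairs persist as
   compressed NPZ archives with a JSON geometry sidecar.

5. **Model** (`model`, `autograd`). A 3D fully-convolutional UNET whose
   blocks are DenseNet-style: four 3³ convolution + MISH layers, layer k
   receiving the block input concatenated with all previous outputs
   (in + k·growth channels), followed by a 1×1 transition convolution to a
   fixed `block_channels` width. The transition bounds channel growth
   through the decoder concatenations, which would otherwise grow without
   limit; its width is a config default like the other unspecified widths.
   The encoder pools by 2 between its `n_levels` blocks (average pooling —
   a one-hot occupancy grid is sparse, and averaging preserves occupancy
   fractions across scales); the decoder mirrors with nearest-neighbour
   upsampling and concatenated skip connections, ending in a 1-channel
   sigmoid head, so output spatial shape always equals input shape.
   Arbitrary grids are zero-padded internally to a pool-compatible size and
   cropped back. Tensors ride on a small in-package reverse-mode autograd
   (im2col convolutions, float32), sized for the CPU-scale grids this
   package targets; gradients are verified against finite differences in
   the test suite.

   Training minimises mean per-voxel binary cross-entropy (stable logit
   form; the probability-space loss clamps at 1e-7). A constant p = 0.5
   predictor scores ln 2 ≈ 0.69315 on any label set — the "knows nothing"
   baseline every run is compared against. The optimizer is Adam by
   default, with `adamw` and `ranger` (AdamW + lookahead, k = 6, α = 0.5)
   behind a config switch; the training contract is "an Adam-family
   optimizer", not a particular implementation. Complexes split 9:1 into
   train/validation by complex id — all 24 rotations of a complex stay on
   one side — and any complex whose grid exceeds `max_grid_voxels` is
   forced into validation, mirroring the memory-bound routing of large
   complexes. Everything (init, split, batch order) is seeded; the best
   validation checkpoint is kept.

6. **Binarization** (`postprocess`). Candidate voxels are those within
   6 Å of a surface atom — the support on which a surface-binding score is
   meaningful; clustering bulk vacuum or the protein core would only dilute
   the signal. Candidates become points (x, y, z, score); all four
   dimensions are z-scored, the score axis is then inflated 5×, and k-means
   (k-means++ init, 10 restarts, seeded) forms ceil(n_atoms/1000) clusters.
   A second k-means clusters the per-cluster mean scores into 2 groups and
   the higher-mean group is called binding. Degenerate cases: no
   candidates or zero score variance → empty prediction; a single
   first-round cluster cannot be split in round two, so it is called
   binding only if its mean score exceeds 0.5. Note the granularity
   consequence: below ~1000 protein atoms the first round degenerates to
   k = 1, so desk-scale demonstrations of the mechanism use a
   proportionally smaller `atoms_per_cluster`.

7. **Evaluation** (`metrics`). Confusion counts, accuracy, sensitivity,
   specificity, precision and MCC (zero-denominator convention: MCC = 0),
   plus AUC via the midrank Mann–Whitney statistic (equal to trapezoid ROC
   integration; verified against scikit-learn). The default evaluation
   region is voxels within 6 Å of any protein atom: counting far-field
   vacuum as negatives would inflate specificity arbitrarily with grid
   size. The whole grid remains available as an option, and reports carry
   both micro (pooled counts) and macro (per-complex mean) aggregate rows,
   since either aggregation is defensible.

## Synthetic test bed

`synth` generates two kinds of fixture. Toy complexes trace an α-helix-like
CA spiral with standard residue/atom nomenclature (side chains marched
outward with seeded jitter) beside a twin-strand DNA ladder translated until
the minimum protein–DNA separation hits a requested contact distance
(±0.5 Å, by bisection). Geometry is idealized, not physical: bond lengths
and torsions are wrong on purpose. These fixtures exercise parsing, typing,
SASA, the mask rule, archives and the CLI end to end — they say nothing
about predictive accuracy on real complexes. The planted-pattern dataset
puts a small cube on one input channel with sparse off-channel background;
the mask is that cube dilated by one voxel. Because the mapping is a
deterministic local function of the input, a small network must drive BCE
far below ln 2 if — and only if — the whole conv/backprop/optimizer stack
works; that is a capacity and correctness check, not a biology result.

## Problem sizes

Tests and the acceptance script run on one CPU: 12³ planted grids
(24 samples, 150 training steps, tiny 3-level growth-8 network), toy
complexes of ~8 residues (~240 atoms, grids near 30×30×20), and 20 random
50-atom structures for the mask oracle. These sizes were chosen so the
full suite completes in minutes while every code path is exercised;
production-scale training on real curated complexes uses the same code with
larger `steps`, default channel widths and `max_grid_voxels` routing.

## Known limitations

- The in-package autograd supports exactly the ops this architecture needs;
  there is no GPU path, and very large grids are bounded by im2col memory.
- The typing table is a rule-based reconstruction; borderline chemistry
  (e.g. CA polarity, carbons β to sulfur) follows the conventions stated
  above and can be overridden via a custom TSV.
- The surface threshold (>0 Å²) is maximally inclusive; stricter thresholds
  change which atoms are typed and therefore the input encoding.
- mmCIF input and automatic structure download are out of scope; the
  workflow is local PDB files in, NPZ/TSV artifacts out.
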