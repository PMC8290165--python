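# Methods

This note documents the models, numerical choices and limitations behind
`vasculograph`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted from data the
package cannot generate itself.

## Pipeline overview

A specimen moves through five stages, each usable on its own:

1. **Segmentation** — region-of-interest masking, percentile-window
   gray-map rescale, multiscale Hessian vesselness, global thresholding,
   optional seeded region growing.
2. **Skeletonization** — 3D topology-preserving thinning to unit-width
   centerlines, plus spur pruning.
3. **Graph construction** — 26-neighbor voxel classification, junction
   cluster merging, chain tracing, adjacency encoding.
4. **Metrics** — clustering coefficient (CC), average path length (APL),
   network structure entropy (E, NSE), scale summaries, node-count vs
   vascular-volume regression.
5. **Group statistics** — normality-gated two-group comparison per metric.

All grids are isotropic, indexed (z, y, x), with physical positions equal
to voxel index × voxel size (default 4.5 μm, the resolution of ex vivo
micro-CT of cast rodent livers). Anisotropic input is rejected with a
resample-first message rather than silently mishandled.

## Synthetic phantoms and what they emulate

No public dataset pairs micro-CT angiography volumes with ground-truth
vascular graphs, so validation rests on parametric phantoms. A phantom is a
recursive dichotomous tree grown from a root vessel: each branch draws its
length from N(`branch_length_mean`, `branch_length_sd`), its daughters
deviate from the parent axis by ~N(`bifurcation_angle_mean`, 8°) at a
random azimuth, radii shrink by `radius_taper` per generation (floored at
1.25 voxels, below which a discrete tube can lose 26-connectivity), and
branches are clipped at the grid boundary, mirroring the truncation of an
excised organ. Three phenomena give the two phenotypes their character:

- **Tortuosity** (`tortuosity_amplitude`): a sinusoidal bow of the branch
  centerline, amplitude relative to branch length, plus small mid-point
  jitter. Measured as arc/chord length per edge.
- **Dropout** (`dropout_prob`): each branch, independently, is deleted with
  its whole subtree — the imaging correlate of necrotic, unperfused tumor
  regions. The first three generations are protected so a specimen always
  retains its major vessels; pass-through points left by a deleted sibling
  are contracted away, so every internal ground-truth node is a true
  bifurcation. With dropout 0 the tree is exactly the full binary tree with
  2^(n_levels+1) nodes, which the tests exploit as a closed-form oracle.
- **Anastomoses** (`anastomosis_rate`): cross-links of two kinds — arcs
  between the two daughters of a bifurcation (producing the triangles that
  give vascular graphs nonzero CC) and shortcut arcs between spatially
  close but graph-distant nodes (≥4 hops, within 2.5 branch lengths),
  standing in for the sinusoidal/capillary interconnections that make
  healthy liver an efficient transport network. A strict tree has CC = 0;
  without this extension the clustering comparison between phenotypes would
  be degenerate.

Rasterization draws every edge as a discrete capsule: a voxel belongs to
the mask iff its center lies within the edge radius of the centerline.
Because the rule is exact (no antialiasing), the returned mask doubles as a
segmentation oracle. Additive Gaussian noise is applied afterwards; no clip
is imposed on float volumes unless requested, so the background noise SD
equals the requested SD exactly (8-bit export clips to 0–255).

### Phenotype presets

The presets are qualitative emulations — sparse, tortuous, dilated, and
disorganized versus even, hierarchical, and interconnected — not fits to
any measured vasculature. They were chosen by simulating the generator and
the reconstruction pipeline during design until the two groups separated
cleanly in the intended directions, and then frozen:

| parameter | normal | tumor_like |
|---|---|---|
| grid | 128³ × 4.5 μm | same |
| n_levels | 6 | 10 |
| branch length | 65 ± 13 μm | 55 ± 14 μm |
| root radius / taper | 11 μm / 0.80 | 14 μm / 0.85 |
| tortuosity | 0.05 | 0.35 |
| dropout | 0 | 0.30 |
| anastomosis rate | 0.25 | 0 |
| radius jitter | 0 | 0.30 (lognormal σ) |

The 128³ grid matters: in a 96³ grid the same trees collide with
themselves, and rasterized branch contacts create loops that contaminate
both groups' metrics. Tumor-like trees are deeper but sparser; normal trees
are bushier with cross-links. Consequently normal phantoms have more nodes,
higher CC (triangles), higher NSE (larger, more uniform networks) and
shorter paths, while tumor-like phantoms are smaller, stringier and less
organized — the direction of every group contrast the pipeline is expected
to reproduce. What passing these comparisons shows is that the *pipeline*
preserves and detects such structural differences; it does not show that
real tumors have these parameter values.

Phantoms do not emulate: beam hardening or reconstruction artifacts,
partial-volume intensity gradients at vessel walls, perfusion failures of
the casting agent, capillary beds below voxel resolution, or anatomically
realistic branching asymmetry (Murray-type radius exponents).

## Segmentation numerics

- **Gray-map transform**: percentiles (1, 99.9) map to [0, 1] with
  clipping. Vessels occupy well under 1% of a specimen volume, so windows
  ending at the 99th percentile collapse onto the background; if the window
  is degenerate on a non-constant volume the transform falls back to
  min/max with a warning (constant volumes return zeros, warned).
- **Vesselness**: Frangi filter, bright-ridge polarity, per-voxel maximum
  over scales (default 4.5/9.0/13.5 μm, bracketing the phantoms' 5.6–14 μm
  radii), α = β = 0.5, γ auto. A Gaussian pre-smoothing of one voxel
  (4.5 μm) suppresses voxel-scale noise before differentiation. The
  normalized response is returned through a square-root stretch: raw
  vesselness is so right-skewed that a global Otsu threshold lands inside
  the vessel class; the stretch restores a bimodal histogram whose Otsu
  split sits at the vessel/background boundary. On preset phantoms this
  chain reaches Dice ≈ 0.93 noise-free and ≈ 0.92 at noise of 10% of the
  foreground intensity (the acceptance script recomputes both).
- **Thresholding**: strictly-greater-than convention (ties → background),
  threshold recorded in provenance. Otsu on a constant volume raises a
  degenerate-histogram error.
- **Region growing**: 26-connected, running-mean homogeneity criterion
  |I − mean| ≤ tol, confined to a 2-step dilation of the input mask;
  output always contains the seeded mask components. It is a repair step
  for gaps, not a primary segmenter, and is off in the default pipeline.

## Skeletonization

3D thinning (Lee's method via scikit-image) provides the medial axis. Two
repairs enforce the topology contract:

- Thinning can erase an entire small component (even-width slabs reduce to
  nothing); any input component without a surviving skeleton voxel gets one
  voxel back at its innermost point (maximum distance transform,
  first-in-C-order tie-break), preserving the component count.
- **Spur pruning** walks from each endpoint to the first junction voxel
  and deletes the walked path if it is shorter than `min_length_um`
  (default 13.5 μm = 3 voxels — the scale of single-voxel thinning barbs,
  which would otherwise each mint a fake bifurcation plus terminal).
  Whole components are never removed. If removing a spur leaves its
  junction voxel with mutually 26-connected neighbors, that barnacle voxel
  is deleted too (provably harmless to connectivity). The operation runs to
  a fixed point, so it is idempotent.

## Graph construction details

- Classification thresholds follow the neighbor-count rule exactly; voxels
  with zero neighbors become `terminal_singleton` nodes so they remain
  visible without claiming connections.
- Junction clusters merge by 26-connected components; the representative
  coordinate is the member voxel nearest the cluster centroid, ties broken
  by smallest (z, y, x) — identical inputs always give identical nodes.
- Edge lengths accumulate steps of 1, √2, √3 × voxel size from node voxel
  through the chain to node voxel. Directly adjacent node voxels yield an
  edge with chain length 0.
- Parallel chains between one node pair collapse into a simple edge with a
  `multiplicity` attribute (the metrics are defined on simple graphs);
  chains closing on their own junction are recorded self-loops, excluded
  from the simple edge set and from the metrics. The cycle rank
  (all traced chains + self-loops − nodes + components) is therefore
  conserved, which the torus phantom checks end-to-end.
- A chain cycle touching no node voxel at all (a bare loop, e.g. a torus
  skeleton) is anchored by one node of kind `cycle` carrying a self-loop —
  the one situation the terminal/bifurcation dichotomy cannot express.

## Metric conventions

- CC averages over **all** N nodes, with degree-0/1 nodes contributing 0;
  this keeps CC within [0, 1].
- The APL normalization follows the verbal definition (mean shortest
  distance over pairs). Disconnected specimens are common in practice
  (fragmented casts), so both the `connected_pairs` and `zero_fill`
  conventions are implemented, and every report records which one it used.
  `zero_fill` is the default and is the convention under which heavily
  fragmented networks produce APL values below 1. Which convention any
  given published value used cannot generally be inferred; comparisons
  should state theirs.
- Entropy uses natural logarithms. Normalization is NSE = E/ln N′ with
  N′ the degree-positive node count (E_min = 0, E_max = ln N′); degree-0
  nodes are excluded from the importance distribution (0·ln 0 := 0) with a
  warning. An edgeless graph has no importance distribution and is
  rejected.
- Implementation is vectorized (triangle counts from the cube of the
  sparse adjacency; hop distances from scipy's unweighted shortest-path),
  and the test suite and acceptance script verify it against deliberately
  naive brute-force implementations (pairwise neighbor enumeration,
  pure-Python BFS, direct entropy sum) to 1e-9 on seeded random graphs.

## Statistics

Normality is tested per group with the Kolmogorov-Smirnov statistic
against a normal with estimated parameters, i.e. the Lilliefors variant —
appropriate because population parameters are never known for these
samples. If both groups pass at α = 0.05 the comparison is a two-sided
Student's t-test (equal variances by default, Welch by flag) and groups
are summarized mean ± SD; otherwise a two-sided Mann-Whitney U with
median (25th–75th IQR) summaries. Constant samples are declared non-normal
with a warning rather than crashing the gate. No multiple-testing
correction is applied across the three metrics; the report footer says so.
The acceptance script verifies the empirical type-I error of this gate-plus-
test procedure stays in [0.03, 0.07] over 1000 same-distribution replicates.

## Pipeline and reproducibility

The YAML config is schema-checked (unknown keys rejected by name; phantom
overrides validated by constructing the spec, so range errors carry the
field's own message) and recorded verbatim in the run manifest, along with
the package version and SHA-256 hashes of every output file. All
randomness flows from the single config seed through per-specimen derived
seeds (kept below 2³¹), and every stage is deterministic given its inputs,
so identical config + seed reproduce identical file hashes — the
acceptance script reruns a small pipeline twice and checks this bit-level.
The group comparison stage runs only when each group has at least three
specimens (below that no test in the toolkit is meaningful).

Default problem sizes — 128³ voxel phantoms, 10 specimens per group for
phenotype contrasts, 100 random graphs for oracle equivalence, 1000
replicates for calibration — keep a full desk-scale study within minutes
on one CPU while leaving each check statistically well-resolved.

## Known limitations

- Metrics are hop-count-based by definition; physical-length path metrics
  are deliberately out of scope.
- Radii are not estimated along reconstructed centerlines (the metrics do
  not use them); ground-truth radii exist only on the synthetic side.
- The skeleton-repair voxel for an erased component preserves component
  count but not that component's geometry.
- Segmentation is classical (filter + threshold + growth); no learned
  model, no acquisition-side corrections (flat/dark-field), no manual
  boundary editing.
- Reconstructed graphs of crowded or highly tortuous specimens contain
  contact-induced junctions and loops absent from the generating tree;
  this is a property of voxel-domain reconstruction that real data share,
  not a bug the phantoms hide.
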