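# Methods

This note documents the models, conventions and design choices behind
`lcnmorph`: what each pipeline stage computes, which parameters matter and
why their defaults were chosen, what the synthetic-arbor generator does and
does not emulate, and the numerical details a user would otherwise have to
read out of the source.

## Data model

A reconstruction is a forest of rooted trees over traced points, each point
carrying a position (μm), a local process diameter (μm) and a structure label
(soma / axon / dendrite). Nodes are stored in topological order (parents
precede children), so every traversal is a single pass. Anatomical axes are
decoupled from file x/y/z through an `axis_map`; the default corresponds to
sagittal sectioning (x = rostrocaudal, y = dorsoventral, z = mediolateral)
and can be overridden per file for transversely cut material.

Varicosities are point features in a sidecar table, resolved to a host axon
node at load time: an explicit `host_node_id` wins; otherwise the nearest
axon node within a tolerance (default 2 μm ≈ the largest plausible
varicosity diameter with margin) is used, with distance ties broken toward
the lowest node id so attachment is deterministic. A marker farther than the
tolerance from every axon node is an error, not a silent drop.

The soma is represented both as labelled nodes (a chained ring, so SWC
round-trips are lossless) and as a planar contour polygon used for the area
measurement. Z-shrinkage of histological sections is corrected by scaling
the section-normal axis by nominal/measured thickness; the normal defaults
to mediolateral (sagittal sections).

## Morphometry conventions

- A *segment* belongs to its child node's label; total length is the sum of
  Euclidean segment lengths of a class.
- A *branch point* is a node with ≥ 2 children of its own label, so a
  trifurcation counts once and the soma giving off several stems is not a
  dendritic branch point.
- Segment volume uses the conical frustum between endpoint diameters,
  V = π·l/12·(d₁² + d₁d₂ + d₂²), because traced calibers vary continuously
  along processes; a cylinder is the d₁ = d₂ special case.
- Extents are coordinate spans (max − min) over a class's node positions;
  radii are ignored, matching caliper-style measurements on reconstructions.
- Soma area is the absolute shoelace area of the contour after projection
  onto its best-fit (principal-component) plane — exactly the 2-D shoelace
  for a planar contour, well-defined for a slightly puckered one.
- The *axon origin* is the unique axon node whose parent is not axon-labelled.
  If the parent is a soma node the origin is somatic (distance 0); otherwise
  it is dendritic, and the distance is the path length along the dendrite
  from the nearest soma ancestor to the attachment node. This matches the
  anatomical reading "distance from soma to the axon origin point along the
  dendrite".
- Sholl profiles count features (dendritic branch points or varicosities) in
  half-open concentric spherical shells [k·w, (k+1)·w) around the soma
  centroid (defaults: 50-μm shells for branch points, 100-μm for
  varicosities).
- Path distances to varicosities are measured along the tree from the axon
  take-off node to the host node plus the marker's residual Euclidean offset.
  The reference point is configurable (`axon_origin` or `soma`); the default
  is the axon origin because the propagation model starts there, and for
  these cells the two differ by at most tens of μm against millimetre-scale
  paths.

## Primary-branch decomposition

The main axon is traced from the take-off node by always continuing onto the
child of largest diameter, ties broken toward the longest subtree. This is a
deterministic proxy for what an anatomist identifies visually; it is correct
whenever the main axon stays the thickest process, which holds for the
generator and for typical LCN material where primary branches are distinctly
thinner. Every subtree hanging off the main axon is a primary branch,
numbered in take-off order. Territorial overlap between branches i and j is
|voxels(i) ∩ voxels(j)| / min(|voxels(i)|, |voxels(j)|) on a voxel grid
shared by the whole axon (segments are sampled at edge/4 steps so thin
straight stretches do not skip voxels); the min-normalization makes a small
branch engulfed by a large one read as full overlap.

## Varicosity voxel maps

The axonal bounding box (over axon node coordinates) is anchored at its
minimum corner and padded to whole voxels (default edge 100 μm). Binning is
half-open floor division; a point exactly on the outer box boundary belongs
to the last voxel, so every varicosity maps to exactly one voxel and counts
are conserved. Intensity is count / max(count) per cell (all zeros for an
empty grid), and the VTK export writes the intensity both as color scalar
and implicitly as the opacity channel. The anchor at the bounding-box corner
is a reproducibility choice; any fixed anchor yields equivalent maps up to
voxel relabelling.

## Propagation-time model

Segments are myelinated iff their mean endpoint diameter is strictly above
the threshold (default 0.35 μm, an electron-microscopy-derived boundary
between thick myelinated pieces, mean ≈ 0.76 μm, and varicose unmyelinated
terminals, mean ≈ 0.31 μm). Velocities are power laws anchored at 1 μm:
10 m/s myelinated (linear in d, the classic myelinated-fiber scaling, in the
range of small myelinated dorsal-horn projection axons), 0.38 m/s
unmyelinated (∝ √d, the membrane-limited scaling for unmyelinated fibers,
matching C-fiber velocities measured at room temperature). Both exponents
are configurable in [0, 2]; setting the unmyelinated exponent to 1
reproduces the plain l/(k·d) delay form, and the two parameterizations agree
exactly at d = 1 μm, so the anchors are the invariant quantity. With the
defaults, v_myel(d) > v_unmyel(d) for every d above the threshold
(10·0.35 = 3.5 > 0.38·√0.35 ≈ 0.22 m/s), which guarantees that enabling
myelination never slows any node — a property the tests assert.

Times are accumulated in one preorder traversal from the take-off node;
units work out to delay[ms] = length[μm] / (v[m/s] · 1000). The axon initial
segment is treated like the rest of the axon (its length is not separately
known for these cells). Varicosities add no delay of their own — diameter
irregularities are known to add delay in principle, but are deliberately not
modelled — and a marker's residual offset from its host node is traversed at
the host node's velocity. Propagation is conduction-only: no cable
equations, ion-channel kinetics, branch-point failure or temperature
scaling; room-temperature constants mean absolute times are upper bounds.

`compare_models` reruns the map with all segments forced unmyelinated and
reports 100 · max_thresholded / max_all-unmyelinated. For a uniform
1-μm axon this is exactly 100·0.38/10 = 3.8%; for realistic arbors, whose
distal paths are dominated by thin unmyelinated cable, it sits much higher
(≈ 60–70% for the default synthetic cells), and cells with long thick
solitary branches drop further than compact cells.

## Synthetic arbor generator

Because archival reconstructions are not distributed with the package, the
generator builds LCN-like cells whose cohort statistics emulate the
published all-cell means, and records every measured quantity at
construction time (`GroundTruth`) so that pipeline measurements can be
checked for exact agreement. All draws come from one seeded
`numpy.random.default_rng`; the same seed yields byte-identical SWC and
marker files.

Construction, in order:

1. **Soma** — a 12-point contour ring of diameter 22.4 μm in the sagittal
   plane, stored as chained soma nodes.
2. **Stem dendrites** — count drawn as round(N(4.4, 1.2)) clipped to [2, 8];
   each stem is a graded-step trunk (15/30/45/50/40 μm) with one bifurcation,
   radiating mostly in the rostrocaudal–mediolateral plane. Dendrite
   coordinates are then rescaled per axis to the target extents
   (320/323/159 μm rc/ml/dv) with ±2% jitter.
3. **Axon origin** — dendritic with probability 0.64, at a target path
   distance drawn from N(16, 8) μm clipped to [3, 60] (the nearest stem node
   is used, and the short first stem segment keeps realized distances in
   range); otherwise somatic.
4. **Main axon** — constant 0.76 μm (above threshold, the measured mean
   myelinated caliber), a ventrodorsal loop then a winding rostral run.
5. **Primary branches** — 3–7 (uniform), taking off from successive run
   nodes in an alternating rostral/caudal manner; the first rostral and first
   caudal branch carry the rostrocaudal span, the rest are local
   (350–900 μm). Trunks are 0.5 μm (myelinated) over their proximal 300 μm
   and 0.3 μm beyond, emulating the myelinated appearance persisting only
   into low-order branches. Branches on the same side fan out mediolaterally
   in stratified direction bins so their territories overlap only partially.
6. **Varicose terminals** — every trunk node carries one meandering twig (a
   3-node stem bifurcating into two 4-node daughters, per-step random-walk
   directions at the varicosity spacing, default 8 μm, diameters drawn from
   0.2–0.35 μm — below threshold); the two leading branches additionally
   carry dense bouquets of 14 twigs at staggered path offsets
   (200/450/700/950 μm). One varicosity (diameter uniform 0.5–1.5 μm) sits
   exactly at every twig node, so marker attachment and path-offset handling
   are exact by construction. The bouquets reproduce the compact local
   accumulations that dominate published density maps: with this geometry the
   per-cell maximum 100-μm-voxel count lies stably inside the reported
   79–273 band, with the density peak within the first few hundred μm of,
   but not centered on, the soma, and path-distance histograms peaking
   around 0.5–1.2 mm.
7. **Solitary branch** — with probability 0.33 (or pinned in `SyntheticSpec`) the
   main axon continues distally as a constant-diameter (0.76 μm,
   myelinated-appearing), varicosity-free branch, default 1500 μm — the
   putative propriospinal projection. Modelling it as the distal
   continuation of the main axon keeps the primary-branch count equal to the
   requested number.
8. **Extent calibration** — the finished axon (and its markers) is rescaled
   per axis about the take-off point to the target extents (2312/636/295 μm
   rc/ml/dv) with ±2% jitter, so measured extents land within 5% of targets
   by construction.

Ground truth is measured from the final geometry with independent local
sums that mirror the stated conventions (not by calling the morphometrics
functions), so exact agreement between pipeline and ground truth is a real
consistency check rather than a tautology.

What the generator does **not** emulate: tracing noise, section-boundary
artifacts and missing pieces; realistic dendritic taper and spines;
per-neuron idiosyncrasies of any one published cell (the targets are cohort
means); biological growth rules (alternating branching and the ventrodorsal
loop are geometric, not mechanistic); varicosity diameter–location
correlations. Passing tests therefore demonstrate the *pipeline's*
correctness and the cohort-level plausibility of the synthetic material —
not that the generator reproduces any individual real neuron.

## Numerical choices and degenerate inputs

- Coordinates are μm throughout; no scaling on load. SWC is written with six
  decimals, so round-trips are lossless well below 10⁻³ μm.
- Threshold comparisons are strict ("above" the myelination threshold);
  d = 0.35 μm exactly is unmyelinated.
- Half-open binning everywhere (Sholl shells, path-distance and time
  histograms, voxels), with the outer box boundary closed for voxels.
- An empty feature set yields an empty histogram or an all-zero grid, not an
  error; an empty tree class yields length/volume 0 but extents raise.
- Zero-length segments contribute zero length, volume and delay.
- The all-zero voxel grid reports its centroid at the grid origin.
- CSV outputs are written at six significant digits for byte-stable reruns.
- Cohort sizes: the test suite and the acceptance script use 10–30 synthetic
  cells and random trees up to 10⁴ nodes, enough for the statistical checks
  (two standard errors over 30 seeds) at a few seconds of runtime.

## Known limitations

- The ASC reader supports the documented subset only (trees of samples,
  branch groups, marker blocks) — not the full Neurolucida grammar (no
  colors, spines, section markers or DAT/XML).
- The main-axon rule (largest-diameter child) can diverge from an
  anatomist's visual identification on material where a primary branch is
  locally thicker than the main axon.
- Branch-territory overlap depends on the voxel edge; values are comparable
  only at a fixed edge (default 100 μm).
- Propagation times are estimates for ranking and mapping, not physiological
  predictions (room-temperature constants, no active properties).
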