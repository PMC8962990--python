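# Methods

## Model and procedure

All operators act on 8-bit grayscale volumes (2D images are treated as
single-slice volumes). Flat erosion/dilation use a configurable structuring
element; the default is the 11-neighbour 3D element — the full 3×3 in-plane
square plus the two face-adjacent voxels in the slices above and below.
Homothetic sizes λB are realised as λ-fold iteration of the unit element;
λ = 0 is the identity. At the volume border, out-of-domain neighbours are
ignored (erosion pads with 255, dilation with 0), which keeps
anti-extensivity/extensivity exact on 8-bit data. The exact in-plane/axial
split of the default element is a design choice: the two out-of-plane
voxels are taken at the axial centres.

The max-tree of a volume is built by union-find over voxels sorted by
descending gray level (numba kernels), then canonised; node ids ascend from
the root so every parent has a strictly lower level. The construction works
over an arbitrary neighbour-offset adjacency. Correctness is established in
the test suite against three independent oracles: the tree-reconstruction
identity, a flood-fill regional-maxima oracle, and scikit-image's max-tree
for box connectivities.

For a regional maximum Mi (a tree leaf), the hyperconnected function
gMi = R(f, hMi) is evaluated tree-side: voxel p takes the level of the
lowest common ancestor of p's node and the leaf. Its volume
Vol(gMi) = Σ gMi is computed from the leaf's root path: an ancestor *a* with
path child *c* contributes level(a)·(area(a) − area(c)). Vol is defined as
the sum of the reconstructed function over the whole domain (not a subtree
integral); the two readings rank maxima identically on the constructed test
images, but the whole-domain sum is the one the volume criterion uses. The
hyperconnected opening keeps the supremum of the gMi with Vol ≥ μv (an empty
selection maps to the all-zero bottom); the extreme criterion keeps the
argmax volume, and on a tie keeps *all* tied maxima — their supremum is
deterministic and consistent with the opening's supremum form.

The lower leveling iterates f ∧ [g ∨ (δ₁(g) − α)] to its fixpoint. The
dilation inside the step uses the unit structuring element (finest slope
control; the envelope size λ is reserved for the outer erosion/dilation),
and δ(g) − α is clamped at 0. The marker sequence is non-decreasing and
bounded by f, so termination is guaranteed; convergence is "no voxel
changed", with an error (reporting the changed-voxel count) after max_iter =
10,000 steps. α = 0 reproduces geodesic reconstruction exactly; α = 255
freezes the marker.

## Connectivity

Flat-zone adjacency is configurable (6/18/26 in 3D, 4/8 in 2D). The default
for the max-tree, the levelings and the pipelines is the **graph induced by
the structuring element itself** (10 neighbours for the default element;
exactly 8-connectivity in 2D). This is what makes the exact degeneracies
hold operator-for-operator: the α = 0 leveling propagates along the SE
graph, so it equals the tree-side reconstruction only when the tree uses the
same adjacency — with mixed adjacencies HLL(α=0) and MHF would differ on
3D-diagonal paths. Standalone geodesic reconstruction defaults to 26/8.

## Pipelines

Both pipelines run: optional reconstruction smoothing (opening by
reconstruction after closing by reconstruction, size 2 by default, applied
before the max-tree to cut the number of regional extrema) → erosion at
λ = 3 → selection on the max-tree (extreme volume by default) → full
reconstruction (MHF) or iterated lower leveling at α = 3 (HLL) → dilation at
λ = 3 → Otsu threshold → mask ∧ original. Otsu is computed over the full
256-bin histogram including zeros (a nonzero-only variant is available); the
mask is the strict upper set {f > t} with ties broken toward the lowest t,
so background 0 never enters the mask. No post-threshold cleanup is applied
by default; a largest-connected-component flag exists but is off. The whole
3D volume is processed at once — the structuring element is already 3D.

## The phantom: what it emulates and what it does not

The evaluation phantom is a 64×80×64 head: brain ellipsoid (semi-axes
18/26/18 voxels), dark dura gap, skull and scalp shells (3 and 5 voxels at
120 and 90), and two bright eye spheres (radius 5 at 160) sitting in carved
orbital openings, overlapping the brain margin by about one voxel and the
orbit rim of the skull/scalp shell by a sub-voxel-to-one-voxel annulus. This
reproduces the defining difficulty: above the dura intensity the whole head
is one hyperconnected component, and an erosion at λ = 3 severs the thin
eye necks, separating the brain. Two geometric choices deserve comment:

* **Dura width 5.** The pipelines' own preprocessing (size-2 reconstruction
  smoothing) seals any dark sheet thinner than about twice the smoothing
  size: the closing's marker δ₂(f) bridges the gap everywhere and
  reconstruction cannot restore it, which would fuse brain and skull before
  the max-tree ever sees them. Five voxels is the minimum width whose dark
  core survives, and it mirrors real T1 anatomy, where the CSF/dura gap is
  wide relative to the smoothing scale.
* **White-matter dome.** The brain interior is a parabolic intensity dome
  (mean 140, centre ≈ 149, cortical edge ≈ 134) mimicking bright central
  white matter over dimmer peripheral gray matter. On a perfectly flat brain
  the global maximum — the HLL marker — would be placed by the noise alone,
  occasionally at the brain edge, which makes the slope-α decay traverse the
  full diameter; in real T1 the maximum sits centrally, and the dome models
  exactly that.

Additive Gaussian noise (sd 5, clamped) is applied last; a per-seed
validation asserts the dura stays below the brain's 5th-percentile
intensity, i.e. the volume criterion remains well-posed. The phantom does
*not* model MR physics — no bias fields, partial-volume effects, Rician
noise, or anatomical texture beyond the dome — so passing phantom tests
demonstrates the operators and the pipelines' logic, not clinical
performance on repository data. At this scale both pipelines recover the
brain with Dice ≈ 0.995 over ten seeds, and removing the viscosity (λ = 0,
no smoothing) drops Dice to ≈ 0.44 on every seed.

## Numerical choices and problem sizes

* All intensities are quantised to uint8 on load (min–max rescale when a
  file exceeds [0, 255]); the leveling slope α lives on the same 8-bit
  scale.
* Oracle-equivalence tests run on random volumes up to 12×12×6 (50 volumes
  for the brute-force morphology oracles, 20 for the max-tree identities),
  where nested-loop oracles stay exact and fast; the phantom experiment uses
  ten 64×80×64 seeds. These sizes keep the full suite and the acceptance
  script to a few minutes on one CPU while exercising every code path.
* Determinism: tree construction sorts by (level, flat index), phantom
  generation uses a single seeded generator, and both pipelines are
  deterministic for a fixed input and configuration.

## Known limitations

* T1-weighted contrast is assumed (bright brain over dark dura); other
  modalities would need different criteria.
* The volume criterion presumes the brain is the largest bright structure
  after erosion; severe cropping or pathology could break that premise.
* The lower leveling loses α per unit step, so at fixed α the reconstructed
  fraction of the brain depends on brain diameter; α should be scaled down
  for much larger volumes.
* Anisotropic voxel spacing is carried through I/O but ignored by the
  morphology (the element is defined in voxel units).
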