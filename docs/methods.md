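# Methods

`budvision` implements two computer-vision pipelines for grading dried
chrysanthemum-tea flower buds from plate images, together with the
synthetic benchmark that makes both pipelines testable end to end.

## The two acquisition modes

**Gel mode (`gel16`).** A backlit transmittance imager produces a 16-bit
grayscale frame: dark silhouettes on a bright field, many buds per frame in
an organized grid. All color and texture are discarded by the acquisition
physics; only the silhouette carries information.

**Phone mode (`phone8`).** A hand-held 8-bit RGB photograph of buds on
white paper. Four printed QR-like fiducials mark the corners of a square
sample area; the photograph suffers perspective distortion, an uneven
illumination gradient and a cast shadow. The fiducials allow the sample
area to be located and rectified before segmentation.

## Morphological branch (gel)

The processing chain is: 3x3 median filter (edge-replicated borders) →
Otsu binarization over a 256-bin histogram spanning the image's own
intensity range (so the pipeline is invariant to global linear intensity
rescaling) with the dark side taken as foreground → 8-connected component
labeling with a speck filter (`min_area`, default 64 px²) → Moore
border-following to extract each bud's outer contour as a closed
8-connected pixel chain.

From each (mask, contour) pair, 14 descriptors are computed:

| descriptor | definition |
|---|---|
| perimeter `P` | summed Euclidean steps along the closed chain (1 or √2) |
| area `A` | foreground pixel count |
| long axis `L` | max pairwise distance between contour points |
| short axis `S` | extent of the line through the center of mass ⊥ to the long axis, inside the filled mask |
| incircle radius `r_in` | max of the exact Euclidean distance transform |
| excircle radius `r_ex` | minimal enclosing circle of the contour points |
| area-equivalent diameter `d_eq` | √(4A/π) |
| circularity | 4πA/P² |
| shape parameter | P²/A |
| aspect ratio | L/S |
| compactness | d_eq/L |
| roundness | r_in/r_ex |
| irregularity | population variance of contour-point distances to the center of mass |
| normalized irregularity | same after dividing the distances by their mean |

Center of mass means the filled-region centroid (contour-point centroids
are biased by boundary sampling). The long axis is computed exactly on the
convex hull of the contour (the diametral pair of a point set lies on its
hull) and is test-verified against the all-pairs brute force. The minimal
enclosing circle is delegated to an exact geometric kernel and
test-verified against full pair/triple enumeration.

The feature table is z-scored (population SD, fitted on training rows
only), explored with PCA (sign convention: the largest-magnitude loading
element of each component is positive), and classified with three families
under one protocol: stratified 9:1 train/test split, exhaustive grid
search by stratified 10-fold cross-validation on the training set only,
refit of the winner, single test evaluation. The grids are: KNN with
k ∈ {1..5} × Minkowski power p ∈ {2, 3} (10 candidates); single-hidden-layer
MLP with size ∈ {5, 7, …, 29} × {ReLU, tanh}, Adam solver, up to 1000
iterations (26 candidates); RBF-kernel SVM with C ∈ {2⁰..2¹⁰} ×
γ ∈ {2⁻⁸..2⁰} (99 candidates). Ties resolve to the first candidate in
canonical enumeration order (k then p; hidden size then ReLU before tanh;
C then γ). Standardization is refit inside every CV fold, so model
selection never sees held-out rows.

Two tasks share the feature table: flowering *stage* (2 classes — "fetal"
pre-bloom buds vs open "bloom" buds) and product *type* (7 classes).

## Raw-image CNN branch (phone)

Fiducial detection binarizes the photo, then looks for dark square
components containing exactly one large hole with a centered dark core
(the concentric-square signature); the corner estimate is the mean of ring
and core centroids, which is warp-stable to sub-pixel accuracy. The
homography mapping the four corners to a square is solved and the sample
area resampled bilinearly. Segmentation then runs on the fiducial-free
interior of the rectified image — with the near-black fiducials included
the intensity histogram is trimodal and the Otsu split can land below the
buds. Each bud is cropped with a 2-px margin (background retained),
resized bicubically straight to 50x50 (aspect ratio not preserved) and
scaled to [0, 1], giving the 7,500-dimensional network input.

The network family stacks 2-5 repeated units of convolution → ReLU →
batch normalization → average pooling, followed by one fully connected
layer and softmax. Convolutions are stride 1 with "same" zero padding
(even kernels pad one less before than after). Average pooling uses
window = stride = pool size with ceiling-mode sizing via edge replication:
the production pool sequence 2, 8, 4, 2 on a 50-px input runs
50 → 25 → 4 → 1 → 1, which is infeasible under floor-mode sizing — the
ceiling convention is therefore adopted and audited layer by layer in the
tests. The production architecture uses four units of 32/64/128/256
filters with 2x2 convolutions (175,655 parameters); nine candidate
architectures varying depth (2-5), kernel (2-5) and channel counts are
available for architecture search.

Training minimizes softmax cross-entropy with RMSProp (decay 0.9,
ε = 1e-8) at a constant learning rate of 1e-4, minibatch 128, up to 100
epochs, with seeded shuffling and He initialization. The entire network —
forward, backward and optimizer — is implemented in NumPy; gradients are
verified against numeric differentiation to ~1e-8 relative error, and
seeded runs are bit-reproducible on a fixed thread configuration. After
the last epoch the batch-norm population statistics are re-estimated with
one frozen-weight pass over the training set: with only one or two
minibatches per epoch the running averages kept during training lag the
final weights badly (we observed a 26-point gap between batch-statistics
and running-statistics accuracy on a 189-image task), and the
re-estimation removes that lag exactly.

Architecture search scores candidates on a stratified 10% validation split
carved from the training data; a `paper_mode` switch instead compares
candidates directly on the test set, mirroring published protocols that
accept the selection leakage this implies. Ties resolve to the fewer
parameters.

## Synthetic benchmark

Because no real plate images are distributed with the package, a generator
renders both modes with analytic ground truth. Buds are star polygons in
elliptical coordinates, r(φ) = R·(1 + a·cos kφ + smooth low-order Fourier
perturbation), stretched by an axis ratio and rotated: R controls size, a
and k emulate petal scalloping (driving the irregularity descriptors), the
axis ratio drives the aspect ratio. Canonical circle/ellipse/square
instances additionally carry exact closed-form values of all 14
descriptors (ellipse perimeter via the complete elliptic integral of the
second kind; arc-length-weighted radial variance by dense quadrature),
which the rasterized pipeline must reproduce within stated tolerances.

Seven default class profiles mirror the commercial products' qualitative
ordering: three bloom classes (HB, HG, KX) larger than four fetal classes
(HT, KM, HJ, DT), HG largest and KM/HJ smallest, at roughly 0.4x the
pixel scale of the 295-dpi originals so a 3x3 grid fits a 512-px plate.
Two purpose-built profile sets isolate single factors: `stage` (two
classes with disjoint size ranges, so the size signal alone supports
near-perfect stage classification) and `color` (seven classes sharing one
shape distribution and differing only in hue at near-equal luma — shape
features are uninformative by construction while color is fully
informative, reproducing the headline contrast between the two branches).

Gel plates add Gaussian noise (σ = 600 of 65,535) and salt-and-pepper
specks (5e-4); phone plates add an 8% linear illumination gradient, a 10%
soft shadow, σ = 2 sensor noise, and a random mild projective warp (corner
perturbations up to 3% of the frame). Grid placement jitter is bounded by
0.45x the bud scale so buds sharing a grid row always overlap vertically,
keeping the plate's row-major reading order well defined. The generator
does *not* model: touching or overlapping buds, lens distortion, JPEG
artifacts, color constancy failures, or photorealistic petal texture —
passing tests therefore demonstrate correctness of the algorithms under
controlled conditions, not field performance on real teas.

## Problem sizes and numerical choices

The test and acceptance runs use 30 instances per class (210 instances for
7-class tasks) and train the CNN for 30 epochs — the synthetic color task
saturates within ~15 epochs, so this is comfortably past convergence while
keeping a full run on one CPU core in minutes. Other defaults: Otsu on
256 bins; foreground = dark side in both modes (transmittance silhouettes;
buds darker than paper); 8-connected foreground / 4-connected background;
`min_area` 64 px²; boxes half-open, x = column, y = row, 0-based; short
axis sampled along the perpendicular at 0.25-px steps with nearest-pixel
membership; population (not sample) variance for the irregularity
features.

## Known limitations

- The irregularity features use the raw 8-connected contour-pixel
  distances without arc-length resampling (their defining convention).
  Chains sample axis-aligned boundary runs more densely than diagonal
  ones, so these two features carry a direction-dependent bias of up to
  ~5-10% under arbitrary rotation (exact under 90° rotations) and a mild
  resolution dependence; the other twelve descriptors are
  rotation-invariant to ~3%.
- The short axis is measured on a resampled line and is reproducible only
  to one 0.25-px sampling step under grid flips.
- Segmentation has no watershed step: touching buds would merge (the
  generator forbids overlap; real plates keep buds separated).
- Buds cut by the frame border are not specially handled; the fiducial
  border band of rectified phone plates is excluded from segmentation.
- The 8-connected chain overestimates smooth perimeters by ~5%, which
  propagates into circularity (≈0.90 for a rasterized disk) and the shape
  parameter; tolerances in the tests account for this rasterization bias.
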