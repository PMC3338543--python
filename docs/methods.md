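# Methods

## The measurement model

The pipeline treats a bright-field micrograph as a noisy mid-gray field
in which cells appear as closed dark regions bounded by a bright edge
halo. Guidance is quantified per cell from the *longest* neurite only:
the skeleton branch ending at the endpoint most distal from the soma
centroid. Three angles summarize each cell, all in degrees in
(-180, 180] with 0 pointing toward decreasing concentration (right, in
canonical orientation), +-180 toward increasing concentration (left),
positive up:

- **initiation angle** — direction of the straight chord from the point
  where the traced skeleton branch enters the soma mask to the point 45
  path-pixels farther along the branch;
- **terminal angle** — direction of the chord from the point 45
  path-pixels before the distal endpoint to the endpoint;
- **turning angle** — `|terminal| - |initiation|`; positive means the
  neurite ended more aligned with the gradient than it began.

The 45-px offset equals 16.7 um at the default calibration of
0.371 um/px, the median soma radius in the original data; measuring
"45 pixels away" *along the path* (not as a Euclidean radius) is the
convention used throughout, and the synthetic generator computes its
ground-truth angles with the identical chord rule, so generator and
measurement share one angle definition.

Direction classes partition the circle by a restriction angle R
(default 120, valid 60-180): attracted iff `|angle| >= 180 - R/2`,
else repulsed iff `|angle| <= R/2`, else neutral. Boundaries are
inclusive toward attracted/repulsed, attracted checked first. Turning
angles are classified by a closed +-5 degree neutral band.

The guidance test is a Pearson chi-square goodness-of-fit of the
attracted and repulsed tallies against equal expectation (df = 1, no
continuity correction); neutral cells do not enter. This specification
reproduces the published p-values 0.044 (from 187/150) and 0.005 (from
55/29) exactly at their printed precision. For 93/52 it yields
p = 0.00066, which rounds to 0.0007 rather than the published 0.0006;
the original tabulation for that one entry evidently differed (it may
have included neutral counts, which were not printed). Note also that
the chi-square(1) tail is an asymptotic approximation: at n = 145 it
differs from the exact two-sided binomial null probability (0.00083,
whether computed by `binomtest` or by resampling) by more than
Monte-Carlo error at 10^6 draws. A Yates-corrected statistic would
match the exact binomial closely but breaks agreement with both
reproducible published values, so the uncorrected test is used and the
asymptotic-vs-exact gap is simply documented here.

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| pixel size | 0.371 | um/px | from the stated 45 px = 16.7 um conversion |
| Sobel threshold factor k | 4.0 | — | edge iff magnitude > k x frame-mean magnitude; the original threshold is unstated, k is exposed in config and frozen per run |
| dilation | 3 iterations of 3x3 | px | closes up-to-3-px breaks in thin neurites |
| cell-mask area gate | 5000-30000 | px | 685-4107 um^2: single-neuron size range |
| soma opening element | disk, 31 px wide | px | closest odd-width discrete disk to the 30 px (11.1 um) diameter |
| soma area gate | 2000-10000 | px | 274-1369 um^2 |
| minimum branch length | 45 | px | shorter branches cannot carry a 45-px chord |
| restriction angle R | 120 | deg | sectors of equal width around +-180 and 0; swept 60-180 |
| split fraction | 0.25 | — | raw frames hold the steep gradient in their left quarter (148:444 um span ratio implies a quartile split); configurable since the acquisition geometry is not fully specified |

Normalization is per-image min-max (constant frames map to zeros):
the simplest contract consistent with a fixed relative Sobel threshold.
Border-touching components are excluded by default because their
morphology is truncated and their angles unreliable. Hole filling uses a
4-connected background so that 8-connected edge contours seal. Neurite
length is reported both as the path step count and as the geodesic with
Euclidean step weights (1 axial, sqrt(2) diagonal) times the pixel size;
the geodesic is the default length because a straight-line reading of
"distance from initiation point to the end-point" is also emitted
(`neurite_straight_um`) for audit.

## Tracing rules and tie-breaks

- The distal endpoint maximizes Euclidean distance to the soma centroid;
  exact ties break by smallest (row, col).
- From that endpoint the path follows the skeleton's weighted shortest
  path (Dijkstra) to the nearest soma-mask pixel; because filled masks
  thin to trees this path is unique in practice, and any loop created by
  unusual topology is broken by the geodesic rule and flagged
  (`loop_broken_by_geodesic`) in `qc_flags`.
- The initiation point is the first path pixel inside the soma mask; the
  path is truncated there. Cells whose path never reaches the soma mask,
  or is shorter than 45 steps, are rejected with recorded reasons.

## Exact symmetries

Horizontally flipping a frame must map every measured angle by
`theta -> sign(theta) (180 - |theta|)` and leave lengths and branch
counts unchanged; 180-degree rotation must add 180 (wrapped). Two
implementation details make these symmetries exact rather than
approximate:

- iterative thinning subiterations are directionally biased, so masks
  are thinned in a canonical orientation (the lexicographically smallest
  of the four axis-flip variants) and mapped back;
- the Sobel threshold uses an order-canonical (sorted) sum, making the
  frame-mean bit-identical for mirrored pixel arrays.

One degenerate point is excluded from the attracted/repulsed swap
property: at R = 180 the neutral sector vanishes and `|angle| = 90` is a
fixed point of the mirror lying on the shared closed boundary of both
sectors; the deterministic precedence rule (attracted first) classifies
it identically in both orientations. Continuous angle data never hits
this point exactly.

## The synthetic scene generator

The generator emulates exactly the features the measurement chain relies
on: a mid-gray background (0.5), dark cell interiors (0.22), a 2-px
bright halo (0.88) at every cell boundary so the Sobel stage sees closed
contours, neurites as ~5-px-wide tubes along piecewise-linear waypoints
(45-px segments with a small random turn, default sd 3 deg/segment), and
additive Gaussian noise (sd 0.02). Population defaults — soma radius
35 px, neurite lengths uniform in 100-160 px, somata placed by rejection
sampling with a minimum centre distance of 2.5 soma radii inside a
margin that makes placement independent of neurite direction — were
chosen once so that rendered cells land comfortably inside the published
size gates (cell masks about 6000-9000 px, somata about 4000-5000 px).
Initiation angles follow a von Mises distribution centred on 180 deg
with concentration kappa (kappa = 0 is the uniform control): the
standard single-parameter circular family.

What the generator does **not** model: optical point-spread blur,
uneven illumination, contrast variation between cells, debris,
overlapping cell clusters (beyond incidental neurite crossings), or any
fluorescence channel. Passing the recovery tests therefore shows the
measurement chain is correct for well-formed bright-field-like input,
not that segmentation is robust to every real-world artefact.

A systematic feature worth knowing when interpreting recovery numbers:
the traced neurite starts at the *opened soma-mask boundary*, which lies
a few pixels outside the geometric soma rim the ground truth uses, so
measured geodesic lengths run about 3-8 px short of truth — well inside
the 10% tolerance at the default length range.

## Problem sizes and seeds

The test suite and the acceptance script use synthetic runs of 200 cells
(25 frames of 1200x1200 px, 8 cells each) for morphometry recovery, 100
cells for the biased end-to-end run, 1000 populations of n = 150 for
type-I calibration, 300 replicates per kappa in {0, 0.25, 0.5, 1} for
power monotonicity, and n = 10^4-10^5 angle draws for distributional
checks. All stochastic components take explicit seeds; identical
(inputs, seed) reproduce scenes bit-for-bit and pipeline CSV outputs
byte-for-byte.

## Known limitations

- Only the longest neurite per cell is analyzed; multi-neurite
  morphology is not scored.
- The original normalization and Sobel threshold are unstated; both are
  configurable and the defaults documented here are this package's own
  choices, so absolute segmentation yields are not comparable to the
  original study, only the downstream measurement contracts.
- Touching cells whose masks merge are rejected (multiple somata) rather
  than split; dense cultures reduce yield.
- The slope-ratio identity (exactly 3 for a quartile split) holds to
  floating-point rounding for arbitrary spans; for the published
  148/444 um pair it is exact.
- Static frames only: no cell tracking across time points.
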