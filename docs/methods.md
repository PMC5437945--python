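# Methods

## Landmark scheme

Fifteen homologous points describe the vasculature and blade of a lobed,
palmately veined leaf: paired points straddling each proximal vein at the
petiolar junction (1–2 right, 5–6 left, separated by twice the vein
half-width), one point at the base of each distal vein on its distal side
(4 right, 3 left), the proximal lobe tips (7, 15), proximal sinuses (8, 14),
distal lobe tips (9, 13), distal sinuses (10, 12), and the apex (11). The
paired vein-base points make vein thickness a measurable trait — the feature
that most distinguishes landmark data from outline data when predicting node
position.

## Generalized Procrustes analysis

Full Procrustes superimposition: each configuration is centered and scaled to
unit centroid size (the square root of summed squared deviations from the
centroid); configurations are then iteratively rotated — with reflection
permitted by default — and optimally re-scaled onto a running mean that is
re-estimated and re-unit-sized each pass. Convergence is declared when the
mean moves less than `tol = 1e-10` in Frobenius norm (`max_iter = 200`;
non-convergence sets a flag rather than raising). Pairwise alignment solves
the orthogonal Procrustes problem by SVD; when reflection is disallowed the
smaller singular value's sign is flipped, and an exact tie between the
reflecting and non-reflecting optimum resolves to the determinant +1
solution.

Because the orientation of a GPA mean is arbitrary (it inherits the first
configuration's frame), the converged mean is put in a canonical frame:
principal axes of the mean shape, each axis oriented so that its
landmark-index-weighted coordinate sum is non-negative. Index weights — not
plain moments — are needed so the rule can tell a labeled configuration from
its reflection even when the point cloud itself is mirror-symmetric.
Single-axis flips are reflections and are applied only when reflection is
allowed. With this frame the result is invariant to arbitrary similarity
transforms (and reflections, when permitted) of the inputs. The invariance is
guaranteed in the regime GPA is meant for — many configurations scattered
around a common shape; for widely dispersed arbitrary point sets the GPA
objective can have multiple local optima and no algorithm is
order-independent there.

PCA is run directly on the aligned coordinates without tangent-space
projection: shape variation after superimposition is small in this setting,
making the distinction second-order.

## Elliptical Fourier descriptors

Coefficients are computed in closed form for a polygonal contour with
`dt_p` equal to segment length (the arc-length parameterization; a pixel
chain with steps 1 and sqrt(2) is simply a special case):

    A_n = T / (2 n^2 pi^2) * sum_p (dx_p / dt_p)
          [cos(2 pi n t_p / T) − cos(2 pi n t_{p−1} / T)]

and analogously with sin for B_n and with dy for C_n, D_n; the offsets A0, C0
are the arc-length means of x(t), y(t). Contours are resampled to 500 equal
arc-length points before analysis (configurable) to stabilize coefficients
across image resolutions; 20 harmonic ranks are retained by default.

Normalization removes start point, rotation, scale, and translation using the
first-harmonic ellipse: the start-point phase
`theta1 = 0.5 atan2(2(A1 B1 + C1 D1), A1^2 + C1^2 − B1^2 − D1^2)` rotates
each rank-n coefficient block by `n theta1`; the orientation
`psi1 = atan2(C1*, A1*)` is removed by a spatial rotation; all coefficients
are divided by the semi-major magnitude `E = sqrt(A1*^2 + C1*^2)`; offsets
are discarded. The result satisfies A1 = 1, B1 = C1 = 0 with D1 retaining its
sign (first-harmonic chirality). `theta1` is defined modulo pi; the branch is
fixed from shape content — among the even-rank coefficients, scanned A then D
then B then C in rank order, the first one exceeding 1e-9 in magnitude is
made positive — so normalized coefficients are invariant to where the
traversal started (a raw atan2 branch would flip the sign of every even rank
for start shifts beyond half a period). Shapes whose even-rank coefficients
all vanish are insensitive to the branch by the same token. A first harmonic
with energy below `(1e-12 T)^2` cannot anchor the normalization and is
rejected.

One consequence of the arc-length parameterization worth recording: the
normalized D1 of an ellipse is *not* its semi-axis ratio. For a 2:1 ellipse
the first arc-length harmonic gives D1 ≈ 0.5869 (verified against adaptive
quadrature of the Fourier integrals), not 0.5; the 0.5 value belongs to the
angular parameterization. The test suite asserts the quadrature value.

Boundary tracing of binary masks is Moore-neighbor following with Jacob's
stopping criterion, starting at the top-most then left-most foreground pixel,
emitted counterclockwise in math coordinates (x = column,
y = height − 1 − row). Pixel centers are vertices; masks must contain exactly
one 8-connected foreground component of at least 4 pixels.

## Morphospaces and eigenleaves

Covariance PCA (no per-trait standardization — traits share units within each
block) with constant columns (variance < 1e-12) dropped and recorded; for
normalized EFD traits this removes A1, B1, C1, which are invariants of the
normalization rather than traits, and they are restored at their constant
values whenever a trait vector is reconstructed. Component signs follow the
convention that each loading's largest-magnitude entry is positive.
Eigenleaves are `mean + m * sqrt(eigenvalue) * loading`, mapped back to a
15-point configuration (landmark block) or through the inverse Fourier series
(EFD block). An all-constant trait matrix yields a zero-component model
rather than an error.

## Discriminant analysis

Gaussian LDA with pooled within-class covariance and observed class-frequency
priors, the classification rule being maximum posterior under equal-covariance
Gaussians. The solver is scikit-learn's SVD-based one, which handles a
singular pooled covariance by truncating negligible directions; this plays
the role a diagonal ridge would otherwise play for the near-collinear
80-column EFD blocks, so no explicit ridge term is added. Near-constant
traits are screened (variance ≤ 1e-12) and recorded before fitting. All
reported predictions are leave-one-out: each sample is classified by a model
fitted to all other samples, which compensates for uneven replication across
species and vines. A LOO fold may reduce a class to a single training
sample; the discriminant remains defined and the fold proceeds (at least two
classes must survive). Node position is a categorical class for the LDA and
an ordinal only in the Spearman correlation of actual versus predicted node
(`t = rho sqrt((n−2)/(1−rho^2))`, two-sided). Feature-set comparison tables
report per-group percent correct for landmarks, EFDs, and their
column-concatenation, with exact ties resolved both > landmark > EFD and
flagged.

## Trait correlation and clustering

Spearman's rho on mid-ranks (tie-corrected) for every trait pair, p-values
from the t approximation (cross-checked against scipy's implementation in the
tests); p-values are reported unadjusted, as the display convention masks
only p < 0.05. Constant traits have undefined correlations and are recorded
as missing and excluded from clustering. Clustering is agglomerative on
d = 1 − rho (signed; complete linkage by default, `1 − |rho|` and other
linkages available). d is symmetric with zero diagonal but violates the
triangle inequality — acceptable for agglomerative use, and stated here so no
one mistakes it for a metric. Trait names are sorted before clustering so
exact distance ties resolve lexicographically. The dendrogram is exported as
Newick and as a merge table.

## Synthetic leaf generator

A leaf is built from interpretable parameters (defaults in parentheses, blade
length units): midvein length (1.0), distal/proximal lobe lengths
(0.75 / 0.55), lobe angles from the midvein (0.55 / 1.05 rad), distal and
proximal sinus depths (0.35 / 0.25, the fraction by which the sinus point is
drawn in from the adjacent lobe tips), vein half-width (0.02), signed
asymmetry (0), serration amplitude (0), outline sample count (500). The 15
landmarks are placed per the scheme above; the outline is a periodic cubic
spline (chord-length parameterized) through the nine blade landmarks plus a
small basal anchor, so landmark and contour data are mutually consistent by
construction. At zero asymmetry the outline is mirror-symmetric to machine
precision; landmarks lie on or inside the outline within the spline-sampling
tolerance (~1e-4 blade lengths at 500 points, shrinking quadratically).

Asymmetry scales the left-side lobe lengths and angles by (1 + a) and the
right side by (1 − a). The antisymmetric form matters: it preserves the
symmetric shape component to first order, so asymmetry variance isolates into
the B/C harmonic coefficients (the separation is exact only in the small-a
limit; at |a| ≈ 0.05 a second-order symmetric leakage is measurable).
Signed a, with either side allowed to be the larger, makes the B/C block
uncorrelated with the symmetric traits — a one-sided |a| would couple them
through the shared magnitude.

The dataset generator composes species mean parameters, a per-node additive
heteroblastic gradient (defaults: distal sinus depth +0.02, proximal sinus
depth +0.015, distal lobe length +0.01 per node — later nodes more deeply
lobed, monotone by construction), Gaussian per-leaf noise (SD 3% of each
parameter's magnitude, floor 0.005), and signed asymmetry noise
(SD 0.05, species-independent). Sampled parameters are clipped into the
generator's validity region. The default template is 8 species in 4 classes,
species means separated by 3 between-leaf SDs along random directions in
parameter space (class archetypes twice as far), 3 vines per species, 10
nodes per vine — 240 leaves, a desk-scale stand-in chosen so the whole
pipeline runs in seconds; the real collections this emulates are an order of
magnitude larger, with 7–28 nodes per vine. One integer seed drives a
spawned per-leaf RNG stream, so generation is deterministic.

What the generator does **not** emulate: serration-scale high-harmonic
texture (off by default), multi-lobed shape polymorphism within a species,
allometric size gradients (size is removed by both analyses anyway),
node-to-node alternation of asymmetry (phyllotactic signature), measurement
noise in landmark placement separate from biological variation, and imaging
artifacts of scanned leaves. Passing tests therefore demonstrate the
correctness of the machinery and the recoverability of planted effects, not
the effect sizes of any real collection.

## Problem sizes and numerical checks

Unit and acceptance tests run on the 240-leaf default template and smaller;
brute-force oracles are used where feasible: a 0.001-rad rotation grid for
pairwise and generalized Procrustes on 4-landmark configurations, adaptive
quadrature of the Fourier integrals for EFD coefficients on random 20-gons
(relative tolerance 1e-6), and direct covariance eigendecomposition for PCA.
Chance-level controls permute labels and compare leave-one-out accuracy with
the binomial band around 1/k. Pipeline determinism is asserted on SHA-256
manifests of all outputs (the config copy, which records run-local paths,
and the timestamped log are excluded from hashing).
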