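# Methods

## Problem

Outline-based geometric morphometrics quantifies the shape of a closed
2-D silhouette — here, lacewing (Neuroptera) larval head capsules with
their paired piercing stylets — and compares the *disparity*
(morphological variety, as opposed to species counts) of groups of
specimens across time slices with very unequal sampling: rich extant
collections against sparse Cretaceous/Eocene/Miocene amber records.
`morphodisp` implements the full chain: elliptic Fourier descriptors of
outlines, a PCA morphospace, and bootstrap/rarefaction-corrected
sum-of-variances disparity with pairwise tests.

## Elliptic Fourier descriptors

A closed outline traversed at uniform speed along its arc length has
coordinate functions x(t), y(t) of period T (the perimeter).  Their
Fourier series yields, per harmonic n, four coefficients
(a_n, b_n, c_n, d_n) plus centroid constants (A0, C0).  For a polygonal
contour the integrals are evaluated exactly segment by segment
(`efa.compute_efd`); no quadrature is involved.  Tests cross-check the
closed form against an independent trapezoid integration of the Fourier
integrals (10^4 samples, agreement ~5e-9).

The descriptors are parameterised by **arc length**, as in the classic
chain-code formulation and the software lineage this package follows.
One consequence worth knowing: an ellipse with semi-axes (2, 1) does
*not* reduce to the single harmonic (2, 0, 0, 1) — that value belongs to
the equal-angle parameterisation.  Under arc length the exact first
harmonic is (1.8284, 0, 0, 1.0730) and small higher "reparameterisation"
harmonics appear.  A circle, whose arc length and angle coincide, is the
clean closed-form fixture: (1, 0, 0, 1) and nothing else.

### Normalisation (NEFDs)

Size, rotation, translation and digitisation starting point are removed
by standardising on the first-harmonic ellipse: a starting-point phase
θ = ½·atan2(2(a₁b₁ + c₁d₁), a₁² + c₁² − b₁² − d₁²) rotates harmonic n by
nθ in parameter; the spatial rotation ψ = atan2(c₁*, a₁*) is removed;
all coefficients are divided by the semi-major axis E*.  Afterwards
a₁ = 1, b₁ = c₁ = 0, and |d₁| ≤ 1 is the first ellipse's aspect ratio.

θ has two solutions π apart (the two ends of the major axis), which
differ only in the sign of the even harmonics.  Conventions that pick
the solution from the pre-normalisation coefficients (e.g. requiring
a₁* > 0) are **not rotation-invariant**: the same shape rotated far
enough flips branches and all even harmonics change sign.  We therefore
break the tie shape-intrinsically: the leading even-harmonic entry
(first of a₂, b₂, c₂, d₂, a₄, … exceeding 1e-7) is made positive.  With
this rule the NEFDs of similarity-transformed and re-started copies of a
shape agree to ~1e-15 (tested at 100 transforms × 10 shapes).  Shapes
whose even harmonics all vanish (pure ellipses) are unaffected by the
ambiguity.

A reflection alignment (negate b_n, d_n when d₁ < 0) is available behind
`allow_reflection` but off by default: outlines are stored
counterclockwise, which pins d₁ > 0 for consistently digitised material.
Near-circular first harmonics make θ ill-conditioned; this is harmless
for the elongated head+stylet shapes the pipeline targets but is a known
limitation for round outlines.

### Feature matrix

The PCA input drops the normalisation constants a₁, b₁, c₁ (identically
1, 0, 0) and keeps d₁, giving 4N − 3 features for N harmonics (77 at the
default N = 20).  Keeping d₁ follows the convention of analysing all
non-constant normalised coefficients; it carries the first ellipse's
aspect ratio, a biologically meaningful elongation signal.

## Morphospace PCA

Covariance-matrix PCA (centred, not scaled): harmonic coefficients share
units, and unit-variance scaling would inflate the low-amplitude high
harmonics.  The decomposition is delegated to
`sklearn.decomposition.PCA` (full SVD); eigenvalues use the (n − 1)
denominator and conserve total feature variance to 1e-9.  Eigenvector
sign is fixed by making the largest-magnitude loading of each component
positive, so runs are platform-reproducible.  Components with eigenvalue
above 1e-12 × total variance are retained and passed downstream; the
rest are numerical null space.  Per-group, per-slice occupation is
summarised as per-PC min/max/range on the untreated (non-resampled)
scores; empty subsets yield explicit n = 0 rows.

## Disparity

The disparity of a subset is the **sum of variances** of its retained PC
scores — the trace of the subset's sample covariance ((n − 1)
denominator).  Uncertainty: each of `n_boot` (default 10,000) bootstrap
replicates draws m specimens with replacement and records their sum of
variances.  **Rarefaction** sets m below the subset size so subsets of
very different n are compared at a common size; the default
"smaller-group" policy uses, for each group, the smallest of its
time-slice subsets (the fossil slice, usually).  Rarefied replicates are
still with-replacement draws, mirroring the combined
bootstrap+rarefaction of the established disparity tooling.

Per-subset random streams are seeded as crc32(root:group:slice), so
adding or removing a subset never perturbs another subset's draws; the
same scheme (root, group, slice, index) seeds each synthetic individual.

### Pairwise tests and their caveat

Subset pairs (within each group, across its time slices, by default) are
compared with Welch two-sample t-tests **on the bootstrap replicate
vectors**, Bonferroni-corrected across the pairs tested.  Replicates of
the same data are not independent observations, so with n_boot in the
thousands these tests are massively anticonservative — under the null
(two subsets from one generative distribution) they reject far above the
nominal level, a property the test suite asserts rather than hides.
The procedure is retained because it is the established workflow in the
disparity literature this package reimplements; every p-value row is
labelled "bootstrap-replicate t-tests (anticonservative)", and
`percentile_overlap` offers a calibrated alternative (do the 2.5–97.5%
replicate intervals intersect, and how much of the narrower interval is
shared).

## Synthetic data generator

`synthetic` renders parametric head+stylet silhouettes: a superellipse
head capsule (exponent 2 = ellipse, > 2 boxier, < 2 diamond-like — the
dustywing extreme) unioned with two bilaterally symmetric tapering
stylet bands whose centerline is a circular arc (signed curvature;
positive bends the tips inward, antlion-fashion) with optional
sinusoidal tooth bumps on the inner edge.  Components are polygonised at
512 points each before the union; the union boundary is resampled to
equal arc-length spacing (default k = 200 points, comfortably above the
2 × 2 × 20 samples needed for 20 harmonics) and validated (simple,
counterclockwise, ≥ 8 distinct points).

Groups are archetypes plus within-group Gaussian parameter noise;
strictly positive parameters (lengths, widths, exponent, tooth
amplitude) are perturbed on the log scale so they stay positive, the
signed curvature additively.  Draws whose polygon self-intersects, or
whose crossed stylet tips enclose a hole, are rejected and redrawn (a
rejection rate above 50% aborts with advice to lower the noise); at the
default noise scales ~2% of draws are rejected.

The default design mirrors the asymmetric sampling of the study system:
230 Cretaceous + 34 Eocene + 12 Miocene + 787 extant = 1063 specimens,
split across five archetypes — three present in all slices, one
confined to the Cretaceous, one only extant.  Noise scales (0.05–0.08)
were chosen once as plausible within-group variation for this grammar.
Within a group the noise is constant through time, so within-group
cross-slice disparity differences in the default design reflect sampling
alone; morphotype turnover lives in the restricted-occurrence groups.

What the generator does *not* emulate: anatomical detail (antennae,
labial palps, segment boundaries), digitisation noise correlated along
the outline, asymmetric or damaged specimens, and real between-slice
shape drift within lineages.  Passing tests therefore demonstrate the
pipeline's statistical behaviour, not fidelity of any archetype to a
real larva.

## Validation experiment sizes

The method-validation experiments run at desk scale, chosen as the
smallest sizes at which the properties are stable: noise-ratio recovery
(2× noise contrast, n = 30 per group, n_boot = 2,000, 100 replicates;
success = correctly ordered disparity with Bonferroni-adjusted
p < 0.001), rarefaction behaviour (equal noise, n = 30 vs 300, rarefied
to 30, three seeds), invariance (100 transforms), and full-design
determinism (two complete runs at n_boot = 10,000, byte-compared CSVs).
`scripts/acceptance.py` recomputes all of these plus the full-design
summary from a single root seed.

## Known limitations

- Welch tests on bootstrap replicates are anticonservative by design
  (see above); use the percentile-overlap check for calibrated
  judgements.
- Rarefaction corrects the dispersion of the disparity estimate, not
  the sampling noise of a tiny fossil subset's point estimate; with
  m = 4 (the default design's Miocene subsets) replicate distributions
  are wide and individual overlaps vary seed to seed.
- NEFD normalisation is ill-conditioned for near-circular shapes.
- Re-digitising an outline from a different starting point perturbs
  coefficients through polygon-chord discretisation (~1e-2 on spiky
  shapes at k = 200); the exact invariance holds for point-set
  transforms.
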