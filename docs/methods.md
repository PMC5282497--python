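# Methods

`spermtopo` re-implements, as a tested and fully synthetic-data-driven
pipeline, a 3D/2D analysis of how telomeres, centromeres and nucleolar
organizing regions (NORs) are arranged inside human sperm nuclei.  The raw
microscopy of such studies (deconvolved multi-channel DAPI+FISH z-stacks) is
rarely deposited, so the package pairs the measurement chain with a
generator that plants known spatial structure; every stage can then be
checked by parameter recovery instead of by eye.

## The measurement model

**Nucleus and landmarks.**  A sperm nucleus is modelled as an ellipsoid with
semi-axes `(a, b, c)`; the tail attaches at one pole of the long axis and
the head apex sits at the other, so the tail→head length is `L = 2a` and the
widest diameter measured at 90° to the tail axis is `D = 2·max(b, c)`.  On
real (or rendered synthetic) images the mask comes from Gaussian smoothing
of the DAPI channel followed by a threshold (Otsu by default, fixed value as
an override), keeping the largest connected component and filling holes; the
head point is the mask-surface point farthest from the supplied tail point,
and `D` is the maximum caliper extent of the surface projected onto the
plane orthogonal to the tail→head axis.  Tail identification is taken as
given (a manual step in the imaging protocols this emulates); automatic tail
detection is out of scope.

**Radial position.**  Each rendered FISH signal's centroid gets a distance
`d` to the nuclear border from the anisotropic Euclidean distance transform
(EDT) of the mask (`scipy.ndimage.distance_transform_edt` with physical
voxel sampling), interpolated trilinearly at the centroid.  `d` is
normalised by the radius `R = D/2` and binned into thirds: periphery
(`d < R/3`), intermediate (`R/3 ≤ d < 2R/3`), interior (`d ≥ 2R/3`).  Bins
are half-open with the top bin closed; the edge convention affects a
measure-zero set and is fixed for determinism.  `d > R` is clamped with a
warning, since it indicates an axis mis-measurement.

A numerical note on the EDT: for a flat interface the voxel-centre EDT
overestimates the distance to the continuum boundary by about half a voxel,
but for curved voxelised surfaces staircase "corner cutting" cancels most of
that overshoot.  Validated against the analytic distance on spheres and
spheroids at 0.1 µm voxels, the raw interpolated EDT is biased by only about
+0.02 µm, whereas subtracting the flat-interface half-voxel overshoots to
−0.03 µm and visibly distorts the sphere shell fractions.  The raw value is
therefore used by default (`surface_correction=False`), with the
flat-interface correction available for near-planar masks.

**Longitudinal position.**  Every detected signal — rendered or not — is
projected onto the tail→head axis; the projection `s ∈ [0, L]` is binned
into tail / mid / head thirds.  The same code path serves 2D images (the z
component is simply absent), matching study designs whose 2D arm is
longitudinal-only.

**Detection and the rendering gate.**  FISH channels are masked to the
nucleus, lightly smoothed (σ = 0.1 µm), and thresholded at the rendering
gate (default 50): connected components with ≥ 2 voxels become *rendered*
signals with intensity-weighted centroids.  No watershed splitting is
applied — neighbouring clusters that fuse above the threshold merge into one
signal, deliberately mirroring conservative iso-surface rendering.  Local
maxima above a lower *presence* gate (default 18) that fall outside every
rendered component are counted as detected-but-not-rendered; they enter
longitudinal counts but are excluded from the radial analysis, which needs a
reconstructed object.  Peaks are strict local maxima deduplicated greedily
within 0.3 µm (keeping the brightest); a wider suppression box would let the
monotone flank of a bright object veto a genuine dim peak well outside its
component, which is exactly the situation the presence gate exists for.

**Clusters and colocalization.**  Telomere/centromere cluster counts use
single-linkage agglomeration of signal centroids at a merge radius (default
0.3 µm, about the lateral resolution limit; 0 yields one cluster per
signal).  Probe signals (NOR, centromeres 1/5/19) are associated with their
nearest chromocenter within a proximity radius (default 0.5 µm); signals
beyond it stay unassociated.  The chance expectation for "how many distinct
chromocenters do n probe signals hit" is computed exactly under independent
uniform assignment: `P(j) = S(n, j) · k!/(k−j)! / k^n` with Stirling numbers
of the second kind, cross-checked against full enumeration in rational
arithmetic.

**Statistics.**  Region counts are tested with Pearson's chi-squared
goodness of fit (df = k−1) against two nulls, reported side by side: *equal
thirds* (the reading of "random" consistent with the kind of p-values such
studies print) and a *volume-weighted Monte-Carlo null* (fractions of
uniform random points inside the actual mask — the outer third of the radius
holds roughly two thirds of the volume, so the two nulls differ
substantially).  Between-subject reproducibility is a chi-squared test of
homogeneity on the subject × region table without continuity correction;
3D-vs-2D method agreement is a two-tailed paired t-test on per-subject
fractions or per-cell mean counts (both modes exist because the published
description does not fix one).  Per-subject tests pool that subject's cells;
no hierarchical model is fitted, and no multiple-testing correction is
applied by default (a Bonferroni helper is a flag away in the caller's
hands).  Degenerate paired cases are explicit: identical vectors give p = 1;
zero variance with non-zero mean is flagged rather than silently dividing by
zero.

## The synthetic generator

`SyntheticSpec` holds the study conditions; the defaults are fixed once:

| parameter | default | why |
|---|---|---|
| subjects × cells | 10 × 30 | the cohort size the analysis is built for |
| treated semi-axes | (4.08, 3.00, 3.00) µm | analytic volume 153.8 µm³ ≈ the 153.9 µm³ mean of DTT-swollen nuclei; only volumes, not axes, are reported, so a prolate 1.36:1 spheroid was chosen |
| untreated semi-axes | (3.03, 2.23, 2.23) µm | volume 63.1 µm³ ≈ 62.83 µm³; preserves the 2.4-fold swelling |
| voxel size | 0.1 µm isotropic | resolves the 0.3 µm merge scale; anisotropic (e.g. 0.2 µm z-step) supported and tested |
| radial fractions | (0.42, 0.45, 0.13) | back-derived from the reported "if all non-rendered telomeres were peripheral: 57/33/10" arithmetic at 26.4% exclusion |
| longitudinal fractions | (0.2481, 0.5042, 0.2477) | the printed 3D telomere tail/mid/head percentages |
| telomere units | 92 | 46 chromosomes × 2 telomeric ends |
| cluster sizes | all tetramers | see below |
| chromocenters | 7 (from 46 centromere units) | the reported ~7 chromocenters per cell |
| NOR / cen-1/5/19 signals | 3 / 3 | the reported ~3.2 / ~2.6 discrete signals |
| cluster jitter | 0.15 µm | sub-resolution scatter of cluster members |
| PSF σ | 0.1 µm | lateral Gaussian width of a 1.4 NA, 60× system; deconvolved stacks are at least this tight |
| spot amplitude | 200 / unit | bright units clear the rendering gate after smoothing (single-unit smoothed peak ≈ 71 > 50) |
| dim cluster amplitude | 70–130 total per cluster | smoothed peak lands strictly between presence (18) and rendering (50) gates |
| tail background | 10, decay 1.5 µm | the tail-proximal haze that degrades nearby signals |
| noise σ | 5 | read noise; ≈ 0.75 after detection smoothing |
| non-render target | 0.264 | the reported 26.4% telomere exclusion rate |

**Planting positions.**  Cluster seeds draw a (radial, longitudinal) region
pair from the configured marginals and are rejection-sampled uniformly
inside the ellipsoid until both bins match; joint dependence between the two
axes is not modelled.  Cluster members scatter within the jitter radius and
are additionally conditioned on the seed's region pair — unconstrained
scatter leaks probability mass across bin boundaries (about +2 points into
the periphery at these settings) and would break the generator's contract
that planted fractions are exact at the spot level.  Every spot stores the
region labels recomputed from its own final position via the same assignment
functions the analysis uses, so ground truth and analysis cannot drift
apart.  Geometrically impossible joint targets (e.g. interior ∩ head in a
sphere) raise an error reporting the achieved fractions.  The exact
point-to-ellipsoid-surface distance behind the truth labels solves the
Lagrange foot-point equation by vectorised Newton iteration with a
closed-form fallback on symmetry axes, and is tested against a brute-force
surface-sampling oracle.

**Why renderability is a cluster property.**  Members of one cluster sit
within ~0.2 µm of each other and fuse into a single blob at imaging
resolution, so a per-unit dim flag could never make detection fail (one
bright member would render the lot).  Whole clusters are therefore flagged
non-renderable with probability equal to the target rate and rendered as a
single dim total amplitude shared among members.  The detector — not the
flag — decides their fate: with the default gates 90–95% of dim clusters are
recovered as presence-only signals, and the recovered non-rendered fraction
sits within ~1 point of the planted rate.

**Why all tetramers.**  Telomere clusters in sperm are described as dimers
or tetramers, with ~20 clusters observed per cell.  Those two statements are
arithmetically incompatible with 92 telomeres: dimers/tetramers bound the
mean cluster size at 4, hence at least 23 clusters.  The default takes the
attainable extreme (92/4 = 23 tetramers), which after rendering losses and
occasional merging yields ~20–22 observed signals per cell, of which ~15
render — closely tracking the published 20.77 observed / ~15 rendered.  The
dimer:tetramer mix remains a config knob for users who prefer the 50:50
flavour (expected 30.7 clusters).

**Chance-level probe anchoring.**  NOR and cen-1/5/19 signals pick an
anchor chromocenter uniformly at random (then jitter within 0.2 µm).  This
deliberately reproduces the *null* of the colocalization analysis, so the
simulated distinct-chromocenter distribution matches the exact PMF; it does
not emulate the preferential (non-random) sharing a real cohort shows.

**Determinism.**  Each cell's randomness derives from
`SeedSequence(spec.seed, spawn_key=(subject, cell))` with separate
substreams for placement and rendering per channel, so ground-truth tables
are byte-identical across runs and independent of whether images are
rendered.

## What the synthetic data does and does not show

The generator emulates ellipsoidal nuclei, cluster structure, planted
marginal region fractions, a tail-background/dim-cluster non-render
mechanism, PSF blur and Gaussian read noise.  It does **not** emulate
nuclear shape irregularity or hooked heads, joint radial×longitudinal
dependence, spectral bleed-through, deconvolution artefacts, per-cell
variance in spot counts (92 units per cell, exactly), or biologically
preferential chromocenter composition.  Passing recovery tests therefore
demonstrates that the measurement chain is unbiased under the stated
imaging model at realistic geometry and SNR — not that it is robust to every
property of real microscopy.

Known quantitative limits, measured on the default cohort: cluster merging
at the rendering threshold removes ~5–8% of signals preferentially from the
denser intermediate/interior regions, biasing recovered radial fractions by
up to ~+2 points toward the periphery; the maximum-projection 2D arm merges
many more signals (≈ 8 per cell versus ≈ 21 in 3D), which reproduces — in
exaggerated form — the reported 3D/2D count discrepancy while leaving the
longitudinal *fractions* in agreement between arms.

## Pipeline sizes and runtimes

The default cohort analysis streams 300 cells (~0.45 M voxels per channel)
in bounded memory.  The Monte-Carlo volume null uses 50 000 points (SE
≤ 0.3 points per region); the sphere closed-form check uses 10⁵ points
against (19/27, 7/27, 1/27).  The acceptance script simulates 30 cells for
the non-render recovery target and 100 multinomial cohorts of n = 964 for
the chi-squared bound, sizes at which every quantity's Monte-Carlo error is
well inside the tolerance it is compared at.
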