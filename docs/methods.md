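# Methods

`malustar` simulates young apple trees (*Malus × domestica*) as
functional–structural plant models, measures their diffuse-light
interception efficiency as the sky-integrated silhouette-to-total-area
ratio (STAR), and screens the influence of architectural traits on STAR
with a generalized additive metamodel. This note documents the models,
the parameters that matter, the numerical choices, and what the
synthetic defaults do and do not represent.

## Tree topology

A tree is a set of growth units (GUs) — the shoot portion produced in
one annual flush — connected by bearing relations. Four GU states
exist: long, medium, short and floral. Each year:

1. **Short-shoot mortality.** Every live short GU dies with a constant
   probability (default 0.1 yr⁻¹). Dead GUs produce nothing and carry
   no leaves; mortality affects short shoots only.
2. **Proleptic outgrowth.** Axillary buds stored the previous year
   break, each producing a GU of the type encoded in its lateral fate
   (short / medium / long / floral).
3. **Terminal succession.** Every live terminal bud produces a
   successor GU whose state is drawn from a first-order Markov chain
   over the four states (row-stochastic 4×4 matrix).
4. **Axillary branching.** Every new long or medium GU receives lateral
   fates from a hidden semi-Markov chain (HSMC) whose parameters depend
   on the parent length class: branching zones succeed each other base
   to tip, each zone has an occupancy (length) distribution and a
   categorical observation distribution over the eight lateral fates
   (latent; sylleptic short/medium/long; proleptic
   short/medium/long/floral). Sylleptic laterals grow out immediately;
   proleptic laterals are stored for the next budbreak. Sylleptic and
   proleptic fates are mutually exclusive at a node.

Occupancy distributions may be `fixed`, `uniform_int`, shifted negative
binomial or shifted Poisson — any discrete law with positive support —
plus a `rest` kind: at most one zone per class absorbs the nodes left
after the other zones have drawn their lengths. This keeps a short
distal zone (the acrotonic tip, where long proleptics cluster just
below the apical bud) at the apex of every shoot regardless of the
shoot's node count; making the *final* zone absorb the remainder
instead turns the fate-rich tip into a long segment whenever the median
zone samples short, and lateral production explodes.

Metamer counts per new GU are drawn uniformly from disjoint per-type
ranges (long 40–80, medium 15–39, short 3–14, floral 8). Buds are
processed base-to-top, trunk before laterals, against a single RNG
stream, so equal seeds give bitwise-identical topologies.

First-year trees are initialized from a trunk branching sequence (one
lateral fate per node, base to top, plus the observed trunk length).
Geometry-experiment trees must carry no sylleptic shoots in year 1:
their trunk fates are drawn from the long-parent HSMC with sylleptic
fates mapped to latent, so the trunk is unbranched in year 1 but its
proleptic buds break at the second budbreak. (A literally all-latent
trunk leaves the year-2 canopy sparser than the leafy year-1 trunk and
mean STAR *rises* from year 1 to 2, contradicting the dilution pattern
the experiment is about.)

## Organ geometry

* **Leaf area.** LA(d, rk) = f(d)·LA_max·[rk/n_p if rk < n_p else 1],
  where f is a symmetric logistic over the 12-day leaf development
  period, affinely rescaled and clamped so f(0)=0 and f(12)=1 exactly.
  The rank scaling models the smaller final size of pre-formed leaves
  (default n_p = 8); the discontinuity at rk = n_p is intended.
* **Internode length.** IL(d) = IL_min + g(d)·IL_max·c_z with g the
  analogous 10-day logistic and c_z ∈ [0,1] indexed on the branching
  zone (default 1.0 in extension zones, 0.3 in basal/latent zones). An
  additional per-shoot-type elongation factor (long 1.0, medium 0.5,
  short 0.08, floral 0.05) makes short and floral GUs the near-rosette
  spurs they are in real crowns; without it spur leaves string out along
  tens of centimetres and canopies never densify.
* **Calendar.** Budbreak is day 0; metamers of a GU appear one
  phyllochron apart (2 d on long/medium, 1 d on short/floral shoots).
  All whole-tree evaluations happen on day 90 of each season, the
  simulated 30 June, when short and medium shoots have stopped
  extending. Leaves live on the current season's shoots only; older GUs
  are wood.
* **Pipe model.** Cross-sectional area is conserved at every junction:
  the distal-most internode of every axis has diameter TSD (the
  top-shoot-diameter trait) and every internode's area is the sum of
  its distal continuations' areas (relative error < 1e-9 by
  construction; an optional per-leaf petiole area term defaults to 0).
* **Bending.** One small-deflection Euler–Bernoulli pass per axis, base
  to tip: the curvature increment of internode *i* is
  (1 − c)·M_grav,i / (E·I_i), with M_grav,i the gravity moment of the
  distal mass about the internode (levers from the unbent pose), I =
  πd⁴/64, E the wood elasticity (default 3 GPa) and c a scalar
  phototropic righting fraction (default 0.5; c = 1 balances gravity
  exactly and leaves axes straight). Lateral axes insert at the
  branching-angle trait from their bearer with a 144° phyllotactic
  azimuth. Numerical guards: curvature steps are clamped at 0.2 rad per
  internode, bending stops once an axis points 45° below the horizontal
  (a weeping limit), and a zero-diameter internode with distal mass
  warns and takes the clamp. Without the weeping limit, thin-shoot
  trees curl into balls and the TSD trait acquires a large artificial
  effect on STAR. The cantilever check (tip deflection mgL³/3EI within
  5 % in the stiff regime) pins the discretization.
* **Leaves.** Each leaf is a planar 8-vertex polygon inscribed in a 2:1
  ellipse and rescaled so the polygon area equals the leaf area
  exactly; the blade leans away from the axis by a constant 45° petiole
  angle at the node's phyllotactic azimuth.

## Light interception

STAR = PLA / TLA: projected (silhouette) leaf area over total leaf
area, overlaps counted once, in [0, 1].

* **Sky dome.** The hemisphere is partitioned into 46 sectors of
  exactly equal solid angle (ring construction; ring counts chosen for
  near-square cells; a single-sector ring is a zenith cap). The
  classical 46-direction turtle table can be emulated by loading custom
  directions; the testable contract is the partition itself (count,
  equal areas, Σω = 2π).
* **SOC weights.** w_i ∝ L(e_i)·sin(e_i)·ω_i with the standard
  overcast-sky gradation L(e) = (1 + 2 sin e)/3, normalized to sum to
  1. Whether the original integration included the sin(e) flux term is
  not documented; a flag (`flux_term=False`) switches to pure
  radiance×solid-angle weighting. The default includes it.
* **Projection.** Orthographic rasterization of all leaf polygons onto
  the plane perpendicular to each direction (scanline fill of an
  occupancy grid, numba-compiled). Default resolution 2 mm per pixel,
  auto-tightened to a tenth of the typical (median-area) leaf width and
  coarsened so the grid never exceeds 1536² cells. Cross-checks: an
  independent Monte-Carlo ray-sampling estimator (point-in-polygon via
  shapely) agrees within 1 % on random canopies, and exact polygon
  unions are available for small fixtures.

## Virtual experiments

* **Geometry experiment.** A Latin hypercube sample (default n = 300,
  one stratum per row per trait, uniform marginals) over leaf area
  LA_max ∈ [3·10⁻⁴, 9·10⁻³] m², internode length IL_max ∈ [8·10⁻³,
  5·10⁻²] m (IL_min fixed at 8·10⁻³ m), top shoot diameter ∈ [10⁻³,
  8.5·10⁻³] m and branching angle ∈ [0, 130]°. The printed upper bound
  of the branching-angle range in the source table (1.3×10⁻², with
  degree units) is inconsistent with the described response domain
  (effects discussed up to and beyond 65°) and is treated as a typo;
  the default range is [0°, 130°] and documented here rather than
  silently corrected elsewhere. Each row runs a 5-year simulation;
  TLA and sky-integrated STAR are recorded each 30 June.
* **Topology experiment.** One tree per first-year trunk branching
  sequence, default geometry traits, default Markov/HSMC models in
  later years. Branching densities (laterals per metre of trunk,
  total sylleptic/proleptic and the six-way length-class split) are
  echoed per tree as metamodel inputs.
* **Seeding.** A master seed spawns per-tree seeds by fixed arithmetic
  on the tree id, so any subset of a design reruns identically.

## Sensitivity metamodel

STAR_i = f₀ + Σ_k f_k(X_k,i) + ε_i, no interactions. Each f_k is a
cubic penalized regression spline (basis dimension 10) under a
sum-to-zero constraint over the data, with the exact ∫f″² curvature
penalty, whose null space is exactly the linear functions. (A
second-difference coefficient penalty was probed and rejected: with
clamped knots its null space is not linear-in-x near the boundaries,
leaving 10⁻³-scale residuals on exactly linear data.) Per-term
smoothing parameters minimize GCV by coordinate descent on a log grid.

* **e.d.f.** is the trace of the term's block of the influence matrix:
  1 for a straight line, 2 for a parabola, up to 9 for an unpenalized
  term (basis dimension minus the centering constraint).
* **Interpolation regime.** When the model residual is numerically zero
  (RSS below 10⁻¹⁰·TSS, with an absolute floor for constant responses),
  prediction-error criteria cannot identify the smoothing parameter —
  every candidate interpolates. The fit then collapses each term to its
  minimal-degree polynomial that still reproduces the response to
  machine precision. This recovers the classical e.d.f. semantics
  exactly (line → 1, parabola → 2, constant → dropped, e.d.f. 0) where
  mechanical GCV would report an arbitrary, typically maximal, e.d.f.
* **Inference.** The per-term F statistic and p-value come from the
  classical nested F test of the term's unpenalized basis against the
  null on the term's partial residual. For a single term this test is
  exactly F-distributed under the Gaussian null (its p-values pass a
  Kolmogorov–Smirnov uniformity check over 500 null replicates, which
  penalized-smooth approximations conditioned on data-selected
  smoothing do not); for additive designs it is near-exact. Larger F ⇔
  stronger effect. No multiple-testing correction is applied across
  terms; significance stars use the conventional 0.05/0.01/0.001
  thresholds.
* **Reporting.** Adjusted R² = 1 − (RSS/(n−edf_total))/(TSS/(n−1)).
  Response curves are the centered term effects on an even grid over
  the observed range with a ±2·SE band (Bayesian coefficient
  covariance); a zero crossing marks where the expected response equals
  the mean response. Centering is enforced over the data (the field
  convention); term integrals over the observed range are then ≈ 0 for
  uniform/LHS designs but not identically.

## Synthetic defaults: what they emulate and what they do not

The Markovian parameters estimated for the 'Fuji' cultivar and the 108
observed hybrid trunk sequences behind the original study are
unpublished, so the package ships toy stand-ins:

* `default_markov_params()` encodes the known *qualitative*
  organization — vigour drift toward short/floral GUs in the succession
  chain; a latent basal zone, a mixed median (`rest`) zone and a small
  acrotonic distal zone on long parents; a mostly latent two-zone model
  on medium parents. Emission rates were set so that vigorous-GU
  multiplication is ≈ 2 per year and a 5-year geometry-experiment tree
  reaches a TLA of order 5–10 m² with a few hundred GUs, the scale
  reported for real 5-year-old trees. They are package defaults, not
  estimates.
* `generate_trunk_sequences()` draws per-sequence sylleptic/proleptic
  propensities so the 108-sequence batch spans ≈ 0–25 sylleptic and
  0–40 proleptic laterals per metre — the density ranges over which the
  original response functions are interpretable — with a common
  latent-base / mixed-middle / acrotonic-tip zonation. No genotype
  structure is represented.

Consequences for interpretation: passing tests demonstrate the
*mechanisms* (overlap dilution of STAR with age; the dominance of
internode length and leaf area, with opposite signs, over branching
angle and top shoot diameter; the acrotonic placement of long
proleptics) at a reduced scale. Absolute levels — mean STAR per year,
TLA trajectories, F magnitudes, adjusted R² — are properties of the toy
parameterization and are not comparable to the published values, which
depended on the unpublished parameterization and observed sequences.

## Problem sizes and stochastic-property tests

Qualitative pattern checks run the geometry experiment at 50 trees × 4
years × 5 master seeds — sizes chosen to give the additive fits ≥ 10
observations per term while keeping a full check affordable on a
laptop. The year-to-year Markov demography adds small per-tree STAR
jitter at this scale: measured positive year-over-year increments never
exceed ≈ 0.025, while genuine declines are an order of magnitude
larger. Stochastic properties are therefore asserted as: pooled
per-year mean STAR strictly decreases; ≥ 90 % of trees show no STAR
increase above the 0.025 jitter allowance; internode length and leaf
area carry the two largest F in ≥ 90 % of per-year fits with leaf area
negative and internode length positive; top-shoot-diameter p-values
have median > 0.05 and TSD is never among the top two.

## Known limitations

* Fruit growth, flowering phenology, correlative inhibition and
  light-dependent mortality are not modelled (constant short-shoot
  mortality only), so highly branched trees can reach unrealistically
  large leaf areas.
* Bending is a single elastic pass per year: no iterative equilibrium,
  no torsion, no within-year re-bending from secondary growth, no
  petiole flexion.
* Only explicit leaf-level projection is implemented; multi-scale
  statistical (porous-envelope) foliage representations are out of
  scope, as are clear-sky (direct sun) integration and orchard-level
  scenes — the STAR here describes a single standing tree.
* The HSMC parameter table is indexed by parent length class
  (long/medium) only; how parameters vary with parent length in finer
  detail is a structural guess.
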