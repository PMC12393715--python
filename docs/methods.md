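# Methods

## Model

Three kinds of circular particles live in a square field of side `L`
(600 um by default) with periodic boundaries: muscle units (radius 6 um,
passive), hemocytes (radius 4 um, self-propelled), and fat body cells
(maximum radii 18–28 um, equally spaced across the population, mean 23 um;
self-propelled once risen). Motion is overdamped — velocity equals net
force over a friction coefficient — and integrated with an explicit Euler
scheme at `dt = 0.5 s`. Simulated time is reported in hours after puparium
formation (hAPF) with origin 12 hAPF and 7,200 steps per hour.

Contacting disks (center distance strictly below the radius sum) interact
with a linear spring on the overlap length plus a constant pairwise
adhesion. The adhesion matrix encodes the biology: phagocytosis is a
strong adhesion `a_E = 10 nN` between a hemocyte and an uneaten muscle
unit; on first overlap the unit becomes *eaten*, its host being the
nearest-center overlapping hemocyte. An eaten unit keeps `a_E` with its
own host only and otherwise counts as a hemocyte for the intercellular
strengths (`a_HH` between hemocyte-likes, `a_HF` hemocyte-like/fat,
`a_FF` fat/fat). Since adhesion only acts in contact, a host–cargo pair
separated beyond contact by crowding exerts no restoring force; the bond
is then considered broken, the unit reverts to uneaten, and any hemocyte
may re-engulf it. A host accepts any number of units, but geometry caps
the stable load: a fragment touching the host subtends `2 asin(6/10)`,
so at most `floor(pi/asin(0.6)) = 4` fit — the maximum the simulations
actually produce.

Default mechanical constants: `mu = 0.03 N s/m`, `k = 1e-3 N/m`,
`a_HF = 2 nN`, `a_HH = a_FF = 0`, hemocyte propulsion `v_H = 5 nN`
(free speed `v/mu` = 10 um/min), fat propulsion `v_F = 2.5 nN`, turning
probability `p = 0.005` per step (persistence time ~100 s). `mu` and
`v_H` together set the observed 6-min-window hemocyte speed in the
full-density baseline to 1–3 um/min; with `k` as above, propelled cells
tolerate overlaps of a few um, reflecting cell deformability.

### Initial conditions and fat-body floating

900 uneaten muscle units start uniformly distributed over two vertical
belts of width 100 um centered at `L/4` and `3L/4` (450 each; the
inter-belt and wrap-around gaps are both 200 um at full scale);
800 hemocytes start uniform over the belt complement. Fat body cells
either exist from the start (90 cells at full radius, outside the belts)
or "float" (70 cells anywhere, radius zero). Floating cells are inert
while their radius is zero; from 14 hAPF each starts growing at the first
minute boundary at which no uneaten muscle disk overlaps its full-size
disk, then gains 0.383 um per minute up to its maximum (a 23-um cell
completes in 61 min) and propels itself once its radius is positive.

### Hemocyte heterogeneity

Three motility scenarios keep the population means fixed: homogeneous
(all `v = 5 nN`, `p = 0.005`); speed-heterogeneous (random halves at 1
and 9 nN); turn-heterogeneous (random halves at `p = 0.009` and 0.001).

### Stabilization operations and calibration

Five operations slow the muscle units by ramping one parameter linearly
over steps 129,600–273,600 (30–50 hAPF), updated at one-minute
boundaries: spatial confinement (repulsive slabs of thickness `w(t)`
growing on the top and bottom edges, with the y-periodicity removed while
walls are active; wall force `-k (r_i + w - y_i)` toward the interior),
hemocyte propulsion multiplier, global friction, `a_HF`, and `a_HH`.
Reference endpoints: 90 um per wall, x0.80, 0.039 N s/m, 4 nN, 2.2 nN.

Each operation's magnitude is set by regression: sweep several
magnitudes, measure per trial the *calibration percentage* y — the pooled
median muscle-unit speed at 50 hAPF as a percentage of that at 30 hAPF
(6-min displacement windows) — fit ordinary least squares y ~ magnitude,
and select the magnitude with predicted y = 80, i.e. a one-fifth
slowdown. This ratio definition is the one consistent with the reference
endpoints: at the defaults the model responds near-linearly, the x0.80
propulsion endpoint yields y ≈ 81, the 90-um wall at full scale y ≈ 83,
and the friction endpoint bounds the propelled-speed change at x0.77 —
whereas no operation can reach an 80-point *decrease* at any magnitude
(confinement saturates near a 45–49% decrease at its geometric limit).
The ramp window follows the 30–50 hAPF reading (129,600–273,600); holding
the ramp endpoint from 42 hAPF instead shifts the response by only a few
points.

## Measurements

All metrics treat simulated trajectories and external coordinate tables
identically; lengths in um, times in minutes.

* **Speed** — minimum-image displacement over a 6-min window divided by
  six, evaluated at 1-min cadence (the window is fixed; the cadence is the
  sampling default). Summaries pool units, times, and trials and report
  medians.
* **Horizontal variance** — sample variance (n−1) of x within the left and
  right field halves, averaged; raw coordinates, no unwrapping.
* **Nearby counts** — for each muscle unit, the number of others within
  30 um (inclusive), plain Euclidean distance without periodic wrap.
* **Ring radii** — degree-1 persistent homology of the growing-disk
  filtration of the unit centers; classes with lifetime > 10 um are rings
  and their death radii the ring radii. Implemented as alpha-complex
  persistence on the Delaunay triangulation with all filtration values as
  radii (triangle = circumradius; edge = half-length if its diametral disk
  is empty, else the smallest incident circumradius). H1 pairs come from a
  dual-graph Kruskal sweep: triangles (weighted by circumradius, plus an
  unbounded face at infinity) merge across edges in decreasing filtration
  order; each merge pairs the edge value (birth) with the absorbed
  component's largest triangle value (death), the elder rule keeping the
  component with the larger maximum. For planar points this equals full
  Čech persistence, which the test suite verifies against an independent
  boundary-matrix-reduction oracle on point sets of up to 8 points.
  Collinear inputs have no loops and return an empty list; zero-lifetime
  pairs from degenerate (cocircular) inputs are dropped.
* **Steering consistency** — mean cosine of the angle between consecutive
  frame-to-frame velocities of one track, in [−1, 1]; terms adjoining a
  zero displacement are skipped with the divisor reduced, and a fully
  static track is undefined (NaN).
* **Frame-difference index** — per consecutive frame pair, the spatial
  mean of the absolute pixel difference (dF) normalized by the mean
  intensity of the earlier frame (F0); no thresholding, masking, or
  background subtraction. The index rises monotonically with per-interval
  displacement and saturates once displacement exceeds the object size,
  so it underestimates fast motion.
* **Rank tests** — Brunner-Munzel (midranks, t approximation with
  Satterthwaite degrees of freedom; the relative effect
  `P(X<Y) + P(X=Y)/2` is reported alongside; degenerate variance raises
  with a pointer to the label-permutation fallback) and Siegel-Tukey
  (alternating extreme ranks starting with rank 1 at the minimum, midranks
  for ties, Wilcoxon rank-sum normal approximation with tie correction, no
  continuity correction). Medians are not aligned before Siegel-Tukey, so
  it conflates location and scale when medians differ. Both tests are
  two-sided.

## Synthetic data

Every fixture is generated by the package itself: initial worlds and
trajectories by the scenario builder, point clouds with known geometry
(polygons, lattices) in the tests, and image stacks by the renderer
(selected particles as filled disks at their radii, Gaussian blur,
optional additive noise, quantization). The renderer emulates the
geometry of a single-channel maximum projection, not microscopy physics:
no photon noise model, no bleaching, no depth attenuation, no anisotropic
PSF. Tests passing on these fixtures therefore validate the measurement
pipeline and the model's collective behavior, not instrument-specific
image properties.

## Numerical choices

* Synchronous update: all forces from pre-update positions, one Euler
  step, then phagocytosis and bond-break transitions on the new positions
  — order-independent within a step.
* Contact is strict overlap; adhesion acts only in contact, so the force
  is discontinuous at the contact edge (no smoothing, by construction).
* Coincident centers (measure-zero): the pair direction is +x for the
  lower index and its negation for the other; a host–cargo pair, which is
  legitimately near-concentric, is left at rest at exact coincidence.
* Neighbor search: uniform cell grid (CSR counting sort per step) with
  cell size at least the largest small-particle interaction diameter;
  half-neighborhood sweep visits each pair once with per-cell periodic
  image shifts. The few fat cells scan the grid cells covering their
  interaction disk. The compiled step is tested for exact agreement with
  a brute-force all-pairs reference.
* Host ties break to the nearest center, then the lowest index.
* Fat cells with zero radius do not interact (they are "in the depth");
  with the literal contact force a zero-radius point could be pushed
  around by overlapping neighbors.
* A run aborts with a diagnostic naming the particle and step if any
  position becomes non-finite.
* One seedable generator drives a trial; trial t of a condition uses seed
  `base + t`, so runs are bit-reproducible.

## Problem sizes

The simulation batteries in the test suite and the acceptance script run
on a density-preserving reduced field (side x0.5, counts x0.25, belt
width and radii fixed), which preserves global area fractions and
per-particle statistics of the dispersed state; the belt phase is locally
sparser because the belts keep their width, which is why the
engulfment-capacity check uses the full 600-um field. The calibration
sweeps 45/90/135 um wall thickness (half to one-and-a-half times the
reference endpoint) with one trial per magnitude and six trials at the
calibrated magnitude; comparison operations run one trial each at their
reference endpoints. Baseline speed checks use three trials to 24 hAPF.

## Limitations

Two-dimensional, circular, non-deforming cells; no chemotaxis, signaling,
proliferation, or death; muscle fragmentation is abstracted as pre-made
units; hemocyte headings are memoryless between turning events. The
confinement response depends on the field geometry, so calibrated wall
thicknesses are scale-specific (about 48 um at the half-scale field
versus 90 um at full scale). Rank-test p-values pooled across trials
treat per-unit observations as independent, ignoring within-trial
correlation, as in the source workflow.
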