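# Methods

## Problem and model

Voxel-based Monte Carlo light transport discretises tissue into a regular
grid of cubic voxels, each holding a label that maps to optical properties
(refractive index n, absorption mu_a in 1/cm, scattering mu_s in 1/cm,
Henyey-Greenstein anisotropy g).  The photon loop is the canonical
hop/drop/spin scheme with statistical weights:

* **hop** — a dimensionless step s = -ln(xi) is consumed across voxels as
  partial optical paths mu_t * l (mu_t = mu_a + mu_s), which samples free
  paths without bias in heterogeneous media.  Voxels with mu_t = 0 (the
  clear media of the validation scenes) are traversed ballistically without
  consuming step.
* **drop** — at each interaction a fraction mu_a / mu_t of the photon weight
  is deposited into the local voxel.
* **spin** — the direction is redrawn from the Henyey-Greenstein phase
  function (mean cosine g; uniform when g = 0) with uniform azimuth.
* **roulette** — photons below a weight threshold (default 1e-4) survive
  with probability 1/m at m times their weight (default m = 10), which
  terminates histories without bias.

The fluence rate per voxel is phi = deposited_weight / (mu_a dx^3 N) in
W/cm^2 per W delivered; voxels of zero-absorption media keep zero.

## Boundary handling at refractive mismatches

At every voxel-face crossing the refractive indices of the two voxels are
compared.  On a mismatch, unpolarized Fresnel reflectance
R = (Rs + Rp)/2 (R = 1 at or beyond the critical angle) decides — by a
single random draw, never by weight splitting — between specular reflection
and vector-Snell refraction.  The accuracy of both the probabilities and the
outgoing angles hinges on the boundary normal used.  Four modes:

* `matched` — no Fresnel handling at all (reference limit).
* `facet` — the axis-aligned outward normal of the crossed voxel face.  For
  a flat edge of orientation theta the best axis approximation errs by
  min(theta, 90 - theta), i.e. up to 45 degrees, and the error in *reflected*
  directions is up to twice that.
* `surface` — the precomputed smoothed surface normal stored for the
  photon's pre-crossing voxel (see below).
* `interp` — a masked trilinear interpolation of the stored normals at the
  crossing point, restricted to the eight bracketing voxel centroids whose
  medium shares the refractive index of the pre-crossing voxel.  Masked
  vertices are zeroed, not re-weighted; the final unit normalization absorbs
  the lost magnitude.  Fractions use round-half-away-from-zero so a query at
  a voxel centroid returns exactly that voxel's vector (banker's rounding
  would break this identity at x.5 coordinates).

Fallback chain for degenerate (zero) normals: interpolated -> stored ->
facet.  Crossing points stay on the voxel faces; no attempt is made to move
them onto a reconstructed virtual surface, which is the known source of the
small residual beam discontinuities in the sphere scene.

After a reflection the photon is nudged 1e-7 voxel units along its new
direction.  With an oblique surface normal the reflected direction can still
point across the face at grazing incidence; the photon then simply continues
in the neighbor voxel.  This rare borderline case is accepted rather than
special-cased.

Grid exit is an escape (recorded with face, position, direction, weight and
the photon's reflection/transmission counts); no Fresnel event is imposed at
the outer grid faces.

## Surface-normal map construction

From the label volume alone:

1. list the unique refractive indices present;
2. build a {0,1} occupancy map per index;
3. apply the separable 3x3x3 Sobel-Feldman operator ([-1,0,1] derivative,
   [1,2,1] (x) [1,2,1] smoothing, replicate padding) to each map.  The sign
   convention makes gradients point from the boundary into each region's
   interior;
4. smooth each gradient component with a penalized least-squares smoother:
   minimise ||y - z||^2 + s ||Lap z||^2 on the grid, solved exactly in the
   DCT-II domain with spectral gain 1/(1 + s lambda^2).  The smoother
   reproduces constants, is scale-invariant, s = 0 is the identity, and the
   DCT-II basis implies reflective boundary handling at the grid faces.
   Default smoothing factor s = 2.  Smoothing across several voxels is what
   suppresses the rasterisation staircase; too large an s deforms the
   estimated surface;
5. mask each smoothed field by its own occupancy map and sum, so fields
   from opposite sides of a boundary never mix or cancel;
6. normalize each voxel's aggregate to unit length.

Vectors are kept only inside a dilated shell (default 3 voxels) around the
mismatched boundaries: smoothing leaks tiny magnitudes deep into region
interiors which would otherwise normalize into spurious unit vectors far
from any boundary, where transport (boundary voxels) and interpolation
(their immediate neighbors) never look anyway.  Aggregates with magnitude
below 1e-9 are stored as exact zeros and fall back to the facet normal.

Measured accuracy on the sphere scene (radius 1 cm, dx = 0.01 cm, s = 2),
against the analytic radial normals over the interior boundary shell:
mean error 1.46 deg, 95th percentile 3.7 deg, 99th percentile 6.1 deg,
maximum 8.9 deg.  The tail sits at the sphere's poles, where the surface is
nearly grid-aligned and staircase terraces are many voxels wide — wider than
the s = 2 smoothing reach.  A side-incident beam (the validation geometry)
lands on mid-latitudes where errors are far below 5 deg.

## Random numbers and reproducibility

Each photon owns an xorshift64* stream seeded by a splitmix64 hash of
(run seed, photon index): runs are bitwise reproducible, and a photon's
trajectory does not depend on how many photons ran before it.  A pure-Python
mirror of the stream and of the whole stepper exists solely to cross-check
the compiled kernel; the test suite verifies per-photon agreement.

## Analytic oracle

Exact ray-sphere intersection with deterministic Snell refraction (and
reflection under total internal reflection) provides ground truth for the
two clear-media scenes.  The biconvex lens is the intersection of two balls;
the tracer resolves the medium on either side of each surface by evaluating
a piecewise index field just off the crossing point, which keeps the
overlapping-sphere solid unambiguous.  The oracle follows the transmitted
branch (recording the Fresnel R of every hit); the specular reflection of
the first hit is computed separately to grade Monte Carlo photons that
bounced off the sphere.  It is geometry ground truth, not a radiometric
reference — scattering cases are validated by conservation and invariance
properties instead.

## Validation scenes and the choices behind them

The sources of the validation targets state the sphere radius, indices and
voxel size but not the beam geometry, and give no lens dimensions; the
following are this package's documented defaults, fixed once:

* **Sphere scene** — radius 1 cm sphere (n 1.33) in air (n 1.00),
  dx = 0.01 cm on a 220^3 grid; collimated beam of radius 0.15 cm along +z
  whose axis passes 0.7 cm from the sphere centre, striking the side at
  incidence angles of about 33-58 deg.  All media have mu_a = mu_s = 0 so
  trajectories are purely refractive and every escape is deterministic given
  the launch ray.  Escaped photons with exactly one Fresnel reflection and
  no transmission form the reflected beam; each is compared with the
  analytic specular reflection of its own launch ray.  The headline figure
  of merit is the maximum error over the *beam edge* (launch offset >= 95%
  of the beam radius), matching the beam-edge juxtaposition the scene is
  known for; the error over the whole reflected beam is also reported and is
  larger (the normal-map tail doubles into reflected directions).
* **2-D edge sweep** — worst-case facet error is measured by rasterizing
  binary half-plane edges over orientations 0-45 deg and taking, at every
  boundary pixel, the *best* mismatched-face axis (any other choice errs
  more): the maximum is 45 deg at theta = 45.  The Sobel direction error
  uses area-sampled (pixel-coverage, exact closed form) edges over a dense
  orientation x sub-pixel-offset sweep, evaluated at pixels the edge passes
  through centrally (|signed distance| <= 0.05 px): maximum 1.44 deg near
  theta = 35 deg.  Point-sampled binary edges measure something else — the
  staircase, not the operator — and give tens of degrees at individual
  pixels; the coverage model isolates the operator's intrinsic orientation
  error.
* **Lens scene** — symmetric biconvex lens (surface radii 1 cm, centre
  thickness 0.4 cm, aperture 0.8 cm, n 1.52) with mid-plane 0.35 cm deep on
  the axis of a 128^3 grid at dx = 0.01 cm; clear water (n 1.33) around it
  and an aqueous scattering solution (n 1.33, mu_s 100 /cm, g 0.90,
  mu_a 0.1 /cm — negligible against mu_s but enough to accumulate fluence)
  filling z >= 0.55 cm; collimated beam of radius 0.3 cm along +z.  Facet
  and interpolated runs share one seed (identical launch rays); the figure
  of merit is the maximum of 100 (phi_FN - phi_ISN)/phi_ISN over the
  scattering region.  The low-fluence floor for the percent map is 1e-3 of
  the peak reference fluence, which excludes statistically unvisited voxels;
  the file-level `percent_change_map` default floor is 1e-8 in absolute
  fluence units.

Problem sizes used throughout (10^4 photons for the sphere, 10^5 per lens
run, 220^3 and 128^3 grids) are the package's validation defaults; they make
the maximum-error statistics stable at single-CPU scale.

## What the synthetic scenes do and do not show

The phantoms exercise curved, oblique and flat boundaries, index mismatch,
total internal reflection, forward-peaked scattering and roulette, and the
clear-media scenes admit exact per-photon ground truth.  They do not
emulate heterogeneous absorption maps, rough or open surfaces, anisotropic
voxels, or segmentation noise of real tissue volumes; passing tests
demonstrate correctness of the transport and boundary machinery, not
accuracy for any particular biological geometry.

## Numerical choices

* Face crossings snap the crossed coordinate exactly onto the face;
  positions are then nudged 1e-7 voxel units off the face along the current
  direction before the next traversal step.
* Containment tests use voxel centroids everywhere; ties at exact surfaces
  are resolved by strict inequality (a centroid exactly on a sphere is
  outside).
* At exactly the critical angle the TIR branch is taken (R = 1), removing
  the undefined-transmission edge case.
* A hard cap of 2e7 events per photon guards against pathological loops;
  affected weight is reported as `lost` in the run stats and is zero in all
  shipped scenes.
* Normal maps are stored float32 (unit length to ~1e-7); transport computes
  in float64.

## Known limitations

* Single CPU only; no GPU path, no polarization, no time resolution.
* The probabilistic reflect/transmit split leaves the reflected beam of the
  sphere scene a stochastic subset of photons (R is small at moderate
  incidence), so reflected-beam statistics need ~10^4 launches.
* The normal map degrades near grid-aligned poles of curved surfaces (see
  measured percentiles above); a larger smoothing factor trades that tail
  against global surface deformation and is left to the user's visual
  judgement per scene.
* Escape records store one row per escaped photon; multiply-escaping
  photons cannot occur (escape terminates the history).
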